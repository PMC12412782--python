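import numpy as np
import pytest

from elongrate.genomic_io import GeneModel, LibraryStats, SignalTrack


@pytest.fixture
def toy_gene():
    return GeneModel("toy", "chr1", 1000, 2000, "+")


@pytest.fixture
def minus_gene():
    return GeneModel("toy_minus", "chr1", 1000, 2000, "-")


def make_track(gene_id, counts, library_size=None, upstream=None):
    counts = np.asarray(counts, dtype=np.int64)
    if library_size is None:
        library_size = max(int(counts.sum()), 1)
    return SignalTrack(gene_id, counts, library_size, upstream=upstream)


@pytest.fixture
def track_factory():
    return make_track


@pytest.fixture
def bam_factory(tmp_path):
    """Write a small single-end BAM from (chrom, start, length, strand, mapq)
    tuples; returns the sorted+indexed path."""
    import pysam

    def _write(reads, chrom_lengths=None, name="fixture"):
        if chrom_lengths is None:
            chroms = sorted({r[0] for r in reads}) or ["chr1"]
            chrom_lengths = {c: 100_000 for c in chroms}
        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": L} for c, L in sorted(chrom_lengths.items())],
        }
        ref_ids = {c: i for i, (c, _) in enumerate(sorted(chrom_lengths.items()))}
        path = str(tmp_path / f"{name}.bam")
        segs = []
        for i, (chrom, start, length, strand, mapq) in enumerate(reads):
            a = pysam.AlignedSegment()
            a.query_name = f"read{i}"
            a.query_sequence = "A" * length
            a.query_qualities = pysam.qualitystring_to_array("I" * length)
            a.reference_id = ref_ids[chrom]
            a.reference_start = start
            a.cigar = [(0, length)]
            a.mapping_quality = mapq
            a.flag = 16 if strand == "-" else 0
            segs.append(a)
        segs.sort(key=lambda a: (a.reference_id, a.reference_start))
        with pysam.AlignmentFile(path, "wb", header=header) as out:
            for a in segs:
                out.write(a)
        pysam.index(path)
        return path

    return _write


@pytest.fixture
def default_stats():
    return LibraryStats(total_counted=1_000_000, mapq_threshold=10)
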