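"""Gene models, strand-aware per-base read counting, and normalization.

Coordinate conventions
----------------------
External files keep their native conventions (BED is 0-based half-open,
GTF is 1-based inclusive). Internally every :class:`GeneModel` stores
0-based half-open genomic coordinates, while per-gene signal uses 1-based
gene-relative coordinates with base 1 at the TSS (so a minus-strand gene's
base 1 sits at its genomic ``end - 1``).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GeneModel",
    "SignalTrack",
    "LibraryStats",
    "GeneModelParseError",
    "read_gene_models",
    "load_signal",
    "compute_library_stats",
    "compute_fpkm",
    "filter_genes",
    "write_bedgraph",
    "merge_intervals",
]

END_CONVENTIONS = ("three_prime", "five_prime", "full_overlap")


class GeneModelParseError(ValueError):
    """Raised on malformed gene-model input; message names the line."""


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort half-open intervals and merge overlapping/adjacent-overlap ones."""
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass
class GeneModel:
    """One gene's genomic interval, strand and exon structure."""

    gene_id: str
    chrom: str
    start: int  # 0-based, half-open
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: end must exceed start")
        if not self.exons:
            self.exons = [(self.start, self.end)]
        self.exons = merge_intervals(self.exons)
        for s, e in self.exons:
            if s < self.start or e > self.end or e <= s:
                raise ValueError(
                    f"gene {self.gene_id}: exon ({s}, {e}) outside gene body"
                )

    @property
    def n(self) -> int:
        """Gene length in bp."""
        return self.end - self.start

    def rel_to_genomic(self, i: int) -> int:
        """1-based gene-relative base -> 0-based genomic position."""
        if not 1 <= i <= self.n:
            raise IndexError(f"gene-relative base {i} outside 1..{self.n}")
        return self.start + i - 1 if self.strand == "+" else self.end - i

    def genomic_to_rel(self, g: int) -> int:
        """0-based genomic position -> 1-based gene-relative base."""
        if not self.start <= g < self.end:
            raise IndexError(f"genomic position {g} outside gene interval")
        return g - self.start + 1 if self.strand == "+" else self.end - g

    @property
    def tss(self) -> int:
        """0-based genomic position of the TSS base."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class SignalTrack:
    """Per-base read-end counts for one gene, oriented TSS -> TTS.

    ``counts[0]`` is gene-relative base 1 (the TSS). ``upstream`` optionally
    holds counts for bases immediately 5' of the TSS (``upstream[-1]`` abuts
    the TSS), used by promoter-window statistics.
    """

    gene_id: str
    counts: np.ndarray
    library_size: int
    upstream: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be a 1-D vector")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if self.library_size < int(self.counts.sum()):
            raise ValueError("library_size smaller than the gene's own counts")


@dataclass
class LibraryStats:
    """Whole-library counting summary and the filters that produced it."""

    total_counted: int
    mapq_threshold: int = 10
    end_convention: str = "three_prime"
    paired: bool = False

    def __post_init__(self) -> None:
        if self.total_counted < 0 or self.mapq_threshold < 0:
            raise ValueError("total_counted and mapq_threshold must be >= 0")
        if self.end_convention not in END_CONVENTIONS:
            raise ValueError(f"end_convention must be one of {END_CONVENTIONS}")


# ---------------------------------------------------------------------------
# Gene-model parsing
# ---------------------------------------------------------------------------

def _parse_bed_line(line: str, lineno: int) -> GeneModel:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 6:
        raise GeneModelParseError(
            f"line {lineno}: BED record needs >= 6 fields for stranded genes"
        )
    try:
        chrom = fields[0]
        start, end = int(fields[1]), int(fields[2])
        name = fields[3] if fields[3] else f"gene_{lineno}"
        strand = fields[5]
    except ValueError as exc:
        raise GeneModelParseError(f"line {lineno}: {exc}") from None
    if strand not in ("+", "-"):
        raise GeneModelParseError(
            f"line {lineno}: unrecognized strand {strand!r} for gene {name}"
        )
    exons: list[tuple[int, int]] = []
    if len(fields) >= 12:
        try:
            count = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
        except ValueError as exc:
            raise GeneModelParseError(f"line {lineno}: bad block fields: {exc}") from None
        if len(sizes) != count or len(starts) != count:
            raise GeneModelParseError(
                f"line {lineno}: blockCount={count} disagrees with block lists"
            )
        exons = [(start + off, start + off + size) for off, size in zip(starts, sizes)]
    try:
        return GeneModel(name, chrom, start, end, strand, exons)
    except ValueError as exc:
        raise GeneModelParseError(f"line {lineno}: {exc}") from None


_GTF_GENE_ID = __import__("re").compile(r'gene_id\s+"([^"]+)"')


def _read_gtf(path: str) -> list[GeneModel]:
    # exon features are unioned across transcripts of the same gene_id
    per_gene: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GeneModelParseError(
                    f"line {lineno}: GTF record needs 9 fields, got {len(fields)}"
                )
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs = fields[:9]
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise GeneModelParseError(f"line {lineno}: non-integer coordinates") from None
            m = _GTF_GENE_ID.search(attrs)
            if m is None:
                raise GeneModelParseError(f"line {lineno}: missing gene_id attribute")
            gid = m.group(1)
            if strand not in ("+", "-"):
                raise GeneModelParseError(
                    f"line {lineno}: unrecognized strand {strand!r} for gene {gid}"
                )
            start, end = start1 - 1, end1  # GTF 1-based inclusive -> half-open
            rec = per_gene.get(gid)
            if rec is None:
                rec = {"chrom": chrom, "strand": strand, "start": start, "end": end,
                       "exons": []}
                per_gene[gid] = rec
                order.append(gid)
            else:
                if rec["chrom"] != chrom or rec["strand"] != strand:
                    raise GeneModelParseError(
                        f"line {lineno}: gene {gid} spans multiple chromosomes/strands"
                    )
                rec["start"] = min(rec["start"], start)
                rec["end"] = max(rec["end"], end)
            if feature == "exon":
                rec["exons"].append((start, end))
    return [
        GeneModel(gid, rec["chrom"], rec["start"], rec["end"], rec["strand"],
                  merge_intervals(rec["exons"]) if rec["exons"] else [])
        for gid, rec in ((g, per_gene[g]) for g in order)
    ]


def read_gene_models(path: str, fmt: str | None = None) -> list[GeneModel]:
    """Read gene models from a BED6/BED12 or GTF file.

    ``fmt`` is ``"bed"`` or ``"gtf"``; when omitted it is taken from the
    file extension. Parsers are deliberately local so errors can name the
    offending line number.
    """
    if fmt is None:
        ext = os.path.splitext(path)[1].lower()
        fmt = {"bed": "bed", "gtf": "gtf", "gff": "gtf"}.get(ext.lstrip("."))
        if fmt is None:
            raise ValueError(f"cannot infer gene-model format from {path!r}")
    if fmt == "gtf":
        return _read_gtf(path)
    if fmt != "bed":
        raise ValueError(f"unknown gene-model format {fmt!r}")
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            genes.append(_parse_bed_line(line, lineno))
    return genes


# ---------------------------------------------------------------------------
# BAM counting
# ---------------------------------------------------------------------------

def _read_passes(read, mapq_threshold: int) -> bool:
    return not (
        read.is_unmapped
        or read.is_secondary
        or read.is_supplementary
        or read.mapping_quality < mapq_threshold
    )


def _fragment_of(read) -> tuple[int, int, bool] | None:
    """(start, end, is_reverse) of the fragment represented by ``read``.

    Single-end reads represent themselves. For paired data only read 1 of a
    proper pair represents the fragment (counted once), with the fragment
    strand taken from read 1.
    """
    if read.is_paired:
        if not read.is_proper_pair or not read.is_read1:
            return None
        tlen = read.template_length
        if tlen > 0:
            return read.reference_start, read.reference_start + tlen, read.is_reverse
        if tlen < 0:
            return read.reference_end + tlen, read.reference_end, read.is_reverse
        return None
    return read.reference_start, read.reference_end, read.is_reverse


def _end_position(start: int, end: int, is_reverse: bool, convention: str) -> int:
    if convention == "three_prime":
        return start if is_reverse else end - 1
    # five_prime
    return end - 1 if is_reverse else start


def compute_library_stats(
    bam_path: str,
    mapq_threshold: int = 10,
    end_convention: str = "three_prime",
    paired: bool = False,
) -> LibraryStats:
    """Count qualifying read (or fragment) ends genome-wide, once per BAM."""
    import pysam

    total = 0
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        for read in bam.fetch(until_eof=True):
            if not _read_passes(read, mapq_threshold):
                continue
            if paired and _fragment_of(read) is None:
                continue
            if not paired and read.is_paired:
                continue
            total += 1
    return LibraryStats(total, mapq_threshold, end_convention, paired)


def load_signal(
    bam_path: str,
    gene: GeneModel,
    stats: LibraryStats,
    paired: bool | None = None,
    upstream: int = 0,
) -> SignalTrack:
    """Extract the gene's strand-matched per-base read-end counts.

    A read contributes when it passes the MAPQ filter and its alignment
    strand equals the gene strand (fragment strand from read 1 for paired
    data). Under the default ``three_prime`` convention each qualifying
    read adds one count at its 3'-most base in gene orientation;
    ``full_overlap`` instead increments every covered base.
    """
    import pysam

    if paired is None:
        paired = stats.paired
    n = gene.n
    counts = np.zeros(n, dtype=np.int64)
    up = np.zeros(upstream, dtype=np.int64) if upstream else None

    # genomic window, including the requested upstream flank
    if gene.strand == "+":
        win_start, win_end = gene.start - upstream, gene.end
    else:
        win_start, win_end = gene.start, gene.end + upstream
    win_start = max(0, win_start)

    def _deposit(g: int) -> None:
        if gene.start <= g < gene.end:
            counts[gene.genomic_to_rel(g) - 1] += 1
        elif up is not None:
            # distance upstream of the TSS, 1 = immediately 5' of base 1
            d = gene.start - g if gene.strand == "+" else g - (gene.end - 1)
            if 1 <= d <= upstream:
                up[upstream - d] += 1

    with pysam.AlignmentFile(bam_path, "rb") as bam:
        if gene.chrom not in bam.references:
            raise ValueError(f"chromosome {gene.chrom!r} absent from BAM header")
        for read in bam.fetch(gene.chrom, win_start, win_end):
            if not _read_passes(read, stats.mapq_threshold):
                continue
            if paired != read.is_paired:
                continue
            frag = _fragment_of(read)
            if frag is None:
                continue
            fstart, fend, is_rev = frag
            read_strand = "-" if is_rev else "+"
            if read_strand != gene.strand:
                continue
            if stats.end_convention == "full_overlap":
                for g in range(fstart, fend):
                    _deposit(g)
            else:
                _deposit(_end_position(fstart, fend, is_rev, stats.end_convention))

    return SignalTrack(gene.gene_id, counts, stats.total_counted, upstream=up)


# ---------------------------------------------------------------------------
# Normalization and filtering
# ---------------------------------------------------------------------------

def compute_fpkm(track: SignalTrack, gene: GeneModel) -> float:
    """Fragments per kilobase of gene per million counted library ends."""
    if track.library_size <= 0:
        raise ValueError("library_size must be positive to compute FPKM")
    if gene.n <= 0:
        raise ValueError("gene length must be positive")
    return float(track.counts.sum()) / ((gene.n / 1e3) * (track.library_size / 1e6))


def filter_genes(
    genes: Sequence[GeneModel],
    reference_tracks: Mapping[str, SignalTrack],
    min_length: int = 40_000,
    min_fpkm: float = 1.0,
) -> list[GeneModel]:
    """Keep genes with length >= ``min_length`` and reference FPKM strictly
    greater than ``min_fpkm``."""
    kept = []
    for gene in genes:
        try:
            track = reference_tracks[gene.gene_id]
        except KeyError:
            raise KeyError(f"no reference track for gene {gene.gene_id}") from None
        if gene.n >= min_length and compute_fpkm(track, gene) > min_fpkm:
            kept.append(gene)
    return kept


def write_bedgraph(track: SignalTrack, gene: GeneModel, path: str) -> None:
    """Write the gene's counts as a 4-column bedGraph in genomic order."""
    vals = track.counts if gene.strand == "+" else track.counts[::-1]
    with open(path, "w") as fh:
        run_start = 0
        for i in range(1, len(vals) + 1):
            if i == len(vals) or vals[i] != vals[run_start]:
                v = int(vals[run_start])
                if v != 0:
                    fh.write(
                        f"{gene.chrom}\t{gene.start + run_start}\t{gene.start + i}\t{v}\n"
                    )
                run_start = i
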