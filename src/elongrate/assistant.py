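"""Auxiliary transcription-dynamics statistics.

Pause index, metagene compression with quantile capping, GC content, k-mer
enrichment between gene sets, exon density, and quantile-based clustering
of genes by inferred rate.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

from .genomic_io import GeneModel, SignalTrack, merge_intervals

__all__ = [
    "MetageneMatrix",
    "PauseIndexResult",
    "pause_index",
    "compress_metagene",
    "gc_content",
    "kmer_ratio",
    "exon_density",
    "quantile_split",
    "compare_clusters",
    "gene_sequence",
]


@dataclass
class PauseIndexResult:
    gene_id: str
    value: float | None
    excluded: bool = False
    zero_body: bool = False


@dataclass
class MetageneMatrix:
    """Genes x compressed-position matrix of FPM values."""

    gene_ids: list[str]
    positions: np.ndarray
    fpm: np.ndarray
    cap_quantile: float

    def curve(self) -> np.ndarray:
        """Column means: the metagene profile."""
        return self.fpm.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.fpm, index=self.gene_ids, columns=self.positions)


def _promoter_window(gene: GeneModel, halfwidth: int) -> tuple[int, int]:
    """Genomic half-open interval of TSS +/- halfwidth."""
    tss = gene.tss
    return max(0, tss - halfwidth), tss + halfwidth + (1 if gene.strand == "-" else 0)


def pause_index(
    track: SignalTrack,
    gene: GeneModel,
    promoter_halfwidth: int = 1000,
    all_genes: Sequence[GeneModel] = (),
) -> PauseIndexResult:
    """Promoter-to-body Pol II density ratio.

    The promoter is TSS +/- ``promoter_halfwidth``; the gene body runs from
    the promoter's downstream edge to the TTS, so the two densities are
    disjoint. The gene is excluded (no value) when the promoter window or
    the gene interval overlaps any other gene on the same chromosome.
    Upstream promoter counts are taken from ``track.upstream`` when present,
    otherwise the promoter reduces to its intragenic half.
    """
    hw = promoter_halfwidth
    n = gene.n
    if n <= hw:
        raise ValueError("gene length must exceed the promoter window")

    # overlap exclusion across the promoter + body extent
    ps, pe = _promoter_window(gene, hw)
    ext_start = min(ps, gene.start)
    ext_end = max(pe, gene.end)
    for other in all_genes:
        if other.gene_id == gene.gene_id or other.chrom != gene.chrom:
            continue
        if other.start < ext_end and ext_start < other.end:
            return PauseIndexResult(gene.gene_id, None, excluded=True)

    prom_counts = float(track.counts[:hw].sum())
    prom_len = hw
    if track.upstream is not None and len(track.upstream) > 0:
        up = track.upstream[-hw:]
        prom_counts += float(up.sum())
        prom_len += len(up)
    body_counts = float(track.counts[hw:].sum())
    body_len = n - hw

    prom_density = prom_counts / prom_len
    if body_counts == 0:
        return PauseIndexResult(gene.gene_id, None, zero_body=True)
    body_density = body_counts / body_len
    return PauseIndexResult(gene.gene_id, prom_density / body_density)


def _resample_row(fpm: np.ndarray, target: int) -> np.ndarray:
    """Average the bases mapped to each of ``target`` output positions by
    proportional coordinate mapping; nearest-base fill when upsampling."""
    n = fpm.size
    idx = (np.arange(n, dtype=np.int64) * target) // n
    sums = np.bincount(idx, weights=fpm, minlength=target)
    cnts = np.bincount(idx, minlength=target)
    nearest = fpm[(np.arange(target, dtype=np.int64) * n) // target]
    return np.where(cnts > 0, sums / np.maximum(cnts, 1), nearest)


def compress_metagene(
    tracks: Mapping[str, SignalTrack] | Sequence[SignalTrack],
    target_length: int = 2000,
    cap_quantile: float = 0.99,
) -> MetageneMatrix:
    """Compress each gene's TSS->TTS FPM vector to ``target_length`` points
    and cap the matrix at its ``cap_quantile`` quantile."""
    if target_length < 1:
        raise ValueError("target_length must be >= 1")
    if not 0 < cap_quantile <= 1:
        raise ValueError("cap_quantile must be in (0, 1]")
    items = list(tracks.values()) if isinstance(tracks, Mapping) else list(tracks)
    if not items:
        raise ValueError("no tracks supplied")
    rows = []
    ids = []
    for track in items:
        if track.counts.size == 0:
            raise ValueError(f"track {track.gene_id} is empty")
        if track.library_size <= 0:
            raise ValueError(f"track {track.gene_id} has zero library size")
        fpm = track.counts.astype(float) / track.library_size * 1e6
        rows.append(_resample_row(fpm, target_length))
        ids.append(track.gene_id)
    matrix = np.vstack(rows)
    cap = float(np.quantile(matrix, cap_quantile))
    matrix = np.minimum(matrix, cap)
    return MetageneMatrix(ids, np.arange(1, target_length + 1), matrix, cap_quantile)


def gc_content(sequence: str) -> float:
    """(G+C)/(A+C+G+T), case-insensitive; N bases are ignored. NaN when the
    sequence has no unambiguous base."""
    if not sequence:
        raise ValueError("sequence must be nonempty")
    s = sequence.upper()
    a, c, g, t = s.count("A"), s.count("C"), s.count("G"), s.count("T")
    denom = a + c + g + t
    if denom == 0:
        return float("nan")
    return (g + c) / denom


def _count_kmers(sequences: Iterable[str], k: int) -> tuple[dict[str, int], int]:
    counts: dict[str, int] = {}
    total = 0
    valid = set("ACGT")
    for seq in sequences:
        s = seq.upper()
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            if set(kmer) <= valid:
                counts[kmer] = counts.get(kmer, 0) + 1
                total += 1
    return counts, total


def kmer_ratio(
    set_a: Sequence[str],
    set_b: Sequence[str],
    k: int = 6,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-k-mer frequency ratio between two sequence sets.

    Frequencies use overlapping sense-strand windows with pseudocount
    smoothing over the full 4^k alphabet; output is sorted by descending
    ratio (ties broken alphabetically for determinism).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not set_a or not set_b:
        raise ValueError("both sequence sets must be nonempty")
    counts_a, tot_a = _count_kmers(set_a, k)
    counts_b, tot_b = _count_kmers(set_b, k)
    denom_a = tot_a + pseudocount * 4**k
    denom_b = tot_b + pseudocount * 4**k
    rows = []
    for kmer_tuple in itertools.product("ACGT", repeat=k):
        kmer = "".join(kmer_tuple)
        fa = (counts_a.get(kmer, 0) + pseudocount) / denom_a
        fb = (counts_b.get(kmer, 0) + pseudocount) / denom_b
        rows.append((kmer, fa, fb, fa / fb))
    df = pd.DataFrame(rows, columns=["kmer", "freq_a", "freq_b", "ratio"])
    return df.sort_values(["ratio", "kmer"], ascending=[False, True], ignore_index=True)


def exon_density(gene: GeneModel) -> float:
    """Exons per kilobase of gene length; overlapping records merge to one."""
    return len(merge_intervals(gene.exons)) * 1000.0 / gene.n


def quantile_split(
    rates: Mapping[str, float], q: float = 0.5
) -> tuple[list[str], list[str], float]:
    """Split genes at the ``q`` quantile of their rates.

    Quantile1 holds genes with rate strictly below the threshold, Quantile2
    the rest. Returns (quantile1_ids, quantile2_ids, threshold).
    """
    if len(rates) < 2:
        raise ValueError("need at least 2 genes to split")
    values = np.array(list(rates.values()), dtype=float)
    threshold = float(np.quantile(values, q))
    q1 = [g for g, r in rates.items() if r < threshold]
    q2 = [g for g, r in rates.items() if r >= threshold]
    if not q1 or not q2:
        warnings.warn("quantile split produced an empty cluster", stacklevel=2)
    return q1, q2, threshold


def compare_clusters(
    values: Mapping[str, float], cluster1: Sequence[str], cluster2: Sequence[str]
) -> float:
    """Two-sided Wilcoxon rank-sum p-value comparing a per-gene statistic
    between two gene clusters."""
    a = [values[g] for g in cluster1 if g in values]
    b = [values[g] for g in cluster2 if g in values]
    if not a or not b:
        return float("nan")
    return float(_st.mannwhitneyu(a, b, alternative="two-sided").pvalue)


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def gene_sequence(fasta, gene: GeneModel) -> str:
    """Sense-strand sequence of the gene from a pyfaidx Fasta handle."""
    seq = str(fasta[gene.chrom][gene.start : gene.end])
    if gene.strand == "-":
        seq = seq.translate(_COMPLEMENT)[::-1]
    return seq
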