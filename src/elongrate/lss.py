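"""Least-sum-of-squares transition-point detection and rate inference.

The detector scans every pointer position ``p`` splitting a vector of
normalized treatment/reference coverage ratios into a left segment
``values[1..p]`` and a right segment ``values[p+1..L]``, scores the split by
the summed within-segment sums of squared deviations (the contiguous
2-cluster k-means objective), and picks the minimizing pointer. The search
runs twice: once over coarse gene bins, then base-by-base over the chosen
bin merged with its downstream neighbor.
"""

from __future__ import annotations

import itertools as _itertools
import math as _math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

from .genomic_io import GeneModel, SignalTrack, compute_fpkm, filter_genes

__all__ = [
    "RatioProfile",
    "SplitScan",
    "TransitionCall",
    "RateRunConfig",
    "bin_edges",
    "bin_ratios",
    "base_ratios",
    "ss_scan",
    "count_candidates",
    "split_significance",
    "pointer_significance",
    "refine_to_base",
    "infer_rate",
    "call_transitions",
    "calrate",
    "adjust_pvalues",
]


@dataclass
class RatioProfile:
    """Normalized treatment/reference ratios over bins or bases of one gene."""

    gene_id: str
    level: str  # {"bin", "base"}
    values: np.ndarray
    bin_edges: list[tuple[int, int]]  # 1-based inclusive gene-relative spans
    window_num: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("ratio values must be finite and nonnegative")
        if len(self.values) != len(self.bin_edges):
            raise ValueError("values and bin_edges lengths disagree")


@dataclass
class SplitScan:
    ss: np.ndarray
    argmin: int  # 1-based pointer, ties broken to the smallest
    n_candidates: int


@dataclass
class TransitionCall:
    gene_id: str
    transition_bin: int
    transition_base: int
    p_bin: float
    p_base: float
    q_bin: float = float("nan")
    q_base: float = float("nan")
    significant: bool = False
    rate_bp_per_min: float = float("nan")
    reference_fpkm: float = float("nan")


@dataclass
class RateRunConfig:
    """Knobs for a full rate-inference run."""

    window_num: int = 40
    treatment_minutes: float = 15.0
    alpha: float = 0.05
    pseudocount: float = 1.0
    adjust_method: str = "bh"
    min_length: int = 40_000
    min_fpkm: float = 1.0

    def __post_init__(self) -> None:
        if self.window_num < 2:
            raise ValueError("window_num must be >= 2")
        if self.treatment_minutes <= 0:
            raise ValueError("treatment_minutes must be positive")


# ---------------------------------------------------------------------------
# Binning and ratio profiles
# ---------------------------------------------------------------------------

def bin_edges(n: int, m: int) -> list[tuple[int, int]]:
    """Tile ``n`` bases into ``m`` bins: the first m-1 bins have width
    floor(n/m) and the last absorbs the remainder. 1-based inclusive."""
    if m < 2:
        raise ValueError("need at least 2 bins")
    if m > n:
        raise ValueError(f"cannot tile {n} bases into {m} bins")
    w = n // m
    edges = [(i * w + 1, (i + 1) * w) for i in range(m - 1)]
    edges.append(((m - 1) * w + 1, n))
    return edges


def _normalized_ratio(
    t: np.ndarray, r: np.ndarray, t_lib: int, r_lib: int, pseudocount: float
) -> np.ndarray:
    if t_lib <= 0 or r_lib <= 0:
        raise ValueError("library sizes must be positive")
    return ((t + pseudocount) / t_lib) / ((r + pseudocount) / r_lib)


def bin_ratios(
    treatment: SignalTrack,
    reference: SignalTrack,
    gene: GeneModel,
    m: int,
    pseudocount: float = 1.0,
) -> RatioProfile:
    """Per-bin normalized treatment/reference count ratios over the gene."""
    n = gene.n
    if len(treatment.counts) != n or len(reference.counts) != n:
        raise ValueError("tracks do not cover the gene")
    edges = bin_edges(n, m)
    bounds = np.array([s - 1 for s, _ in edges] + [n])
    t_sums = np.add.reduceat(treatment.counts, bounds[:-1]).astype(float)
    r_sums = np.add.reduceat(reference.counts, bounds[:-1]).astype(float)
    values = _normalized_ratio(
        t_sums, r_sums, treatment.library_size, reference.library_size, pseudocount
    )
    return RatioProfile(gene.gene_id, "bin", values, edges, window_num=m)


def base_ratios(
    treatment: SignalTrack,
    reference: SignalTrack,
    gene: GeneModel,
    region: tuple[int, int],
    pseudocount: float = 1.0,
) -> RatioProfile:
    """Per-base normalized ratios over a 1-based inclusive gene-relative span."""
    s, e = region
    if not (1 <= s <= e <= gene.n):
        raise ValueError(f"region {region} outside gene of length {gene.n}")
    t = treatment.counts[s - 1 : e].astype(float)
    r = reference.counts[s - 1 : e].astype(float)
    values = _normalized_ratio(
        t, r, treatment.library_size, reference.library_size, pseudocount
    )
    edges = [(i, i) for i in range(s, e + 1)]
    return RatioProfile(gene.gene_id, "base", values, edges)


# ---------------------------------------------------------------------------
# The split scan
# ---------------------------------------------------------------------------

def ss_scan(values: Sequence[float]) -> SplitScan:
    """Score every split pointer by summed within-segment squared deviations.

    Pointer ``p`` (1-based, p = 1..L) splits the vector into ``values[1..p]``
    and ``values[p+1..L]``; an empty or single-element segment contributes 0.
    Returns one SS per pointer; ties in the minimum go to the smallest p.
    """
    v = np.asarray(values, dtype=float)
    L = v.size
    if L < 2:
        raise ValueError("need at least 2 values to scan for a split")
    c1 = np.concatenate(([0.0], np.cumsum(v)))
    c2 = np.concatenate(([0.0], np.cumsum(v * v)))
    p = np.arange(1, L + 1)
    sse_left = c2[p] - c1[p] ** 2 / p
    rlen = L - p
    safe = np.maximum(rlen, 1)
    sse_right = np.where(rlen > 0, (c2[L] - c2[p]) - (c1[L] - c1[p]) ** 2 / safe, 0.0)
    ss = np.maximum(sse_left, 0.0) + np.maximum(sse_right, 0.0)
    # squash accumulated rounding noise so exact ties (constant segments)
    # resolve to the smallest pointer
    ss[ss < 1e-12 * max(1.0, float(c2[L]))] = 0.0
    return SplitScan(ss=ss, argmin=int(np.argmin(ss)) + 1, n_candidates=L)


def count_candidates(n: int, m: int, two_stage: bool = True) -> int:
    """Number of SS evaluations for a gene of ``n`` bases and ``m`` bins."""
    if not (2 <= m <= n):
        raise ValueError("need n >= m >= 2")
    return m + 2 * (n // m) if two_stage else n


def split_significance(values: Sequence[float], p: int) -> float:
    """One-sided Mann-Whitney p-value that ``values[1..p]`` are
    stochastically smaller than ``values[p+1..L]``.

    Exact null distribution when both segments have <= 25 elements and the
    data are tie-free; exact permutation enumeration for small tied samples;
    tie-corrected normal approximation otherwise.
    """
    v = np.asarray(values, dtype=float)
    left, right = v[:p], v[p:]
    if left.size == 0 or right.size == 0:
        raise ValueError("both segments must be nonempty")
    no_ties = np.unique(v).size == v.size
    small = left.size <= 25 and right.size <= 25
    if small and no_ties:
        method = "exact"
    elif small and _math.comb(v.size, left.size) <= 5000:
        return _exact_permutation_p(left, right)
    else:
        method = "asymptotic"
    return float(_st.mannwhitneyu(left, right, alternative="less", method=method).pvalue)


def _u_statistic(left: np.ndarray, right: np.ndarray) -> float:
    """Mann-Whitney U1 (left wins; ties count half) — small when the left
    segment is stochastically smaller."""
    gt = (left[:, None] > right[None, :]).sum()
    eq = (left[:, None] == right[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def _exact_permutation_p(left: np.ndarray, right: np.ndarray) -> float:
    """Exact one-sided p by enumerating every assignment of the pooled
    values to a left segment of the observed size (handles ties)."""
    pooled = np.concatenate([left, right])
    n1 = left.size
    u_obs = _u_statistic(left, right)
    hits = 0
    total = 0
    idx = range(pooled.size)
    for combo in _itertools.combinations(idx, n1):
        mask = np.zeros(pooled.size, dtype=bool)
        mask[list(combo)] = True
        if _u_statistic(pooled[mask], pooled[~mask]) <= u_obs + 1e-12:
            hits += 1
        total += 1
    return hits / total


def pointer_significance(values: Sequence[float], p: int) -> float:
    """Split p-value Bonferroni-corrected for the data-driven choice of the
    pointer among the L-1 candidate splits with two nonempty segments."""
    L = len(values)
    return min(1.0, split_significance(values, p) * max(L - 1, 1))


# ---------------------------------------------------------------------------
# Two-stage refinement and rates
# ---------------------------------------------------------------------------

def expansion_region(n: int, m: int, transition_bin: int) -> tuple[int, int]:
    """Gene-relative 1-based inclusive span of the transition bin merged with
    its downstream neighbor (the last bin alone when transition_bin == m)."""
    edges = bin_edges(n, m)
    if not 1 <= transition_bin <= m:
        raise ValueError("transition_bin outside 1..m")
    start = edges[transition_bin - 1][0]
    end = edges[transition_bin][1] if transition_bin < m else edges[m - 1][1]
    return start, end


def refine_to_base(
    treatment: SignalTrack,
    reference: SignalTrack,
    gene: GeneModel,
    transition_bin: int,
    m: int,
    pseudocount: float = 1.0,
    pointer_fn=None,
) -> tuple[int, float, RatioProfile]:
    """Re-run the scan base-by-base inside the expanded two-bin region.

    Returns (transition_base, selection-corrected base-level p, profile).
    ``pointer_fn`` maps a ratio vector to a 1-based pointer; defaults to the
    SS-scan argmin (the HMM baseline passes its own).
    """
    region = expansion_region(gene.n, m, transition_bin)
    if region[1] - region[0] + 1 < 2:
        raise ValueError("expansion region shorter than 2 bases")
    profile = base_ratios(treatment, reference, gene, region, pseudocount)
    if pointer_fn is None:
        pointer = ss_scan(profile.values).argmin
    else:
        pointer = pointer_fn(profile.values)
        if pointer is None:
            return -1, float("nan"), profile
    transition_base = region[0] + pointer - 1
    L = len(profile.values)
    p_base = pointer_significance(profile.values, pointer) if pointer < L else float("nan")
    return transition_base, p_base, profile


def infer_rate(transition_base: int, treatment_minutes: float) -> float:
    """Elongation rate in bp/min: TSS-to-transition distance over block time."""
    if treatment_minutes <= 0:
        raise ValueError("treatment_minutes must be positive")
    return transition_base / treatment_minutes


def adjust_pvalues(pvals: np.ndarray, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg adjustment; NaNs are passed through untouched."""
    if method != "bh":
        raise ValueError(f"unsupported adjustment method {method!r}")
    p = np.asarray(pvals, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = _st.false_discovery_control(p[ok], method="bh")
    return q


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def call_transitions(
    genes: Sequence[GeneModel],
    treatment_tracks: Mapping[str, SignalTrack],
    reference_tracks: Mapping[str, SignalTrack],
    config: RateRunConfig | None = None,
    method: str = "lss",
    apply_filters: bool = True,
) -> pd.DataFrame:
    """Run the full two-stage transition scan over a gene set.

    Returns one row per tested gene with bin- and base-level pointers,
    selection-corrected Wilcoxon p-values, BH-adjusted q-values, the
    significance gate (bin-level q <= alpha) and the inferred rate.
    ``n_ss_evals`` instruments the number of SS evaluations actually
    performed (LSS only).
    """
    if config is None:
        config = RateRunConfig()
    if method not in ("lss", "hmm"):
        raise ValueError("method must be 'lss' or 'hmm'")
    if method == "hmm":
        from .hmm import hmm_transition_point

        def _bin_pointer(v):
            ptr, valid = hmm_transition_point(v)
            return ptr if valid else None

        def _base_pointer(v):
            ptr, valid = hmm_transition_point(v)
            return ptr if valid else None
    else:
        _bin_pointer = None
        _base_pointer = None

    tested = (
        filter_genes(genes, reference_tracks, config.min_length, config.min_fpkm)
        if apply_filters
        else list(genes)
    )
    if not tested:
        warnings.warn("no genes pass the length/FPKM filters", stacklevel=2)

    rows = []
    for gene in tested:
        t = treatment_tracks[gene.gene_id]
        r = reference_tracks[gene.gene_id]
        profile = bin_ratios(t, r, gene, config.window_num, config.pseudocount)
        m = config.window_num
        n_evals = m
        if _bin_pointer is None:
            tbin = ss_scan(profile.values).argmin
        else:
            tbin = _bin_pointer(profile.values)
        row = {
            "gene_id": gene.gene_id,
            "chrom": gene.chrom,
            "strand": gene.strand,
            "n": gene.n,
            "method": method.upper(),
            "transition_bin": np.nan,
            "transition_base": np.nan,
            "p_bin": np.nan,
            "p_base": np.nan,
            "rate_bp_per_min": np.nan,
            "reference_fpkm": compute_fpkm(r, gene),
            "n_ss_evals": np.nan,
        }
        if tbin is not None:
            row["transition_bin"] = tbin
            if tbin < m:
                row["p_bin"] = pointer_significance(profile.values, tbin)
            tbase, p_base, base_profile = refine_to_base(
                t, r, gene, tbin, m, config.pseudocount, pointer_fn=_base_pointer
            )
            if tbase > 0:
                row["transition_base"] = tbase
                row["p_base"] = p_base
                row["rate_bp_per_min"] = infer_rate(tbase, config.treatment_minutes)
            if method == "lss":
                row["n_ss_evals"] = n_evals + len(base_profile.values)
        rows.append(row)

    df = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "chrom", "strand", "n", "method", "transition_bin",
            "transition_base", "p_bin", "p_base", "rate_bp_per_min",
            "reference_fpkm", "n_ss_evals",
        ],
    )
    if df.empty:
        for col in ("q_bin", "q_base", "significant"):
            df[col] = []
        return df
    df["q_bin"] = adjust_pvalues(df["p_bin"].to_numpy(), config.adjust_method)
    df["q_base"] = adjust_pvalues(df["p_base"].to_numpy(), config.adjust_method)
    df["significant"] = (df["q_bin"] <= config.alpha).fillna(False)
    return df


def calrate(
    treatment_bam: str,
    reference_bam: str,
    genes: Sequence[GeneModel],
    config: RateRunConfig | None = None,
    method: str = "lss",
    mapq_threshold: int = 10,
    end_convention: str = "three_prime",
    paired: bool = False,
) -> pd.DataFrame:
    """End-to-end rate inference from a treatment/reference BAM pair."""
    from .genomic_io import compute_library_stats, load_signal

    if config is None:
        config = RateRunConfig()
    t_stats = compute_library_stats(treatment_bam, mapq_threshold, end_convention, paired)
    r_stats = compute_library_stats(reference_bam, mapq_threshold, end_convention, paired)
    treatment_tracks = {
        g.gene_id: load_signal(treatment_bam, g, t_stats, paired) for g in genes
    }
    reference_tracks = {
        g.gene_id: load_signal(reference_bam, g, r_stats, paired) for g in genes
    }
    return call_transitions(genes, treatment_tracks, reference_tracks, config, method)
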