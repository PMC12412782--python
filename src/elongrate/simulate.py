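"""Synthetic drug-block nascent-RNA datasets and the accuracy harness.

Each simulated gene carries a reference track with roughly uniform Poisson
coverage and a treatment track whose 5' region (up to a per-gene truth
point) is read-depleted. Negative mode omits the depletion entirely and is
used to measure false-positive rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_io import GeneModel, SignalTrack
from .lss import RateRunConfig, call_transitions

__all__ = [
    "SimConfig",
    "SimDataset",
    "AccuracyReport",
    "simulate_dataset",
    "evaluate_accuracy",
    "accuracy_grid",
    "write_truth_table",
    "read_truth_table",
    "write_genes_bed",
    "write_dataset_bedgraph",
    "write_gene_bam",
]

GENE_GAP = 1000  # bp between consecutive simulated genes
CHROM = "chrS"


@dataclass
class SimConfig:
    """Generative parameters for one synthetic dataset."""

    n_genes: int = 150
    gene_length_range: tuple[int, int] = (40_000, 60_000)
    base_rate: float = 1.0  # expected reference reads per base
    distance: float = 0.5  # depleted-region length as fraction of the gene
    difference: float = 0.02  # depleted/intact expected-signal ratio
    depth: float = 1.0  # treatment intact-region depth multiplier
    window_num: int = 40
    seed: int = 0
    negative: bool = False
    dispersion: float | None = None  # NB overdispersion; None = Poisson

    def __post_init__(self) -> None:
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ValueError("invalid gene_length_range")
        if not 0 < self.distance <= 1:
            raise ValueError("distance must be in (0, 1]")
        if not 0 <= self.difference <= 1:
            raise ValueError("difference must be in [0, 1]")
        if self.depth <= 0 or self.base_rate <= 0:
            raise ValueError("depth and base_rate must be positive")
        if self.n_genes < 1:
            raise ValueError("need at least one gene")


@dataclass
class SimDataset:
    genes: list[GeneModel]
    reference_tracks: dict[str, SignalTrack]
    treatment_tracks: dict[str, SignalTrack]
    truth: dict[str, int] | None  # gene_id -> true transition base (1-based)
    config: SimConfig = field(repr=False, default=None)


@dataclass
class AccuracyReport:
    n_genes: int
    n_called: int  # significant calls
    n_correct: int
    accuracy: float
    false_positive_rate: float | None
    deltas: list  # signed bp errors for significant calls on positive genes


def _draw_counts(rng: np.random.Generator, mean: float, size: int,
                 dispersion: float | None) -> np.ndarray:
    if mean == 0:
        return np.zeros(size, dtype=np.int64)
    if dispersion is None:
        return rng.poisson(mean, size)
    # NB with mean `mean` and shape `dispersion` (var = mean + mean^2/dispersion)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size)


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Generate genes, truth points, and reference/treatment count tracks.

    Deterministic under ``config.seed``. Library sizes are the total counts
    of each simulated track set (a self-contained sequencing universe).
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.gene_length_range
    genes: list[GeneModel] = []
    ref_counts: dict[str, np.ndarray] = {}
    trt_counts: dict[str, np.ndarray] = {}
    truth: dict[str, int] = {}
    cursor = GENE_GAP
    for i in range(config.n_genes):
        n = int(rng.integers(lo, hi + 1))
        gid = f"simgene_{i + 1}"
        strand = "+" if i % 2 == 0 else "-"
        genes.append(GeneModel(gid, CHROM, cursor, cursor + n, strand))
        cursor += n + GENE_GAP
        ref_counts[gid] = _draw_counts(rng, config.base_rate, n, config.dispersion)
        if config.negative:
            trt_counts[gid] = _draw_counts(
                rng, config.base_rate * config.depth, n, config.dispersion
            )
        else:
            t_base = int(np.floor(config.distance * n + 0.5))  # ties round up
            truth[gid] = t_base
            depleted = _draw_counts(
                rng, config.base_rate * config.depth * config.difference,
                t_base, config.dispersion,
            )
            intact = _draw_counts(
                rng, config.base_rate * config.depth, n - t_base, config.dispersion
            )
            trt_counts[gid] = np.concatenate([depleted, intact])
    ref_lib = int(sum(c.sum() for c in ref_counts.values()))
    trt_lib = int(sum(c.sum() for c in trt_counts.values()))
    reference_tracks = {
        g: SignalTrack(g, c, max(ref_lib, 1)) for g, c in ref_counts.items()
    }
    treatment_tracks = {
        g: SignalTrack(g, c, max(trt_lib, 1)) for g, c in trt_counts.items()
    }
    return SimDataset(
        genes, reference_tracks, treatment_tracks,
        None if config.negative else truth, config,
    )


def run_inference(
    dataset: SimDataset,
    method: str = "lss",
    rate_config: RateRunConfig | None = None,
) -> pd.DataFrame:
    """Run the transition caller over a simulated dataset."""
    if rate_config is None:
        rate_config = RateRunConfig(window_num=dataset.config.window_num)
    return call_transitions(
        dataset.genes,
        dataset.treatment_tracks,
        dataset.reference_tracks,
        rate_config,
        method=method,
        apply_filters=False,
    )


def evaluate_accuracy(
    calls: pd.DataFrame, dataset: SimDataset, tolerance: int = 50
) -> AccuracyReport:
    """Score calls against the generator truth table.

    A positive gene is correct when its call is significant and the inferred
    base lies within ``tolerance`` bp of the truth; the denominator is all
    simulated genes. In negative mode the false-positive rate is the
    fraction of genes called significant.
    """
    called_ids = set(calls["gene_id"])
    sim_ids = {g.gene_id for g in dataset.genes}
    if not called_ids <= sim_ids:
        raise ValueError("calls contain genes absent from the simulated dataset")
    n_genes = len(dataset.genes)
    sig = calls[calls["significant"].astype(bool)]
    if dataset.truth is None:
        return AccuracyReport(
            n_genes=n_genes, n_called=len(sig), n_correct=0,
            accuracy=float("nan"),
            false_positive_rate=len(sig) / n_genes, deltas=[],
        )
    deltas = []
    n_correct = 0
    for _, row in sig.iterrows():
        truth_base = dataset.truth[row["gene_id"]]
        if np.isnan(row["transition_base"]):
            continue
        delta = int(row["transition_base"]) - truth_base
        deltas.append(delta)
        if abs(delta) <= tolerance:
            n_correct += 1
    return AccuracyReport(
        n_genes=n_genes, n_called=len(sig), n_correct=n_correct,
        accuracy=n_correct / n_genes, false_positive_rate=None, deltas=deltas,
    )


def accuracy_grid(
    base_config: SimConfig,
    sweep: Mapping[str, Sequence],
    method: str = "lss",
    rate_config: RateRunConfig | None = None,
    tolerance: int = 50,
) -> pd.DataFrame:
    """One accuracy per swept parameter value, other parameters fixed.

    Sweepable parameters: distance, difference, depth, window_num. The seed
    is held fixed across levels so batches stay comparable.
    """
    allowed = {"distance", "difference", "depth", "window_num"}
    rows = []
    for param, values in sweep.items():
        if param not in allowed:
            raise ValueError(f"cannot sweep {param!r}; choose from {sorted(allowed)}")
        for value in values:
            kwargs = {**base_config.__dict__}
            kwargs[param] = value
            cfg = SimConfig(**kwargs)
            dataset = simulate_dataset(cfg)
            rc = rate_config
            if rc is None or param == "window_num":
                rc = RateRunConfig(window_num=cfg.window_num)
            calls = run_inference(dataset, method=method, rate_config=rc)
            report = evaluate_accuracy(calls, dataset, tolerance)
            rows.append(
                {
                    "parameter": param,
                    "value": value,
                    "method": method.upper(),
                    "n_genes": report.n_genes,
                    "n_called": report.n_called,
                    "accuracy": report.accuracy,
                    "false_positive_rate": report.false_positive_rate,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Plain-text and BAM fixture writers
# ---------------------------------------------------------------------------

def write_truth_table(dataset: SimDataset, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tn\ttruth_base\n")
        for gene in dataset.genes:
            t = "" if dataset.truth is None else dataset.truth[gene.gene_id]
            fh.write(f"{gene.gene_id}\t{gene.n}\t{t}\n")


def read_truth_table(path: str) -> dict[str, int | None]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, int | None] = {}
    for _, row in df.iterrows():
        val = row["truth_base"]
        out[row["gene_id"]] = None if pd.isna(val) else int(val)
    return out


def write_genes_bed(genes: Sequence[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def write_dataset_bedgraph(dataset: SimDataset, prefix: str) -> tuple[str, str]:
    """Write treatment/reference tracks as two bedGraph files."""
    paths = (f"{prefix}.treatment.bedgraph", f"{prefix}.reference.bedgraph")
    for path, tracks in zip(paths, (dataset.treatment_tracks, dataset.reference_tracks)):
        with open(path, "w") as out:
            for gene in dataset.genes:
                track = tracks[gene.gene_id]
                vals = track.counts if gene.strand == "+" else track.counts[::-1]
                run_start = 0
                for i in range(1, len(vals) + 1):
                    if i == len(vals) or vals[i] != vals[run_start]:
                        v = int(vals[run_start])
                        if v != 0:
                            out.write(
                                f"{gene.chrom}\t{gene.start + run_start}"
                                f"\t{gene.start + i}\t{v}\n"
                            )
                        run_start = i
    return paths


def write_gene_bam(
    tracks: Mapping[str, SignalTrack],
    genes: Sequence[GeneModel],
    path: str,
    read_length: int = 20,
    mapq: int = 60,
) -> str:
    """Emit a sorted, indexed BAM realizing the tracks' 3'-end counts.

    Each count at gene-relative base i becomes one single-end read on the
    gene strand whose 3'-most base sits at that genomic position. Used to
    exercise the BAM-reading path end to end.
    """
    import pysam

    chrom_len = max(g.end for g in genes) + read_length + GENE_GAP
    chroms = sorted({g.chrom for g in genes})
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": chrom_len} for c in chroms],
    }
    records = []
    serial = 0
    for gene in genes:
        track = tracks[gene.gene_id]
        for rel_idx in np.nonzero(track.counts)[0]:
            g = gene.rel_to_genomic(int(rel_idx) + 1)
            for _ in range(int(track.counts[rel_idx])):
                a = pysam.AlignedSegment()
                a.query_name = f"r{serial}"
                serial += 1
                a.query_sequence = "A" * read_length
                a.query_qualities = pysam.qualitystring_to_array("I" * read_length)
                a.mapping_quality = mapq
                a.cigar = [(0, read_length)]
                a.reference_id = chroms.index(gene.chrom)
                if gene.strand == "+":
                    a.reference_start = max(0, g - read_length + 1)
                    a.flag = 0
                else:
                    a.reference_start = g
                    a.flag = 16
                records.append(a)
    records.sort(key=lambda a: (a.reference_id, a.reference_start))
    with pysam.AlignmentFile(path, "wb", header=header) as out:
        for a in records:
            out.write(a)
    pysam.index(path)
    return path
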