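# elongrate

Inference of RNA Pol II transcription elongation rates from drug-block
nascent-RNA sequencing (Pro-seq/Gro-seq). When transcription initiation is
blocked (e.g. with DRB), each gene develops a read-depleted 5' region whose
extent marks how far already-engaged polymerases travelled during the block.
`elongrate` locates that depleted/intact transition point per gene with a
two-stage least-sum-of-squares (LSS) change-point scan over normalized
treatment/reference coverage ratios, and converts the distance into a rate
(bp/min).

## What's inside

- **`elongrate.genomic_io`** — BED6/BED12/GTF gene models, strand-aware
  per-base read-end counting from indexed BAMs (MAPQ filter, 3'/5'/overlap
  conventions, paired-end fragments), FPKM, and length/expression gene
  filters.
- **`elongrate.lss`** — the core method: per-bin and per-base normalized
  ratio profiles, the SS split scan (contiguous 2-cluster k-means
  objective), one-sided Mann-Whitney significance with a per-gene
  selection correction and BH adjustment across genes, bin→base two-stage
  refinement, and `calrate` orchestration.
- **`elongrate.hmm`** — the comparison baseline: a 2-state Gaussian HMM
  (Baum-Welch + Viterbi) run inside the same bin-expansion framework.
- **`elongrate.assistant`** — pause index, metagene compression with
  99%-quantile capping, GC content, k-mer enrichment between gene sets,
  exon density, rate-quantile gene clustering.
- **`elongrate.simulate`** — fully synthetic Poisson benchmark datasets
  (parameters: distance, difference, depth, window_num), the ≤50 bp
  accuracy criterion, negative-control false-positive rates, and parameter
  sweeps; can realize datasets as BAMs for end-to-end testing.
- **`elongrate.cli`** — `rate`, `pause`, `metagene`, `structure`,
  `simulate`, `evaluate` subcommands; every run writes a JSON manifest.

## CLI quick start

```sh
# infer rates from a treatment/reference BAM pair (15-min block)
elongrate rate --treatment drb15.bam --reference untreated.bam \
    --genes genes.bed --time 15 --out rates.tsv

# HMM baseline on the same inputs
elongrate rate --treatment drb15.bam --reference untreated.bam \
    --genes genes.bed --time 15 --method hmm --out rates_hmm.tsv

# pause indices / metagene matrix
elongrate pause --bam untreated.bam --genes genes.bed --out pause.tsv
elongrate metagene --bam untreated.bam --genes genes.bed \
    --target-length 2000 --cap-quantile 0.99 --out metagene.tsv

# gene structure (GC, exon density; k-mer ratios between rate quantiles)
elongrate structure --fasta genome.fa --genes genes.bed \
    --rates rates.tsv --kmer 6 --out structure.tsv

# synthetic benchmark round trip
elongrate simulate --n-genes 150 --difference 0.02 --seed 1 --out-prefix sim
elongrate evaluate --calls sim.calls.tsv --truth sim.truth.tsv --out report.json
```

Output tables are tab-separated; the transition-call table carries one row
per tested gene (`transition_bin`, `transition_base`, bin/base p- and
q-values, `significant`, `rate_bp_per_min`, `reference_fpkm`).

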