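# isomirpe

Paired-end-aware isomiR simulation, calling and benchmarking.

## The problem

Mature microRNAs appear in small RNA-seq data as families of sequence
variants — **isomiRs** — arising from imprecise Drosha/Dicer processing
(templated 5'/3' length variants), non-templated 3' tailing, and internal
editing. Because miRNA inserts (16–28 nt) are much shorter than a 50 nt
Illumina read, a paired-end run reads every insert twice, once per strand,
and the merged consensus of the two mates cancels most sequencing errors.
Single-read (SR) analyses have no such check: every substitution error in a
read mints an apparent internal-SNV isomiR. This package provides the
machinery to quantify that inflation with full ground-truth control: a
simulator for isomiR populations and error-bearing paired reads, an isomiR
caller with miRTOP classification, the SR/PE comparison machinery, and
pre-ranked class-level enrichment. It is aimed at developers and evaluators
of small RNA-seq isomiR pipelines.

## What it computes

* **Ground truth** — per miRNA, one isoform per variant class
  (`canonical`, `iso_5p`, `iso_3p`, `iso_add3p`, and SNV classes by mature
  position: seed 2–7, central-offset 8, central 9–12, central-supplementary
  13–17, `iso_snv` elsewhere), with random positive integer frequencies
  summing to a fixed per-miRNA copy total.
* **Reads** — 2×50 nt pairs with adapter read-through, per-cycle
  substitution profiles (R2 noisier than R1, early-cycle dip on R1),
  random fragment orientation with reverse-complement pairs discarded.
* **Preprocessing** — cutadapt-style semi-global 3' adapter trimming
  (≤10% edits, ≥3 bp overlap) and fastq-join-style overlap merging
  (≥6 bp overlap; join iff mismatch fraction ≤ *pct_diff*).
* **Calling** — minimum-edit decomposition of each read against anchored
  matures into 5'/3' shifts, non-templated tail and ≤1 SNV; miRTOP variant
  labels, reversible `iso-<len>-<code>` license-plate UIDs, miR.gff3 I/O.
* **Quantification & benchmarking** — sequence×sample matrices indexed
  `miRNA|variant|UID` with four aggregation levels; four analysis modes
  (SR1, SR2, PE_0, PE_8); sensitivity = TP/(TP+FN) and precision =
  TP/(TP+FP) against expected counts; the SR false-positive filter that
  removes SR counts contradicted by the merged-pair consensus.
* **Enrichment** — weighted Kolmogorov–Smirnov enrichment score per isomiR
  class on a CPM log2 fold-change ranking (SR vs PE), with size-matched
  permutation NES/FDR.

## Worked example

```python
from isomirpe import RunConfig, run_experiment

result = run_experiment(RunConfig(seed=1, n_mirnas=30, n_replicates=2))
print(result.snv_family_unique_counts())
```

This simulates 30 miRNAs × 100 copies at 10× coverage, analyzes each
replicate in the four modes and prints the number of unique internal-SNV
sequences per mode:

```
mode    unique SNV seqs  sensitivity  precision
SR2                 351        0.974      0.276
SR1                 263        0.984      0.464
PE_8                238        0.984      0.508
PE_0                116        0.907      1.000
```

Only ~40 of those SNV sequences are real (simulated) isoforms; the rest are
error-minted. Diversity falls monotonically from SR2 (noisiest mate) to
PE_0 (strict merging), and PE_0 trades a little sensitivity for essentially
perfect precision — error-bearing pairs simply fail the 0%-mismatch join.
The `examples/` directory has one short script per capability
(`01_simulate_and_call.py`, `02_mode_comparison.py`,
`03_sr_false_positive_filter.py`, `04_class_enrichment.py`); each prints
the numbers it computes and a line on how to read them.

A thin CLI mirrors the library (`isomirpe simulate | trim | join | call |
matrix | compare | evaluate | gsea | all`); `isomirpe all --outdir OUT`
writes every artifact of a four-mode experiment plus a manifest that fully
determines the run.

## Layout

```
src/isomirpe/
  reference.py    mature/hairpin FASTA, anchoring, synthetic references
  variants.py     ground-truth isoform simulation ("biological variation")
  readsim.py      paired-read simulation with per-cycle error profiles
  preprocess.py   adapter trimming, overlap merging
  caller.py       isomiR calling, miRTOP labels, UIDs, miR.gff3
  quantify.py     matrices, aggregation, mode comparison, SR FP filter
  evaluate.py     sensitivity/precision benchmarking
  enrichment.py   pre-ranked class-set enrichment
  pipeline.py     end-to-end four-mode experiment driver
  cli.py          click subcommands
```

See `docs/methods.md` for the models, conventions and their rationale.
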