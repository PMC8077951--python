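# Methods

This note records the models implemented in `isomirpe`, the conventions and
defaults chosen where the design was open, and what the simulation does and
does not establish about real data.

## Reference model and coordinates

A mature miRNA is anchored inside its precursor hairpin; the up to three
nucleotides of hairpin sequence flanking the mature on each side are the
*templated* bases available to 5'/3' length variants. All coordinates are
0-based half-open internally; 1-based inclusive coordinates appear only in
miR.gff3 serialization. RNA input is normalized to the DNA alphabet (U→T)
at ingestion and all output uses T. Matures occurring in more than one
hairpin (or more than once within one) cannot be anchored unambiguously and
are skipped with a warning rather than assigned by guesswork; an explicit
mature→hairpin map (two-column TSV) sidesteps name-convention drift across
reference releases.

The synthetic reference generator draws i.i.d. uniform hairpins (default
70 nt) and embeds a 22 nt mature at a random offset leaving ≥3 nt of flank
on both sides, redrawing on the (rare) internal repeat that would make the
anchor ambiguous. This reproduces the only geometry the analysis depends on
— a uniquely anchorable mature with usable flanks — and deliberately models
nothing else about real precursors (no secondary structure, no base
composition bias, no miRNA families).

## Ground-truth isoform population ("biological variation")

Per experiment, `n_mirnas` (default 100) matures are sampled uniformly.
For each, the canonical sequence is always retained and each non-canonical
class is independently dropped with probability `p_drop` = 0.2 — some
variant classes are absent for some miRNAs, as in real repertoires. One
isoform is generated per surviving class:

* `iso_5p` / `iso_3p`: a signed shift in {−3…+3}\{0}; positive shifts copy
  templated flank bases, negative shifts trim the mature.
* `iso_add3p`: 1–3 non-templated bases; the first added base is constrained
  to differ from the templated flank continuation, otherwise the sequence
  would *be* a templated length variant and the class label would be
  unfalsifiable.
* SNV classes: position uniform within the class window (seed 2–7,
  central-offset 8, central 9–12, central-supplementary 13–17, `iso_snv`
  at position 1 and ≥18), alternate base uniform over the three options.
  The seed is often quoted as positions 2–8; we follow the miRTOP
  classification, which separates position 8 into its own class, because
  the caller emits miRTOP labels.

Integer frequencies over the retained isoforms are drawn from a symmetric
multinomial and zero cells are repaired by transferring one count from the
largest cell, so every isoform has frequency ≥1 and the per-miRNA total is
exactly `per_mirna_total` = 100 (hence 10,000 copies for 100 miRNAs).
Frequencies are allocated after class dropping so the total is exact.
Sequences within a miRNA are guaranteed distinct (collisions are resampled).

## Read simulation

Each ground-truth copy yields `coverage` = 10 fragments. Each fragment gets
a random orientation with probability 0.5 and reverse-complement-orientation
fragments are discarded as whole pairs, so a frequency-*f* isoform yields
Binomial(10·*f*, 0.5) retained pairs — expected 5 to 500 across the
frequency range 1–100. The discard step is retained (not bypassed)
precisely to reproduce that expected-count geometry; an option disables it
for exactness tests.

Inserts are shorter than the 50 nt read, so R1 reads through the insert
into the 3' adapter (TruSeq small RNA by default) and R2 reads the reverse
complement of the insert followed by the reverse complement of the 5'
adapter; a fixed filler sequence stands in for the remaining library
construct (its content never survives trimming). Substitution errors are
injected per cycle; the `hiseq-like` profile puts R1 at 0.1% mid-read,
rising linearly over the second half to 0.4% at cycle 50, with the first
four cycles elevated 3× (base-caller calibration dip), and R2 at twice the
R1 rate at every cycle. All magnitudes are configurable; they are plausible
parametric stand-ins, not fitted instrument profiles. Indels are not
simulated: at this read length Illumina indel rates are orders of magnitude
below substitution rates and the phenomena under study concern
substitutions and termini. Quality characters are deterministic per cycle
(Q = −10·log10 rate, clamped to [2, 41]), which makes quality-aware
consensus behavior reproducible: consensus outcomes depend only on which
cycles disagree, not on resampled quality noise.

## Preprocessing conventions

**Trimming.** The 3' adapter is located by semi-global alignment with
unit-cost substitutions/insertions/deletions: either the full adapter
matched anywhere in the read, or an adapter prefix running off the read 3'
end. A match is accepted when edits / matched-read-length ≤ 0.10 over ≥3
aligned bases; the best match (lowest error rate, then longest, then
leftmost) sets the cut point and everything from it on is removed. Reads
without an acceptable match are kept unchanged. The error-rate denominator
is the matched read-region length; this equals the adapter-match length
under substitutions and differs only in indel cases. An exact-match fast
path covers error-free reads; the DP runs only on the remainder. Optional
3' quality trimming (running-sum method) precedes adapter search and is off
by default, since the reference pipeline's ordering is not documented.

**Merging.** R2 is reverse-complemented, then all overlap offsets between
an R1 suffix and an R2 prefix are scanned from full containment down to 6 bp.
The chosen overlap minimizes the mismatch fraction, ties going to the longer
overlap — a documented, testable criterion that agrees with the common
squared-distance heuristic on clean data. The pair joins iff the exact
rational mismatch fraction is ≤ `pct_diff` (no rounding; 0% therefore means
literally zero mismatches). Consensus: agreeing positions take the base with
quality max(q1, q2); disagreeing positions take the higher-quality base
(ties → R1) with quality |q1 − q2| floored at 2. Under a 0% threshold every
consensus base is supported by both reads — the error-suppression property
the PE analysis modes rest on.

## Calling

A read is explained against every anchor by enumerating decompositions:
5' shift ∈ [−3, +3] (positive = templated extension, requiring flank),
3' shift likewise, then a non-templated tail of ≤3 bases, then ≤1 internal
substitution. Edit count = |shift5| + |shift3| + tail length + SNV count;
the minimum wins. Two conventions make the decomposition well-defined:

* SNVs are only placed on mature-aligned positions. A mismatch inside a
  templated extension invalidates that decomposition (the read is then
  explained with a non-templated tail instead), so every SNV has a 1-based
  mature coordinate and a positional class.
* A tail whose first base equals the templated continuation is rejected —
  that sequence is a longer templated variant, mirroring the generator's
  constraint.

Ties within an anchor prefer fewer SNVs, then smaller total terminal shift,
then shorter tail (terminal explanations over internal edits — internal
SNV calls are exactly the error-prone category), then a fixed lexical order
for full determinism. An equal best edit count on ≥2 distinct matures is
returned as *ambiguous*; ambiguous and unassignable reads never enter
matrices, and any sequence later claimed by two different (miRNA, variant)
assignments is dropped from the combined matrix and reported. Reads outside
16–28 nt are not called. A 7-mer index over flank-extended matures
prefilters candidate anchors; with ≤1 SNV and ≤3 nt shifts at ≥16 nt a true
hit always shares an exact 7-mer with its anchor window, so the prefilter
is lossless within the caller's limits.

Unique sequences are named `iso-<length>-<code>` with the sequence encoded
in base 36 from its base-4 value (A=0, C=1, G=2, T=3), zero-padded per
length: deterministic, injective and exactly reversible, so the UID→sequence
companion table can always be reconstructed. Calls serialize to a
miRTOP-style miR.gff3 (header pragmas, one feature per unique sequence with
`Read`, `UID`, `Name`, `Parent`, `Variant`, `Expression`; canonical
sequences as `ref_miRNA` with `Variant=NA`; compound variants comma-joined).

## Benchmarking

Expected count per truth isoform = frequency × expected-factor (coverage ×
0.5 under orientation discarding). Per isoform: TP if |obs − exp| ≤
tol·exp, FP if obs > (1+tol)·exp, FN if obs < (1−tol)·exp (including 0).
Observed (miRNA, class, sequence) keys absent from the truth are
*new-generation* isomiRs and by default also count as FP (wrongly assigned
mass), which is what drives precision below 1 in single-read modes.
The tolerance (default 0.2) makes the criterion well-defined under binomial
retention noise; tolerance 0 recovers strict matching and is used in the
error-free acceptance run, which must and does yield sensitivity =
precision = 1.0 in all four modes. A true negative is defined as a
zero-expectation isoform with zero observation — the natural reading that
does not overlap the FN definition — and is structurally zero here because
every simulated isoform has positive frequency.

## The four modes and the false-positive filter

SR1 analyzes trimmed forward reads; SR2 the reverse-complemented trimmed
reverse reads; PE_0 and PE_8 the merged consensus at 0% and 8% mismatch
tolerance (8% admits one mismatch in a typical ~21 bp overlap). The filter
operates at read-pair granularity: a pair whose SR call and merged-pair
call disagree is evidence that the SR count is an artifact, and that count
is removed from the filtered SR matrix; unjoined or uncalled merged reads
carry no evidence and leave their pairs untouched. The filter is applied
against PE_8: under a 0% threshold an error-bearing pair cannot join at
all, so PE_0 never produces the contradicting consensus the rule needs.
The mechanism visible in the per-class report follows from the error
profile: R1 early-cycle errors (seed region) meet a higher-quality R2 base
and are corrected in consensus — flagged; R1 mid-read errors outrank the
noisier R2 and survive consensus — not flagged.

## Ranking and enrichment

Unique sequences present in ≥ `min_samples` samples are ranked by
log2(meanCPM_SR + 1) − log2(meanCPM_PE + 1) (CPM per sample over the
combined SR1/PE_0 matrix; pseudocount 1; deterministic tie-break by row
id). CPM normalization makes the metric invariant to library-size scaling.
This simple normalized fold change deliberately stands in for a full
dispersion-modeling DE fit: the quantity under study is the downstream
class-level enrichment, and externally computed two-column rank files are
accepted as a drop-in.

Each class is one gene set (compound labels form the `mixed` set; the sets
partition the matrix index). The enrichment score is the classic weighted
KS running statistic: hits add |metric|^p (default p = 1, the conventional
weighted setting; p is exposed) normalized over the set, misses subtract
1/(N − N_hits); ES is the signed maximum-magnitude excursion, so
ES ∈ [−1, 1] and the running sum ends at 0. The null is set-label
permutation — random size-matched sets — which is the appropriate null for
a pre-ranked list with no phenotype labels to permute. NES divides ES by
the mean same-sign null magnitude; FDR q follows the standard pooled-null
procedure (fraction of pooled same-sign null NES at least as extreme,
divided by the corresponding fraction of observed NES, clipped at 1);
default 1000 permutations, all seeded. Degenerate all-zero-metric rankings
fall back to unweighted hit increments rather than dividing by zero.

## Problem sizes and determinism

The default experiment — 100 miRNAs, ~740 isoforms, 10,000 copies, 10×
coverage, three replicates, ~150,000 retained pairs, four modes — runs in
well under a minute on one CPU, so the package's own acceptance run uses
the study conditions unreduced; examples use 5–50 miRNAs for readable
output. Every stage consumes a child seed derived from one master seed via
a fixed draw order, so a config plus seed reproduces matrices, ranks and
enrichment results exactly, and the run manifest (versions, config, derived
seeds) fully determines a run.

## What the simulation does and does not show

Passing tests establish that the *analysis machinery* behaves as specified
under a controlled error model: exact recovery without errors, and the
SR-inflation/PE-correction structure with errors. The simulation does not
model ligation bias, PCR duplication, size-selection effects, real
instrument error profiles, miRNA families and cross-mapping, or biological
frequency distributions; conclusions about any particular real dataset
require that dataset. Known limitations: no indel handling anywhere in the
stack (consistent across simulator, trimmer, merger and caller, but real
data contains rare indels); at most one SNV per read by default; ambiguous
multi-anchor reads are discarded rather than fractionally assigned; and
the enrichment FDR is a permutation estimate whose resolution is bounded
by the permutation count.
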