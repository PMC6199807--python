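# Methods

## Overview

`asmbs` analyses targeted bisulfite sequencing of long (~1.3 kbp) PCR
amplicons in which every read spans a whole amplicon and therefore carries
both the methylation state of all its CpGs and the alleles of any internal
SNPs.  The pipeline stages are: read QC and demultiplexing, bisulfite-aware
targeted alignment, conversion QC and de-duplication, allele sorting into
per-haplotype methylation matrices, covariate-adjusted per-CpG testing, and
three stacked logistic smoking classifiers that differ in feature selection
and allele adjustment.  A synthetic cohort/read generator supplies data with
the statistical structure the analysis assumes.

## Coordinates and strand conventions

Genomic coordinates are 1-based inclusive; an amplicon's length is
`end − start + 1`.  For minus-strand amplicons the stored reference sequence
is the amplified strand, while CpG sites are always reported as the
plus-strand position of the CpG's C (for a CG at amplified-strand offset
*i* on a minus-strand target, that position is `end − i − 1`).

## Alignment and calling

Reads and references are compared in three-letter space (C→T collapsed on
the amplified strand).  The aligner is a global affine-gap (Gotoh) dynamic
programme, banded around the length-difference diagonal (default half-width
32; gap of length L costs 6 + L).  An edit-distance prescreen (edlib) ranks
the ≤ 6 candidate references and both orientations before the DP runs; the
prescreen only chooses the candidate — scores, CIGARs, and every methylation
or allele call come from the package's own DP, which is checked against an
unbanded brute-force implementation in the tests.  Reads below 80% identity
are unmapped.

Methylation at a reference CpG is called from the *original* read base
aligned over the C: C = methylated, T = unmethylated, anything else (or a
gap) missing.  CpH cytosines (next base ≠ G) tally conversion: a read passes
QC iff its unconverted CpH fraction is strictly below 5% (reads with no CpH
observations pass vacuously and are only flagged); the per-target conversion
rate is 1 − pooled unconverted fraction over passing reads.

SNP alleles are read from the original base after bisulfite
equivalence-classing on the amplified strand ({C,T} collapse): allele pairs
that merge under the collapse — C/T SNPs on plus-strand amplicons, G/A SNPs
on minus-strand ones — return `unknown` for every read and cannot be used
for sorting.  Indel alleles are not called.

De-duplication keys on (sample, target, start, CIGAR, methylation vector,
allele vector) — deliberately conservative, treating any molecule identical
in all observable respects as a duplicate; a looser start+CIGAR key is
available by flag.  The representative is the first read by identifier.

## Haplotype matrices

Per target, one sorting SNP (the first collapse-surviving non-CpG SNP) sorts
reads into allele groups.  A sample is called heterozygous when the minor
allele has ≥ 2 reads and ≥ 20% of informative reads; heterozygotes
contribute two matrix rows, homozygotes one (unknown-call reads stay in
homozygote rows; minor-allele stragglers and, for heterozygotes, reads
conflicting with their group's consensus at any additional SNP are excluded
and counted).  Rows need ≥ 5 supporting reads ("minimum 5x per haplotype");
targets covered in < 80% of the cohort are dropped (the spec leaves the
fraction open; 0.8 reproduces the starved-target outcome).  Methylation
columns overlapping a known CpG-SNP are masked.  Missing rates are
column-mean imputed *before* the logit transform, matching the stated
processing order.

The smoothed logit is `M = ln(m′/(1−m′))` with `m′ = (m(n−1)+0.5)/n`,
`n` = number of subjects in the analysis set (not per-cell depth; the
alternative reading is exposed as an option).  Natural log: every downstream
test and fit is invariant to the base.  `|M| ≤ ln((n−0.5)/0.5)`, so the
matrix is always finite.

## Statistics

Age, gender and diagnosis are regressed out per CpG (OLS with intercept) and
the residuals are tested: binary covariates by two-tailed Welch t tests,
age by the t statistic of its OLS slope.  The ASM contrast compares ref vs
alt rows of heterozygous samples on those residuals.  BH adjustment is
applied within each target's CpG family by default (the display in the
source analysis is per-target; a pooled mode exists).  Rank-deficient
designs raise an error naming the collinear columns; pipeline entry points
instead drop collinear columns, which small cohorts produce by chance.

## Feature selection (Boruta)

Re-implemented: each iteration appends one independently permuted shadow per
real feature, obtains importances (default: scikit-learn random forest, 40
trees, `min_samples_leaf=2`; the oracle is pluggable and must be a
permutation-invariant ensemble importance with iteration-to-iteration
stochasticity — a deterministic oracle violates the binomial gate's
independence assumption), and scores a hit for features beating the best
shadow.  Hits are tested against Binomial(iters, ½), two-sided with
Bonferroni correction over all features; significant excess confirms,
significant deficit rejects, undecided at the cap (default 30 iterations, a
compute-motivated reduction of the canonical 100; decisions at the panel's
feature counts complete in 12–30 iterations) stays tentative.  Rejected
features leave the matrix, as in the canonical algorithm.  Tentative
features are excluded from models (the stricter reading of "important");
a target with nothing confirmed falls back to its index CpG so the stacked
model always sees all retained targets.

## Prediction models

All three models share one uniform (unstratified) random 1:1 subject split.
Per target, a logistic model is fitted on haplotype rows of the selected
CpGs' residuals — `index`: the index CpG only; `boruta`: Boruta-confirmed
CpGs of the plain residuals; `boruta.adjusted`: Boruta-confirmed CpGs of
residuals that additionally remove the row's allele indicator.  Fits are
Newton/IRLS on a log-likelihood with an L2 term of 1e-4 on internally
standardized slopes (intercept unpenalized) — a numerical guard against
separation in ~77-row fits, verified against an independent optimizer to
1e-6.  Subject-level predictions average a heterozygote's two rows ("the
prediction values were averaged"); training itself uses haplotype rows,
since the averaging is stated among prediction values.  A stacked logistic
model combines the per-target probabilities; subjects missing a target
receive that target's train-set mean prediction.  AUC is the rank-based
Mann–Whitney statistic with ties counted ½, equal by construction to
pairwise concordance.

## Synthetic data generator

`synth` emulates the study conditions: 154 subjects (50/154 smokers, 83/154
patients, ~50% women, age ≈ N(26.6, 6.5²) years), six amplicons with the
study's lengths and CpG counts (44, 114, 19, 85, 73, 17) on synthetic
CG-controlled random sequences, one usable sorting SNP per target
(alt-allele frequency 0.3), one CpG-SNP planted for masking, full-length
reads with dual 5-nt barcodes and U1 flanks, constant Q40 qualities,
negative-binomial molecule counts (~100 per haplotype ≈ 200 reads per
barcode per target), 1% CpH conversion failure, 10⁻⁴ substitution error,
5% exact-copy PCR duplicates, and a depth-starved CACNA1D analogue that the
coverage gate must drop.

Effects are injected on the logit scale so truth and estimates are directly
comparable.  Smoking shifts −1.5 at the index CpG and its two neighbours in
every target; ASM shifts +1.0 on the alt haplotype at the index CpG of the
AHRR and IER3 analogues (the two ASM-positive targets, where ASM was
observed at the reference CpGs).  Two noise sources make the cohort
realistic: per-CpG, per-haplotype beta jitter with concentration 8
(methylation-rate scatter ≈ 0.15 at intermediate levels), and a per-subject
smoking-dose multiplier — max(0, N(1, 0.6)) for smokers,
max(0, N(0, 0.3)) for non-smokers — reflecting pack-year heterogeneity and
residual exposure; with both spreads at zero the model reduces exactly to
`logit(p) = logit(baseline) + smoking_shift·is_smoker + asm_shift·carries_alt`.
Under these conditions the index-CpG model attains a median test AUC near
0.90: the synthetic cohort reproduces the direction and rough spacing of the
three-model comparison rather than the absolute printed operating point —
the two cannot be matched simultaneously, because lowering the AUC level
requires subject-level (dose) noise that is shared across all CpGs and
therefore also erases the relative advantage of multi-CpG selection.

Two sampling routes share one cohort truth: full read-level FASTQ (validates
the sequencing pipeline; used with small geometries in tests to bound
runtime) and direct binomial sampling of the methylation matrix at a fixed
depth (default 30; used for the power, error-control and model-comparison
studies, where read-level detail is irrelevant).  What read-level simulation
does *not* model: PCR amplification bias and kinetics, chimeric reads,
quality-score variation along reads, barcode cross-talk, and linkage
disequilibrium between planted SNPs.  Passing tests therefore demonstrate
correctness of the analysis under the assumed generative structure, not
performance on any real cohort.

## Problem sizes in the test suite

Read-level round trips run on three 260–300 bp targets with 6 subjects at
depth ≈ 8; error control uses 500 null replicates and 100 power replicates
of a 200-CpG target at n = 100, depth 20; the model-ordering study runs the
full n = 154, depth 30 conditions over 50 seeds at the matrix level.  These
sizes are the package's own choices for a fast default suite; every
component scales to study-sized inputs through the same interfaces.

## Known limitations

* The alignment band assumes reads are near-full-length amplicons; heavily
  truncated reads fall below the identity floor rather than aligning
  locally.
* Haplotype resolution uses a single sorting SNP per target; multi-SNP
  phase reconstruction is out of scope (reads conflicting with the
  consensus phase are merely excluded).
* The de-duplication key treats biologically identical molecules as
  duplicates; at very high depth with few CpGs this undercounts distinct
  molecules.
* The 50-seed model comparison shows the expected ordering
  (boruta.adjusted ≥ boruta ≥ index in the median) but the median
  adjusted-vs-index AUC gap is ≈ 0.01, smaller than the single-split gap
  printed for the real cohort; single-split AUC differences at n = 77 have
  a standard error of ≈ 0.05 and are not directly comparable to seed
  medians.
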