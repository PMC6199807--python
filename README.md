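# asmbs

Haplotype-resolved analysis of long bisulfite PCR amplicons: from barcoded
long reads to allele-specific methylation (ASM) statistics and stacked
methylation-based smoking prediction.

## The problem

Targeted bisulfite sequencing of ~1.3 kbp amplicons on a long-read platform
captures, on a single molecule, both dozens of CpG methylation states and the
alleles of nearby SNPs.  That makes it possible to (i) quantify methylation
per *haplotype* rather than per sample, (ii) detect ASM — systematic
methylation differences between the two alleles at a locus — and (iii) ask
whether accounting for allele effects improves a methylation biomarker.  The
package implements that full analysis for a panel of six smoking-associated
amplicons (*AHRR*, *ALPPL2*, *IER3*, *GNG12*, *GFI1*, *CACNA1D*; hg19
coordinates ship as a packaged registry), together with a synthetic cohort
and read generator that stands in for patient data.

## What it does

* **Read processing** — mean-Q30 quality gate, exact-match dual 5-nt barcode
  demultiplexing (8 x 12 codes = 96 combinations per library), U1-primer
  flank trimming with strand normalisation.
* **Bisulfite-aware alignment** — banded affine-gap global alignment of
  C→T-converted reads against converted amplicon references; per-CpG
  methylation calls from the original base over each reference CpG; per-SNP
  allele calls after bisulfite equivalence-classing ({C,T} on the amplified
  strand, which is why C>T plus-strand and G>A minus-strand SNPs are
  uninformative); CpH-based conversion QC (reads with unconverted CpH ≥ 5%
  are discarded; per-target conversion rate reported) and conservative
  de-duplication.
* **Haplotype methylation matrices** — reads sorted by the allele at each
  target's sorting SNP; per-(sample, allele) methylation rates with a
  minimum 5x depth gate, starved-target drop, CpG-SNP masking, column-mean
  imputation and the smoothed logit transform
  `M = ln(m'/(1−m'))`, `m' = (m(n−1)+0.5)/n` with `n` the analysis-set size.
* **Statistics** — per-CpG two-tailed Welch t tests of smoking, gender,
  diagnosis and the ASM (allele) contrast on covariate residuals, with
  Benjamini–Hochberg adjustment within each target.
* **Prediction** — three stacked logistic smoking classifiers sharing one
  random 1:1 train/test split: `index` (one EWAS index CpG per target),
  `boruta` (per-target CpGs confirmed by a re-implemented Boruta
  shadow-feature selector over random-forest importances) and
  `boruta.adjusted` (as `boruta`, with the haplotype allele additionally
  regressed out).  Heterozygotes' two haplotype predictions are averaged;
  per-target probabilities feed a stacked logistic combiner; performance is
  test-set ROC/AUC (rank-based, ties = 1/2).

## Worked example

```python
from asmbs import synth, haplo, models

targets = [t for t in synth.synthetic_registry(0) if t.gene_label != "CACNA1D"]
cfg = synth.study_conditions(targets, seed=0)   # 154 subjects, 50/154 smokers
subjects = synth.simulate_cohort(cfg, targets)
cov = synth.covariate_frame(subjects)

mat = synth.sample_haplo_matrix(subjects, targets, depth=30, seed=0)
mat, _ = haplo.apply_depth_filter(mat)           # minimum 5x per haplotype
mat = haplo.mask_cpg_snps(mat, targets)
mat = haplo.impute_missing(mat)

reports = models.evaluate_three_models(mat, cov, targets, seed=0)
for name, rep in reports.items():
    print(f"{name:16s} test AUC = {rep.auc:.3f}")
```

prints (seed 0):

```
index            test AUC = 0.912
boruta           test AUC = 0.908
boruta.adjusted  test AUC = 0.915
```

i.e. on this synthetic cohort the index-CpG model is already a strong smoking
classifier and the allele-adjusted Boruta model edges it out.  Single-seed
AUCs on a 77-subject test set carry a standard error of roughly 0.05, so
model comparisons should always be read across many seeds (see
`scripts/acceptance.py` and the acceptance tests, which use seed medians).

The same run end to end from reads (simulation → FASTQ → demultiplex → align
→ QC → matrices → statistics → models) is available as
`asmbs run --seed 0 --n-subjects 20 --depth 30 --out myrun` or
`asmbs.pipeline.run_pipeline(...)`; it writes per-stage counters, a QC
manifest, SAM output, matrix/statistics TSVs and the model report.

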