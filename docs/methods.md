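# Methods

This note records the statistical models the package implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that matter for
reproducing results.

## Polygenic scores

Discovery GWAS effects are harmonized to the target cohort's counted (ALT)
allele by variant id. Indels and non-ACGT codes are dropped, strand-ambiguous
pairs (A/T, C/G) are dropped before any matching because their strand cannot
be resolved, reverse-strand matches are complemented, and allele-swapped
matches have their effect negated. Each overlapping variant carries a
provenance flag (`match`, `flipped_strand`, `swapped_alleles`,
`removed_ambiguous`, `removed_mismatch`) so every filter is auditable.

Clumping is greedy by ascending P: the most significant remaining variant
becomes an index and removes every variant on the same chromosome within the
window (default 500 kb) whose squared dosage correlation with it reaches the
r² threshold (default 0.1). r² is computed on the target cohort's own
dosages — no external LD reference — and ties in P break toward the smaller
(chromosome, position). Zero-variance dosage columns are treated as r² = 0
with a warning rather than an error, so monomorphic-in-sample variants never
abort a run.

The score is the raw weighted sum `Σ_v dosage(i,v) · β(v)` over clumped
variants with `P(v) < t`, strict inequality, for each threshold in the scan
(default 0.001, 0.01, 0.05, 0.1, 0.2, 0.5, 1; the 0.001 rung is included so
threshold scans cover the finest published granularity). Scores are left
unstandardized: every transmission statistic downstream is invariant to
positive affine transforms of a score column, so standardization would be a
no-op with extra code.

## pTDT

For trio `i` with child score `c_i` and parent scores `f_i`, `m_i`:

    dev_i = (c_i − (f_i + m_i)/2) / SD({(f+m)/2}),

with the mid-parent SD taken over the analysis set with the n−1 denominator.
Under Mendelian transmission and no ascertainment the deviations are
symmetric about 0; a one-sample t-test of mean 0 detects systematic
over-transmission. The mid-parent SD is computed over whichever trio set is
passed in; the pipeline computes deviations once over the full cohort so
that subgroup tests share a common scale (this is configurable by passing a
subgroup-only trio set).

Sidedness: the default report uses the two-sided one-sample t-test, with the
one-sided (toward over-transmission) p always reported alongside and a
`--one-sided` switch in the CLI. Zero-variance deviation vectors return
p = 1 by convention so batch runs never crash on degenerate columns.

Per trait, the working threshold is the one whose whole-sample mean
deviation is largest, ties toward the smaller threshold.

The subgroup permutation null shuffles diagnosis labels over trios with the
subgroup size fixed; p uses the add-one estimator
`(1 + #{perm mean ≥ observed}) / (n_perm + 1)`, one-sided toward
over-transmission, so p = 0 is impossible. An `exact=True` mode enumerates
all C(n, k) assignments for small cohorts.

Auxiliary tests (two-sample Welch t, paired t across trait means,
Shapiro–Wilk, Spearman, Benjamini–Hochberg step-up FDR) use their standard
definitions via scipy/statsmodels.

## Deviation clustering

Trios are clustered on their deviation profiles (one standardized column per
trait, already on a common scale, so distances are plain Euclidean with no
re-scaling) using Ward's minimum-variance linkage. The cluster count is
chosen by majority vote of three internal validity indices evaluated over
k = 2…6: connectivity (neighborhood size 10, lower better), mean silhouette
width (higher better), and the Dunn index (higher better); ties go to the
smaller k, and k-means can be added to the vote as a second method for the
audit table. Only Ward and k-means are implemented: the published
model-comparison step surveyed additional algorithms (SOM, SOTA,
model-based), but the retained method was Ward, and re-implementing the
others adds surface without touching any downstream result.

Silhouette uses `s(i) = (b−a)/max(a,b)`; for a singleton cluster `a(i)` is
defined as 0. A zero maximum intra-cluster diameter maps the Dunn index to
the finite sentinel 1e12 instead of infinity. Observations with negative
silhouette width are removed ("pruning"), and subgroup enrichment in a
cluster is tested with Fisher's exact test using the minimum-likelihood
two-sided rule. The reported interval is the exact conditional (noncentral
hypergeometric) CI obtained by inverting the tail probabilities, and both
the sample odds ratio `ad/bc` and the conditional MLE are reported, since
published tables may print either.

## Imputed expression

Individual-level prediction is `expr(i,g) = Σ_v w(g,v) · dosage(i,v)` with
model alleles harmonized exactly like GWAS effects; genes that lose all
their variants to harmonization are absent from the matrix, never
zero-filled. Per-gene association with subgroup status is a logistic
regression of label on predicted expression, standardized over the analyzed
children first so Wald Z values are comparable across genes. The fit is
IRLS, at most 50 iterations, tolerance 1e-8 on the coefficient step;
separation is declared when the standardized slope exceeds 15 in absolute
value, and separated, non-converged, or zero-variance genes are excluded
with logged reasons.

The summary-level statistic is

    Z(g) = Σ_v w(g,v) · (σ_v / σ_g) · (β_v / se_v),   σ_g² = wᵀ Σ w,

with variant SDs and the covariance Σ taken from a reference dosage panel —
in this package the analysis cohort itself, a self-contained desk-scale
substitute for an external eQTL-panel covariance. Genes with σ_g = 0 or
with no model variant in the statistics are dropped.

Cross-disorder correlation restricts the shared gene universe to genes with
summary-profile p below each cutoff in {1, 0.5, 0.1, 0.05, 0.01, 0.001} and
reports Spearman rho with its p; sets smaller than `min_genes` (default 10)
are emitted without a rho and a recorded reason, so grids never silently
skip rows.

## The synthetic cohort generator

The generator produces data with the structure the analysis assumes, at
desk scale, with known ground truth. What it emulates:

* **LD-blocked haplotypes.** Variants are laid out in blocks (1 kb spacing
  within, 10 Mb gaps between); within a block each allele copies the
  previous variant's allele with probability ρ (default 0.8) and is a fresh
  Bernoulli(AF) draw otherwise. First-order correlation therefore equals ρ,
  blocks are independent, and clumping is non-trivial but tractable. Block
  allele frequencies are uniform on [0.05, 0.5]; 5% of variants get
  strand-ambiguous allele pairs so the harmonization filter is exercised.
* **Point-normal GWAS architecture.** One shared uniform draw per variant
  makes causal sets nested across traits; true effects at causal variants
  are jointly normal across traits under a configurable correlation matrix,
  scaled so the true-score variance equals the trait's heritability-like
  fraction h². Observed effects add noise with SE = 1/√(2f(1−f)N) and a
  Wald-test P — the classic standardized-trait approximation.
* **Liability ascertainment.** A child's liability is
  √h²·(standardized true score) + √(1−h²)·N(0,1); an ascertained subgroup
  keeps only trios whose child exceeds the population quantile (default
  0.9), estimated on an internally simulated reference population. This is
  the textbook construction under which risk alleles are over-transmitted
  to selected offspring; rejection sampling is batched with a retry cap
  (default 10,000 expected draws per trio).
* **Sparse eQTL models.** Each gene draws a fixed number of variants within
  one LD block with standard-normal weights; tissues share entries with a
  configurable probability. A "planted" tissue can draw its eQTLs from the
  causal variants of chosen traits, which concentrates cross-disorder
  expression correlation in that tissue — the testable analogue of a
  cortex-versus-lung contrast.

Defaults mirror the target study design: 379 trios with 39 AS / 202 Non_AS
labels (the remainder unlabeled), six psychiatric traits plus a genetically
unrelated control trait, discovery sample sizes at the published scale of
the corresponding consortium GWAS, and AS-restricted ascertainment on the
three comorbid traits reported as over-transmitted. The ascertainment
intensity of the real cohort is unknowable from the publication; the 0.9
default quantile is a free parameter of the generator, not an estimate.

What the generator does **not** emulate: realistic human LD maps and allele
frequency spectra, sex chromosomes, genotyping or imputation error, rare and
de-novo variation, population stratification, or assortative mating.
Passing tests therefore demonstrate correctness of the statistical machinery
and qualitative recoverability of planted structure, not calibration on real
genotypes.

All randomness flows from a single integer seed through a hierarchical
`numpy.random.SeedSequence` split per stage (panel, effects, trios,
weights), so each stage is independently reproducible and whole runs are
byte-identical given the same seed and config.

## Numerical conventions

* Coordinates are 1-based inclusive throughout (PLINK convention).
* Missing dosages are mean-imputed to 2·AF of the variant, logged; the
  pipeline assumes upstream imputation, so missingness should be rare.
* An `OR` column in summary statistics is log-transformed to `BETA` on load.
* Variant tables are canonically ordered by (chromosome, position), making
  loading order-insensitive.
* Threshold comparisons are strict (`p < t`).
* Cluster labels are contiguous from 1 in order of first appearance, so
  Ward output is deterministic for a fixed input.
* p-values from the generator's Wald tests are clipped to [1e-300, 1] to
  keep them in (0, 1].

## Problem sizes used by the test suite

Simulation-based checks run at sizes chosen to give stable pass/fail
behavior at interactive runtimes: null calibration uses 1000 cohorts of 200
trios on a 100-variant panel; power recovery uses 100 seeds of 200+200
trios; summary/individual concordance uses 4000 individuals and a 100-gene
model; the end-to-end planted-structure run uses 15 seeds of 180 trios with
150 variants, two tissues, and 40 genes per tissue; smaller batteries
(20–40 seeds) cover planted-k recovery and the expression tissue contrast.
Statistical assertions use interval or majority criteria sized to these
replicate counts.

## Known limitations

* The exact conditional CI inversion assumes both margins positive; tables
  with a zero margin raise instead of returning a one-sided interval.
* The clumping r² uses the analysis cohort itself; with very small cohorts
  the LD estimates are noisy, as they would be in PLINK on the same data.
* The summary-level expression Z uses the analysis cohort as its LD
  reference; with an external reference panel the approximation error grows
  with LD mismatch, which the package does not model.
* `choose_k`'s vote can select k > 2 on weakly structured data; the
  enrichment test then requires exactly two retained clusters and is
  skipped by the pipeline rather than forced.
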