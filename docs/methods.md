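# Methods

This note documents the models behind each pipeline stage, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical choices that affect results.

## Overview

`gliores` reimplements, at desk scale, the computational chain used to
discover and exploit a chemoradiotherapy-resistance driver in glioblastoma:

1. derive a resistance gene signature from a treated patient cohort and a
   treated cell-line panel, and intersect the two;
2. score single-cell clusters for copy-number burden (tumor calling) and for
   driver expression / signature enrichment (subcluster classification);
3. project subcluster identities onto spatial transcriptomics spots and ask
   which anatomical regions the resistant subclusters occupy;
4. screen a drug panel for selective potency in high-driver cell lines and
   quantify drug-radiation synergy with the ZIP model;
5. support the surrounding assays: limiting-dilution stem-cell frequency,
   IHC H-scores, subtype calling, Kaplan-Meier / log-rank comparisons.

All inputs can be generated synthetically with planted ground truth, so
every stage is testable end-to-end without external downloads.

## Cohort stratification and signature derivation

**Survival split.** Only deceased, chemoradiotherapy-treated samples enter
the split. The default rule labels samples below the median survival time
"resistant" and the rest "sensitive"; a quantile parameter generalizes the
cutoff. Samples exactly at the cutoff go to the sensitive side so the split
is deterministic. Resistant = shorter survival, because resistance to
therapy manifests as poorer prognosis in a uniformly treated, uniformly
deceased stratum.

**Apoptosis split.** A cell line is "resistant" when no treated condition
(radiation or temozolomide) shows a significant apoptosis increase over its
own control — a two-sided two-sample t-test on replicate fractions at
`alpha` (default 0.05), requiring the treated mean to exceed control. The
significance rule mirrors how such panels are annotated (stars vs "ns"); a
magnitude-threshold alternative would be less portable across lines with
different baseline apoptosis.

**Differential expression.** On log-scale expression, log2FC is the
difference of group means. The default test is Welch's t (unequal
variances); a variance-moderated alternative shrinks per-gene pooled
variances toward an empirical-Bayes prior (scaled-F moments matched via
digamma/trigamma inversion) and adds the prior degrees of freedom to the
t reference distribution. Multiplicity is handled with Benjamini-Hochberg
over all tested genes; genes with zero variance in both groups are dropped
and logged. Volcano filtering keeps genes with |log2FC| >= `lfc_min`
(default 0.5) in the requested direction and raw p <= `p_max` (default
0.05), with inclusive boundaries. Signature intersection is a plain set
intersection; directions must agree.

**Enrichment.** The preranked enrichment score is the classic weighted
Kolmogorov-Smirnov running sum (hit steps weighted by |statistic|), with a
permutation p-value from random same-size gene sets and the +1
small-sample correction.

## Single-cell CNV inference

Counts are log-normalized (per-cell scaling to 10,000 followed by
log2(x+1)). Genes whose mean log expression across the fitted cells is at
or below the expression cutoff (default 0, i.e. only unexpressed genes are
dropped) are removed. Each gene is centered on the mean of the designated
reference (non-tumor) cells, smoothed with a centered moving average of
`window` genes (default 101) strictly within each chromosome — windows
shrink with a warning when a chromosome has fewer genes — then each cell's
profile is re-standardized by subtracting its own median, clipped to
[-1, +1], and entries with magnitude below the noise filter (default 0.2)
are zeroed. Two invariants therefore hold for *any* input: every entry has
|v| <= 1, and every nonzero entry has |v| >= 0.2.

The per-cell **CNV score** is the quadratic summation of the profile
(sum of squared entries); a segment-level variant (mean per contiguous
nonzero run, then sum of squares) is available, since the granularity of
"regions" in a quadratic summation is a free choice. Cells are called CNV+
when their score exceeds the 95th percentile of the reference-cell scores
(deterministic and interpretable); a two-component 1-D clustering rule is
exposed as an alternative.

The median re-standardization has a useful side effect: a focal gain
inflates a cell's library size and thereby deflates all off-segment genes
after normalization; subtracting the per-cell median (an off-segment
statistic) restores the on-segment value to approximately the true log
gain.

## Subcluster classification

Clusters are scored on two axes: the arithmetic mean of the driver gene's
log-normalized expression, and a signature score (per-gene z-scores across
all cells, averaged over signature genes, then averaged within cluster —
chosen over a running-sum statistic for transparency at cluster
granularity; the preranked score remains available).

The **mean±SEM grouping** classifies cluster-level values: high if
v > mean + SEM, low if v < mean − SEM, intermediate otherwise, with SEM =
sample SD of the cluster values divided by √k (k = number of clusters).
Inequalities are strict, so boundary clusters — including every cluster
when the values are constant — are intermediate. SEM is computed across
cluster-level values, matching the granularity at which the grouping is
displayed and used; a per-cell SEM would collapse the intermediate band.
The grouping is equivariant under positive affine transforms away from
exact boundaries.

Marker detection is one-vs-rest and positive-only: genes detected in at
least `min_frac` (default 0.25) of in-cluster cells with log2 mean
difference >= 0.5, ranked by Wilcoxon rank-sum p with BH correction within
cluster. Clusters with fewer than 3 cells are skipped.

## Spatial projection

Anchor-based label transfer is replaced by a dependency-free surrogate with
the same output contract: spatial clusters (or single spots) are
decomposed as nonnegative mixtures of single-cell subcluster centroids on
the top-dispersion shared genes. Both sides are z-scored **with their own
per-gene statistics** — this removes platform- and depth-specific scale so
the mixture is solved in comparable units. Because centered centroids are
collinear (they sum to ~0 across subclusters), plain NNLS is degenerate
along the all-positive direction; a soft sum-to-one row (weighted by the
mean centroid norm) pins the mixture scale. Weights are then normalized
exactly, giving prediction-score rows that are nonnegative and sum to 1.

Region enrichment sums each group's subcluster prediction scores per spot,
averages within anatomical region (CT/IT/LE/MP/PSEU), and z-normalizes
across regions for comparability; raw means are also returned. Constant
group scores map to all-zero enrichment, and a single region is an error
(z undefined).

## Pharmacology

Inhibition follows the four-parameter log-logistic model
y(d) = L + (U−L)·d^h/(d^h + m^h) on a percentage scale, fitted by bounded
trust-region least squares with five seeded starts (best RSS wins); flat
responses and non-convergence return flagged results rather than raising.
IC50 solves y(d) = 50 in closed form and is undefined (None) when U <= 50.

The **differential-IC50 screen** reuses the mean±SEM grouping on driver
expression across cell lines, drops intermediate lines, and per drug runs
Welch's t on log10 IC50 between high- and low-driver groups with BH
correction. A drug is flagged driver-sensitive only when the high-driver
group has the *lower* IC50 and p < alpha; drugs with undefined IC50 in
more than half the lines are dropped. A blood-brain-barrier flag then
restricts hits to drugs that can reach the tumor.

**ZIP synergy.** Monotherapy margins (the B=0 row and A=0 column) are
fitted as log-logistic curves; the zero-interaction expectation at positive
doses (a, b) is y_A + y_B − y_A·y_B; delta = observed − expected in
percentage points, and the summary score is the mean delta over all
strictly-positive dose pairs. The full-formulation option `refit_margins`
additionally refits curves along each row and column and averages them as
a smoothed response surface. The default compares raw observed
combinations against the margin expectation: it is unbiased under the
Bliss null, transparent, and its residual variance is dominated by the
irreducible observation noise of a single-replicate grid. Radiation dose
(Gy) is treated as a concentration-like axis. The optimal combination
maximizes delta among combos reaching `min_inhibition` (default 50%)
observed inhibition, breaking ties toward the lower partner-drug dose and
then the lower primary dose (a minimal-toxicity preference); if nothing
qualifies the best-available pair is returned with a warning flag.

## Assay statistics

**Limiting dilution (ELDA-style).** The single-hit Poisson model
P(respond | x cells) = 1 − exp(−f·x) is fitted as a binomial GLM with a
complementary log-log link and offset log(x); f̂ = exp(intercept) with a
Wald 95% CI on log f (profile-likelihood CI available). Dose-0 rows are
consistency-checked (0 responders required) and excluded. All-negative
plates return f̂ = 0 with a one-sided exact upper bound
(−ln 0.05 / Σ x·n); all-positive plates return f̂ = 1 with a lower bound
solved from the exact likelihood; both carry a boundary flag. Group
comparison is a 1-df likelihood-ratio test of a pooled frequency against
separate frequencies.

**H-score.** 100·weak + 200·moderate + 300·strong area fractions;
linear, bounded in [0, 300].

**Subtype calling.** Markers are z-scored across samples; a sample is MES
when its mean mesenchymal-marker z (CD44, YKL40) exceeds its mean
proneural-marker z (SOX2, OLIG2), ties going to PN (arbitrary but
deterministic, flagged).

**Survival.** Kaplan-Meier curves come from lifelines; the log-rank
chi-square is computed directly (hypergeometric variance with simultaneous
risk-set accounting for ties) — it matches lifelines' statistic to
floating-point precision and is fast enough for calibration studies at
10,000 simulations.

## Synthetic data: what it emulates, and what it does not

The generators draw every randomness stream from one seeded generator per
call (no global state) and are bit-reproducible given (parameters, seed).
Sizes below are the package defaults; they were chosen so the full pipeline
runs in seconds while every planted effect is comfortably detectable.

- **Bulk cohort** (default 200 samples, 600 genes): log-scale Gaussian
  baselines (log-normal expression) with mean 7, gene-level SD 1, residual
  SD 0.3. Dead, chemoradiotherapy-treated samples split 50/50 into latent
  resistant/sensitive groups; 12 planted resistance genes (the driver
  among them) gain +1.0 log2 in resistant samples. Survival is exponential
  with group medians 4 vs 40 months. The wide hazard ratio is deliberate:
  the pipeline re-derives groups from a median-survival split, and group
  misclassification attenuates the observed fold change (at these medians
  ~16% of samples are mislabeled, attenuating planted log2FC 1.0 to ~0.67,
  still above the 0.5 volcano threshold). Real cohorts have weaker
  survival separation and would need larger effects or samples.
- **Cell-line panel** (default 20 lines, 30 drugs): high-driver lines carry
  the planted signature; treatment-induced apoptosis is blunted in
  high-driver lines (coupling parameter; 0 decouples it), and planted
  driver-sensitive drugs have a 4-fold lower IC50 in high-driver lines.
  Viability grids are log-logistic in percent with Gaussian noise (SD 2).
- **Single-cell counts** (default 400 cells, 600 genes): negative binomial
  (gamma-Poisson, dispersion 0.3) around cluster profiles, six equal-sized
  chromosomes, tumor clusters carrying multiplicative 2^gain shifts on
  contiguous gene blocks (defaults: a ~1.5x gain block and a 0.67x loss
  block). Doublets, ambient RNA and batch effects are *not* simulated.
- **Spatial spots** (default 200): noisy mixtures of log-scale cluster
  profiles, each spot dominated (85%) by one cluster; spots dominated by
  the resistant cluster are placed in MP/PSEU regions, others in
  CT/IT/LE. No spot geometry beyond mixture weights.
- **Dose matrices**: the printed grids (0/4/8/12/16 Gy x 0/1/2/5/10/15 µM);
  combination inhibition = clamp(Bliss + magnitude·[both > 0], 0, 1) as a
  percentage plus truncated Gaussian noise. Default monotherapy curves are
  h = 2 with midpoints 5 Gy and 2.5 µM, i.e. both margins traverse their
  full response range within the grids (a potent partner drug, consistent
  with an optimal combination at a low partner dose). Near-saturating
  Bliss surfaces clamp part of a planted deviation, so recovered summary
  scores under-estimate large planted magnitudes while preserving their
  ordering.
- **Dilution plates**: independent wells responding with probability
  1 − (1−f)^x at the standard densities (0, 1, 5, 10, 20, 50 cells x 16
  wells).

Because these are surrogates, passing tests demonstrate the *operations*
are correct and the chain is recoverable under controlled conditions; they
do not certify performance on real cohorts with batch structure, censoring,
or platform effects.

## Numerical choices and degenerate inputs

- Strict inequalities at all mean±SEM boundaries; ties in the survival
  split go to sensitive; subtype ties go to PN. All three are arbitrary
  but documented and deterministic.
- CNV window shrinks to the largest odd width available on a short
  chromosome (warning logged); windows of 1 disable smoothing.
- Log-logistic fitting brackets the midpoint within [min positive dose/10,
  max dose x 10] in log space and the slope within [1e-3, 20].
- The ELDA GLM uses tight IRLS tolerances (1e-10) so the saturated
  single-row case matches the closed form to 1e-6.
- Report JSON is sorted and rounded only where stated; reports are
  byte-reproducible for a fixed config and seed (no timestamps).
- Master seeds spawn independent per-stage streams via SeedSequence; all
  derived seeds stay below 2^31.

## Problem sizes

Default test-suite problem sizes (cells, genes, samples, simulation
counts) are set so the whole suite runs in about a minute on one CPU while
keeping every calibration check at its stated scale (e.g. 1,000 CI-coverage
simulations, 10,000 log-rank null simulations, 100 fuzzed CNV datasets,
50 Bliss-null grids). These sizes are the package's own defaults, not
statements about any external dataset.

## Known limitations

- The moderated-t prior estimation uses moment matching, not the exact
  marginal likelihood; at very small gene counts the prior df estimate is
  noisy (the Welch default is unaffected).
- The NNLS-mixture label transfer is a surrogate for anchor-based
  integration: it assumes spatial spots are approximately linear mixtures
  of subcluster centroids in z-space and has no batch-anchor correction.
- The ZIP summary on a single-replicate 5x6 grid has an irreducible
  noise floor (~0.5 percentage points SD at noise SD 2); distinguishing
  planted deviations below ~1 point needs replicate grids.
- Boundary ELDA plates (all or none responding) return one-sided bounds;
  the point estimate is reported at the boundary and flagged rather than
  omitted.
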