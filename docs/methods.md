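# Methods

## Overview

`dimex` analyzes how gene expression relates to PTSD symptom burden measured
with the 17-item PTSD Checklist (PCL-17): the total score and its four
subdimensions (re-experiencing, avoidance, numbing, hyperarousal).  Because
symptom-expression relationships need not be monotone, every differential
test is built on a penalized spline: the phenotype enters each model as a
smooth function whose complexity is chosen by the data, and the effective
degrees of freedom (edf) of that smooth quantify nonlinearity.  The analysis
runs at three molecular levels — gene counts, isoform abundances, and
alternative-splicing (AS) events — and finishes with post-hoc clustering of
fitted smooths, cross-dimension comparison, and preranked gene-set
enrichment.

## Count model (genes)

For gene *g* and subject *i* with library-size factor *s_i*:

    log E[y_gi] = log s_i + beta_0g + f_g(pheno_i) + c_i' gamma_g

with a negative-binomial likelihood, Var(y) = mu + alpha_g mu^2.  The
covariate vector *c* carries age, race, five immune-cell proportions (CD4T,
CD8T, monocytes, NK, B) and surrogate variables; covariates are standardized
internally (this only relabels coefficients).

**Smooth term.** `f` is a P-spline: cubic B-splines on evenly spaced knots
extending past the observed phenotype range (Eilers–Marx layout), 10 basis
functions by default, a second-order difference penalty, and a sum-to-zero
constraint that separates the smooth from the intercept.  The penalty null
space is then exactly the linear functions, so an infinitely penalized fit
is a straight line with edf = 1 — the property the nonlinearity call
(significant and edf > 1.5) relies on.  The clamped-knot alternative was
rejected after simulation: repeated boundary knots give the basis extra
flexibility at the phenotype extremes and inflate spurious wiggle at
leverage points.  For discrete phenotypes with fewer distinct levels than
basis functions (the two-item avoidance subscale), the basis shrinks to
(levels − 1) functions automatically.

**Smoothing selection.** The smoothing parameter is selected per gene by
Laplace-approximate REML, evaluated on a fixed 25-point log-spaced grid
(lambda from e^-6 to e^18 on a penalty normalized to unit spectral norm);
the grid form lets thousands of genes be fitted simultaneously with batched
linear algebra.  On top of the grid minimum a parsimony rule applies
(`SmoothSpec.score_margin`, default 1.0): among grid points whose REML score
lies within one unit (−2 log-likelihood scale) of the minimum, the largest
smoothing parameter is chosen.  This is the regularization-path analog of
the one-standard-error rule.  Without it, REML near-ties between a straight
line and a noise-driven wiggle break toward the wiggle for roughly one in
five truly linear strong effects (reference GAM implementations behave the
same way), which would blunt the edf-based nonlinearity call; with it,
planted linear effects are classified as linear ~96% of the time while
planted nonlinear effects retain edf > 1.5 in ≥ 99% of significant calls.

**Dispersion.** Per gene, alpha is estimated from Pearson residuals of a
pilot fit by solving sum((y−mu)^2 / (mu(1+alpha mu))) = n − edf_total
(bisection on log alpha); subtracting the model's effective degrees of
freedom removes the downward bias a plug-in estimator would have.  Estimates
are then moderated toward a log-linear mean–dispersion trend with weight
0.5, *upward only*: genes below the trend are pulled toward it, genes above
the trend keep their own estimate.  Symmetric shrinkage was rejected after
null-calibration simulations: pulling above-trend dispersions down
understates variance for exactly the genes where that matters and inflated
the null p < 0.05 rate to 0.07–0.08; with one-sided moderation the rate
tracks the known-dispersion oracle (≈ 0.05).  A gene-wise profile-ML
estimator is retained in the code for reference.

**Test and edf.** The hypothesis f ≡ 0 is tested with a Wald-type statistic
on the smooth coefficients using a rank-r pseudo-inverse of their Bayesian
covariance, r tied to the smooth's edf (fractional part as a partial weight
on the next eigen-direction), against chi-squared with edf degrees of
freedom.  edf is the trace of the smooth block of the influence matrix.
Under the global null with the full pipeline (estimated size factors,
estimated dispersion, 200 subjects, 2000 genes) the fraction of p < 0.05 is
0.04–0.06 across seeds and Benjamini–Hochberg at FDR 0.05 yields zero
discoveries in ≥ 18 of 20 seeds.

**Normalization.** Median-of-ratios size factors (per sample: median over
all-sample-expressed genes of count / gene geometric mean), rescaled to
geometric mean one.  Genes with mean raw count below 5 are filtered first.

## Continuous model (isoforms and AS events)

Isoform abundances are analyzed as log(TPM+1); AS events as logit-PSI.  PSI
of an event is sum(TPM of inclusion transcripts) / sum(TPM of all its
transcripts), set to missing when the denominator falls below 1 TPM, clipped
to [0.01, 0.99] before the natural-log odds transform.  The same penalized
spline applies with a Gaussian likelihood: profiled Gaussian REML for the
smoothing parameter (same grid and parsimony margin), residual variance
estimated per feature, and an F-type test with denominator df = n −
total edf.  Missing samples are dropped per feature via zero weights;
features usable in fewer than 80% of samples, or with zero variance, are
excluded and reported with missing p.  On Gaussian null features the
p-values are uniform (KS test non-rejecting); on PSI computed from the
synthetic event TPMs the null p < 0.05 rate is ≈ 0.06 because PSI is a
within-event ratio and immune to normalization.

## Post-hoc clustering of smooths

Fitted smooths of significant nonlinear genes are evaluated on a common
100-point grid, centered (not variance-scaled: amplitude is meaningful;
scaling is exposed as an option), and clustered with PAM k-medoids
(greedy BUILD, best-improvement SWAP) under Euclidean distance.  The number
of clusters comes from the gap statistic with uniform reference draws in
the principal-component-aligned bounding box (Tibshirani's method B, 50
reference draws).  The selection rule is the *globalSEmax* variant: the
smallest k whose gap lies within one standard error of the global gap
maximum.  The textbook stop ("smallest k with Gap(k) ≥ Gap(k+1) − s")
and its first-local-maximum refinement were both rejected empirically:
for well-separated equal-size curve families the gap curve dips below zero
at small k before rising to its true peak, and both rules then stop at
k = 1.  With globalSEmax, 70 curves drawn from 5 shape archetypes at 10%
noise recover k = 5 in 20 of 20 seeds (and k = 2 for 2 archetypes).

## Cross-dimension comparison

A feature is *unique* to a dimension when its BH-FDR is below 0.05 there
and its raw p exceeds 0.1 in each of the other three dimensions.  Dimension
similarity is summarized by Pearson correlation of −log10 p (the base is
immaterial for r), with pairwise missing-data exclusion.  Venn region
counts are exclusive and sum to the union of significant sets.  The AS
event-type composition of a significant set is tested against
transcriptome-wide proportions with a chi-square goodness-of-fit test;
categories with expected count below 5 are pooled into one combined
category, smallest expected count first (ties broken alphabetically),
stopping when every category meets the floor or two categories remain.
Types absent from the background and unobserved are dropped.

## Preranked GSEA

Genes are ranked by −log10 p.  The enrichment score is the classical
weighted Kolmogorov–Smirnov running-sum extremum (weight 1 on |score|;
weight exposed).  Set-size bounds 15–500 apply after intersection with the
ranked list.  Significance is by gene-label permutation (default 1000,
seeded): nominal p is the matching-sign tail frequency with +1 smoothing;
NES divides ES by the mean |null ES| of matching sign; FDR q pools
normalized positive and negative null and observed NES as in the original
GSEA procedure.  When no set reaches q < 0.1 the report falls back to
nominal p < 0.001.  Gene-label permutation is forced by the design: the
ranking metric is an unsigned −log p, so phenotype permutation is not
available inside this module.  A hypergeometric over-representation test
with BH FDR is provided for annotating short unique-gene lists against the
same GMT collections.

## Synthetic cohort generator

The generator exists so that every stage is testable without cohort data,
and it defines the study conditions for the acceptance checks.

* **Phenotypes.**  Four equicorrelated standard-normal dimension factors
  (latent correlation 0.85); each of the 17 items loads on its dimension
  (loading 0.70 variance share, DSM-IV 5/2/5/5 item split) and is
  thresholded to the 1–5 scale with cut points giving a right-skewed item
  distribution.  These values were set once so the cohort descriptives
  match the target population: mean total ≈ 36.6 (target 36.59), observed
  subscale correlations spanning ≈ 0.62–0.84.  Covariates: age ~ N(52.67,
  8.02), a binary ancestry indicator (p = 0.845), five cell proportions
  (Dirichlet composition scaled by a Beta(9,11) lymphoid total, so the five
  do not sum to a constant and remain jointly identifiable with the
  intercept), two standard-normal surrogate variables.
* **Counts.**  NB with per-gene baseline log-uniform on [20, 500] counts,
  per-gene dispersion log-normal around 0.1 (sd 0.5), log-normal library
  factors (sd 0.15), small random covariate effects, and a planted
  phenotype effect: amplitude × standardized shape of the scaled phenotype.
  Effect classes null/linear/nonlinear (default 80/10/10%); nonlinear
  shapes are five archetypes (quadratic, saturating, sigmoid, U,
  inverted-U), matching the planted k for gap-statistic recovery.  The
  default amplitude 0.5 (log scale) gives essentially full power at 226
  subjects, which is what the edf-classification checks require.
* **Isoform TPM and AS events.**  Log-normal isoform abundances with the
  same effect machinery, columns normalized to 10^6.  Each AS event owns
  1–2 inclusion and 1–2 exclusion transcripts; gene-level abundance is
  split by a PSI drawn as sigmoid(baseline logit + amplitude × shape +
  noise), so planted AS effects live on the logit scale and survive TPM
  renormalization exactly.  Event types default to an SE-modal mix.
* **Determinism.**  Every operation draws from its own child stream of the
  cohort seed, so outputs are bitwise reproducible and independent of call
  order.

What the generator does **not** emulate: read-level noise, GC/length bias,
isoform-to-gene aggregation, correlated gene modules, batch structure
beyond the surrogate-variable covariates, or cell-type mixture signal.
Passing tests therefore demonstrate statistical correctness of the models
on data satisfying their assumptions, not robustness to the full messiness
of cohort RNA-Seq.

### Known limitations

* **Compositional TPM coupling.**  TPM columns of the scaled-down synthetic
  transcriptome sum to 10^6 across only a few hundred isoforms, so planted
  effects perturb every column sum and leak phenotype signal into null
  isoforms (null p < 0.05 rate up to ~0.1–0.25 as the effect fraction
  grows).  This is a property of subset-TPM normalization, not of the
  regression engine — PSI, being a within-event ratio, is immune, and the
  engine is calibrated on directly constructed Gaussian features.  Real
  transcriptome-wide TPMs dilute the effect by orders of magnitude.
* **Size factors under massive differential expression.**  Median-of-ratios
  assumes a mostly-null transcriptome; when a majority of genes carry
  strong planted effects the estimated factors pick up phenotype
  correlation and the null rate inflates.  At the default 20% effect share
  the effect is negligible.
* **Test calibration is asymptotic.**  The Wald reference (chi-squared with
  edf df, conditional on the selected smoothing parameter) is approximate;
  simulations at n = 200–226 show it holds to within the tolerances above,
  but very small cohorts are untested.
* The exact test statistic and dispersion-moderation scheme of the
  published NB-GAM RNA-Seq tools are not public in detail; this package is
  a faithful re-implementation of the described behavior validated by
  simulation and against mgcv on fixtures, not a bit-compatible clone.

## Numerical choices

IRLS converges on relative deviance change < 1e-6 (cap 100 iterations);
fits that fail to converge or produce singular systems are flagged, carry
missing p, and are excluded from the BH family.  Collinear unpenalized
design columns raise an error naming the columns.  Means are clipped to
[1e-10, 1e10] and linear predictors to ±30 during iteration.  Dispersion
search runs on log alpha in [1e-6, 100].  The problem sizes used by the
test suite and acceptance script (2000 genes × 200–226 subjects per run, 20
replicate seeds for calibration and cluster-recovery rates) were chosen as
the smallest sizes at which the measured rates are stable to within a
percentage point or two.
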