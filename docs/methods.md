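# Methods

This note documents the models, estimators, numerical conventions and
design choices behind `omicsig`, and what the synthetic benchmarks do and
do not demonstrate.

## Synthetic cohort generator

The generator emulates a two-arm tumor cohort with five omics layers and
right-censored survival.  Per layer with `p` features and `n` samples:

1. **Network.** A strictly lower-triangular effect matrix `B_true` under a
   fixed feature ordering: each ordered pair (j → i, j < i) is an edge with
   probability `network_density`; effect magnitudes are Uniform[low, high]
   with random sign (defaults 0.3–0.8).  Acyclicity guarantees a
   well-defined generative distribution g = (I − B)⁻¹(shift + ε) and makes
   recovery identifiable.
2. **Groups and DE.** Survival-group labels (good/poor, fair coin) are
   assigned first and drive everything downstream.  A `de_fraction` subset
   of features receives a mean shift of `de_effect × noise_sd` in the poor
   group, *inside* the structural recursion — so descendants of shifted
   features inherit attenuated group differences.  `GroundTruth.de_features`
   lists the directly shifted set; `GroundTruth.total_shifts()` returns the
   propagated distribution-level shift (I − B)⁻¹·s of every feature.  Tests
   that score the DE screen against the direct set therefore use
   effect-free edges, where the two notions coincide.
3. **Survival.** Times are exponential with log-hazard linear in the risk
   features (a subset of the directly shifted features, weight 0.5 per
   unit on the expression scale, baseline hazard 1e−3 per day → median
   survival near two years at the baseline).  Censoring is administrative:
   C ~ Uniform(0, τ) with τ calibrated by bisection so the expected
   censored fraction equals `censor_rate` (default 0.3).
4. **Purity.** Beta(8, 3) per sample — mean 0.73 with roughly a fifth of
   samples below the 0.60 cut, so the purity filter is always exercised.

Defaults (n = 300, five layers of 200 features, density 0.05, de_fraction
0.2, de_effect 2, noise_sd 1) constitute the "strong-signal" cohort used
by the end-to-end benchmarks.  What the generator does **not** emulate:
heavy-tailed counts, layer-specific measurement models (methylation
beta-values, RPPA dynamic range), batch effects, missingness, or
cross-layer regulation (layers are generated independently).  Passing
benchmarks demonstrate correctness of the estimators under a linear
Gaussian world, not performance on real TCGA-like data.

## Preprocessing conventions

* **Population SD everywhere** (divide by n).  Standardization and
  Z-flagging share this convention; it is asserted in tests.
* **Purity boundary**: samples *below* the threshold are removed, so
  purity exactly 0.60 is retained.
* **Z > 2 up-regulation flags** use each feature's mean/SD across all
  retained samples; the inequality is strict.
* Constant features are dropped (with a log record) before
  standardization; missing values are an error, never imputed.

## LASSO solver

`lasso_solve` minimizes (1/(2n))‖y − Xb‖² + λ‖b‖₁ by cyclic coordinate
descent with exact soft-threshold updates; the un-normalized penalized
residual form maps onto this by λ ↦ λ/(2n).  Convergence is declared when
the largest coefficient change in a sweep falls below `tol` (default
1e−8); the per-sweep objective is recorded and an increase of more than
1e−10 raises immediately (the update is an exact per-coordinate minimizer,
so the objective is non-increasing by construction).  Hitting `max_iter`
flags `converged=False` rather than raising.  The analytic zero threshold
is λ_max = max_j |x_jᵀy|/n on centered data.  The inner loop is
numba-compiled; columns are passed Fortran-ordered for contiguity.

λ selection (`select_lambda_cv`) uses 5-fold CV over a 50-point log grid
from λ_max down to 1e−3·λ_max with warm-started paths.  Two rules are
offered: `"min"` (CV-MSE minimizer — the right choice for prediction) and
`"1se"` (largest λ within one standard error of the minimum — the sparser
choice for support selection).

## Random LASSO

Stage 1 (importance): B1 bootstrap rounds, each drawing n observations
with replacement and q1 candidate predictors uniformly; a LASSO on the
submatrix (internally standardized, coefficients back-transformed)
contributes its coefficients, zeros for non-candidates; importance is the
absolute mean.  Stage 2 (selection): B2 rounds drawing q2 candidates
without replacement with probability proportional to importance; the
final coefficient is the mean over rounds, hard-thresholded at
`zero_threshold` (default 1/n).  Defaults: B1 = B2 = 200, q1 = q2 = ⌈p/3⌉.

**λ inside the bootstrap.** The penalty is cross-validated *once* per call
on the full data with the 1-SE rule and shared across all subfits —
re-running CV inside every bootstrap round is both two orders of
magnitude slower and, measured on planted-support instances, markedly
less accurate (bootstrap duplicates make CV folds overlap the training
data, biasing λ low).  The shared λ is additionally scaled by
√(1/(1 − e⁻¹)) ≈ 1.26: a bootstrap sample contains ≈ 63.2% distinct
observations, and the appropriate penalty level grows as the root of the
inverse effective sample size.  With the CV-minimum λ and no correction
the procedure over-selects badly (false-positive rate ≈ 0.47 on the
benchmark instances); with the 1-SE rule plus the effective-sample-size
correction it attains sensitivity 1.0 at FPR ≈ 0.15.

**Randomness.** Every bootstrap round b of each stage draws from an
independent generator keyed (seed, stage, b), so changing B1 never
perturbs stage-2 draws and results are bit-reproducible.

## Network inference

For each survival group separately (poor → Bᵀ, good → Bᶜ), features are
re-standardized *within the group* — a pure between-group mean shift can
then never masquerade as an edge — and each feature is regressed on all
others by Random LASSO; row i of B gets a structural zero at position i.
Networks are inferred per layer; the pipeline restricts each layer to its
strongest DE features (default 30) because per-feature regression is
quadratic in p.

**Recovery scoring** (`edge_recovery`) is on the undirected skeleton: a
neighborhood regression recovers each feature's Markov blanket and
carries no orientation information, so directed comparison against the
acyclic truth would miscount every reversed edge.  The default calls an
edge where both |B[i,j]| and |B[j,i]| exceed 0.05 (the symmetrized "AND"
convention of neighborhood selection); on standardized data a coefficient
of 0.05 explains 0.25% of the target's variance, below scientific
relevance.  The "OR" rule is available.

## Differential expression

Moderated t exactly as in the empirical-Bayes variance-shrinkage
methodology: per-feature pooled two-group variance s² on d = n − 2 df;
hierarchical model s² ~ s0²·F(d, d0); hyperparameters by method of
moments on z = log s², matching E(z) and Var(z) to the exact log-F
moments, with the trigamma inverse solved by Newton iteration.  Posterior
variance s̃² = (d0·s0² + d·s²)/(d0 + d); statistic referred to t on
d0 + d df (normal when d0 = ∞, which arises whenever the spread of log
variances does not exceed sampling spread).  The implementation agrees
with Bioconductor limma's `eBayes` to 1e−8 on shared fixtures.  d0 = 0
recovers the ordinary pooled t exactly.

BH adjustment is the step-up q_(i) = min_{j≥i} p_(j)·m/j, per layer
separately.  Selection uses q ≤ α (default 0.05) ordered by |t̃|
descending with lexicographic tie-breaks; a `top_k` mode caps the
per-layer count instead, for matching fixed selection sizes.

## Prognostic signature and validation

The classification target is the survival-group label.  Per layer, DE
features are ranked by a bootstrap importance under the logistic loss
(balanced class bootstrap, random candidate subsets of ⌈p/3⌉, penalized
logistic fits at a λ cross-validated once by deviance), ties broken by
|moderated t| then feature ID, truncated to the configured sizes
(5/11/30/4/3 by default — the feature-elimination step).  A single
L1-penalized logistic regression (FISTA proximal gradient, intercept
unpenalized, Lipschitz step ‖[1, X]‖₂²/(4n)) is refit on the kept
features.

"Leave-group" cross-validation is read as stratified k-fold on the
survival-group label (k = 5).  Balanced training: each class is bootstrap
resampled to the larger class size.  The *entire* chain — DE screen,
ranking, refit — is rebuilt inside every training fold; the held-out fold
is scored with the fold's model and frozen standardization parameters.
Aggregate accuracy/error/MCC come from summed confusion counts; per-fold
and best-fold values are also reported, since an aggregate and a best
fold answer different questions.  MCC is defined as 0 when a marginal
factor of its denominator vanishes.

## Survival analysis

Kaplan–Meier by the product-limit formula over distinct death times;
censored-only times shrink the risk set without contributing a factor;
deaths precede censorings at tied times.  The two-group log-rank test
uses the hypergeometric variance with the (n_j − d_j)/(n_j − 1) tie
correction, referred to χ²(1).  Both agree with lifelines to 1e−9 on
random fixtures.  The pipeline compares good vs poor groups and the
signature's median-split risk strata.

## Problem sizes in the benchmarks

Acceptance-level checks run at the sizes their conditions state: solver
oracles at n=100/p=10, support recovery at n=100/p=40 over 20 seeds,
network recovery at p=30 with 200 samples per group over 10 seeds, DE
calibration at 1000 features, and the end-to-end run on the default
300-sample five-layer cohort.  Module tests use smaller instances chosen
to exercise the same code paths quickly; the pipeline's quadratic network
stage runs on each layer's top DE features, keeping a full synthetic run
comfortably within a few minutes on one CPU.

## Known limitations

* The generator's linear-Gaussian world is favorable to every estimator
  here; real multi-omics data violate it in rank, tails and batch
  structure.
* Importance-weighted candidate drawing cannot drop weak-importance
  predictors when q2 exceeds the number of strong ones; residual false
  positives in Random LASSO stem from data-fixed noise correlations that
  bootstrap averaging cannot cancel.
* Final Random LASSO coefficients are attenuated toward zero (the average
  includes rounds where a predictor was not a candidate); supports are
  meaningful, magnitudes are conservative.
* Group-specific networks are estimated independently; no test is
  provided for whether an individual edge *differs* significantly between
  groups — `differential_edges` ranks contrasts without a p-value.
* Cross-layer edges and Cox-type survival modeling are out of scope.
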