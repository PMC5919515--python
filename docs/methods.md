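# Methods

This note documents the statistical procedures implemented in `metafuse`,
the choices made where the design was genuinely open, and what the synthetic
data does and does not establish.

## Measurement-error model

A duplicated sample contributes, per metabolite, a level estimate
μ = (x₁+x₂)/2 and a single-degree-of-freedom variance estimate
σ̂² = (x₁−x₂)²/2. Pooling these points over all metabolites of a group
(all amines together; each of the nine lipid classes separately — ten groups
in the default layout) gives the cloud to which the two-component piecewise
law is fitted:

σ²(μ) = σ²_Add for μ ≤ α, and σ²_Add + σ²_Mult(μ−α)² above. The fit scans a
cutoff grid (the 2.5%–97.5% quantiles of the pooled levels, 25 candidates,
plus 0), estimates σ²_Add as a robust location of the variances below the
cutoff (Huber M-location, c = 1.345, MAD/0.6745 scale; `step1` can switch to
a plain mean or median), then regresses the excess variance on (μ−α)²
without intercept above the cutoff, and keeps the candidate minimizing the
plain sum of squared variance residuals. Negative estimates are clipped to
zero; predicted variance is continuous and non-decreasing in μ by
construction.

**Step-2 estimator.** The default slope estimator is Huber IRLS, matching
the robust-regression convention of the original analysis environment. On
simulated duplicates, however, the χ²₁ skew of the per-pair variances biases
the robust slope low, and the cutoff selection compensates by drifting α
upward, which inflates σ_Add substantially (σ_Mult stays within ~10%). The
`step2="ls"` option uses the plain least-squares slope, which is the
SSE-consistent choice and recovers both components to a few percent in the
same simulations. Users who want unbiased parameter recovery (rather than
outlier resistance on real data) should prefer `step2="ls"`; the tests
exercise both.

The **median model** stores the median pair variance per metabolite — a
level-independent error structure that is robust to outlying pairs and, per
the data analyses this package supports, often the better-behaved choice
when each metabolite spans a narrow level range.

**Weights.** Either model converts intensities to element-wise weights
w = 1/σ, with the measured value standing in for the unobserved true level
(the level proxy has to be observable at prediction time). Missing entries
get weight 0; weights are capped at 10³ × the block's median positive weight
so that near-zero variance estimates cannot dominate the weighted fits.
When data have been autoscaled and block-scaled, the error SD is divided by
the same factors (error propagates linearly through affine scaling), keeping
the weighted objective consistent in the transformed units.

## Variance-stabilizing transforms

sqrt and log act element-wise (the log guards zeros with a floor of 1e−12 of
the block maximum — ratios are unitless, so the floor is relative to the
block's own scale). The generalized logarithm g(x) = ln(x + √(x²+λ))
interpolates between a shifted linear map (x² ≪ λ) and ln(2x) (x² ≫ λ); for
negative arguments it is evaluated via ln λ − g(−x), which is exact and
numerically stable.

λ is tuned by maximum likelihood on the replicate pairs: transformed pair
deviations are modelled as homoscedastic normal; profiling out the pair
means and the variance leaves NLL(λ) = N ln σ̂²(λ) − Σ ln g′(x) with
σ̂² = Σ(g(x₁)−g(x₂))²/2 divided by the 2N observations, and
g′(x) = 1/√(x²+λ) supplying the change-of-variables Jacobian. The search is
a bounded scalar minimization over ln λ on [ln(1e−8·s²), ln(1e4·s²)], s²
being the global mean replicate variance (scale-free bounds), tolerance
1e−6. Under two-component noise x = μe^η + ε the minimizer sits near the
variance-stabilizing value var(ε)/var(η); purely additive noise drives λ
above the squared data range (the transform degenerates to linear), purely
multiplicative noise drives it far below it (effectively the log). One λ per
block is the default; `mode="metabolite"` fits one per column with a
per-block fallback for metabolites with fewer than 3 usable pairs, because a
per-metabolite likelihood on ~15 pairs is unstable.

## Weighted low-rank fitting

The element-wise weighted objective ‖W ∘ (X − c − TPᵀ)‖²_F is minimized by
alternating exact weighted least squares: weighted column centering (weights
W², frozen for projection), loadings initialized from the SVD of the
centered matrix, then row-wise score solves and column-wise loading solves
until the relative objective decrease falls below 1e−9 (500 iterations cap).
Because every half-step is an exact WLS solve the objective is
non-increasing — the tests assert this at every iteration. Regression
weights are the *squared* w, since the objective squares the weighted
residual. On exit the loadings are orthonormalized (SVD of the fitted
matrix) and scores re-derived by one more WLS pass, so a training row
re-projected with its training weights returns its stored score. Rows or
columns with all-zero weights contribute nothing to the objective; their
scores/loadings come from the unweighted projection, and they are flagged on
the model. New rows are projected by WLS against the frozen loadings after
frozen centering.

MALS filtering reconstructs each block as centers + T_R P_Rᵀ with R = 7
components by default; maximum-likelihood fusion runs the same solver on the
concatenated, autoscaled and block-scaled blocks and feeds the weighted
scores to the discriminant step.

## SCDA

SCA-P is the SVD of the concatenated pre-processed blocks; the shared scores
are T = X_c P_c. The discriminant maximizes βᵀΣ_Bβ / βᵀΣ_Wβ with
unnormalized scatter sums (β is scale-invariant to that convention);
for two classes β ∝ Σ_W⁻¹(T̄₁−T̄₂), stored unit-length, with offset
β₀ = −½(T̄₁+T̄₂)ᵀβ. The decision value d = tᵀβ + β₀ is zero exactly at the
class-mean midpoint; d > 0 predicts the first class and the boundary itself
is assigned to the second class (an arbitrary but fixed tie rule). Σ_W gets
a ridge of 1e−8·trace(Σ_W)/R only when numerically singular — with 7
components and ~27-sample training folds it normally is not. Variable-level
weights are b = P_c β, split per block by the concatenation map.

## Pre-processing orders

Fixed per route: transform → center/autoscale → blockscale (transform
route); MALS-filter per block → center/autoscale → blockscale (filter
route); autoscale → blockscale → weighted component model (modelling route).
Block scaling divides each block by its Frobenius norm so platforms of
different size and variance contribute equally to the fused fit. Column SDs
use the n−1 denominator. All parameters are estimated on training rows and
replayed verbatim on test rows.

## Cross-model validation

The analysis samples are split into 8 class-stratified parts; with 16+15
samples the first seven parts hold 2+2 and the last 2+1. Each part is
predicted from a model fitted entirely on the other seven — including
scaling, MALS filter models and weighted component fits, which are refit per
training fold. The glog λ and the error models are estimated from the
duplicate work-ups, which are *separate samples* from the 31 analysis
samples, so those fits are fold-invariant and computed once per run; sqrt
and log need no training information at all. Component counts (3/5/7 by
default) are fixed inputs, never optimized inside a fold. The split is
re-randomized (default 25 repeats; fold seeds derived from the master seed
via numpy's SeedSequence and recorded in the result), per-repeat
misclassification counts are averaged, and per-metabolite importance is the
mean |b| over all parts × repeats models. Fourteen method/scaling
configurations are supported: {raw, sqrt, log, glog, MALS-RL, MALS-median} ×
{center, autoscale}, plus the two weighted-fusion variants (always
autoscaled).

The univariate screen is a pooled-variance two-sided two-sample t-test per
metabolite, with counts reported at α = 0.05 and at the Bonferroni limit
α divided by the number of metabolites tested.

## Synthetic data

The generator mirrors the cohort layout: two blocks over the same samples
(43 amines, 165 lipids split over the nine classes with a TG/PC-heavy
composition), 16 + 15 analysis samples, and 15 duplicate pairs drawn from
extra samples labelled `other`. True levels are baseline + scores·loadingsᵀ
with baselines log-uniform on [0.05, 20] (platform ratios span orders of
magnitude), 3 latent components, loadings proportional to the baseline
(biological variation ≈ 15% of the level per latent SD, half the metabolites
uninformative per component), and a between-class mean shift of 1.5 latent
SD on the first component — substantial class overlap, the regime where
misclassification counts are informative. Noise follows the two-component
law x = μ·e^η + ε (default σ_Mult = 0.1, a typical LC-MS relative SD;
σ_Add = 0.02 in ratio units), applied per metabolite group; duplicates are
two independent noise realizations of the same true row. A `piecewise` noise
mode draws directly from the fitted variance law for tests that need the
fitter's exact inverse. Negative observations are clipped to zero
(below-detection behavior).

What the synthetic data does **not** emulate: instrument drift and batch
effects (inputs are taken as already drift-corrected), correlated errors
between metabolites sharing an internal standard, non-normal biological
variation, and structured missingness beyond below-detection zeros. Passing
tests therefore demonstrate correctness of the estimators and the
leakage-free harness under the declared noise model, not performance claims
about any particular real cohort.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` choose sizes that keep a full run
fast while leaving the estimators in their realistic regime: cohort-sized
blocks (61 × 208) for pipeline tests, 10 cross-validation repeats per
configuration in the acceptance script (the harness default is 25), 50–200
Monte-Carlo replications for error-model recovery, and 500 duplicate pairs
per replication for the piecewise-model simulations.

## Known limitations

- The piecewise error-model parameters are weakly identified when the
  level range of a group is narrow or the number of pairs is small; the
  cutoff grid then makes σ_Add unstable (see the step-2 discussion above).
  The median model is the recommended fallback.
- Exactly two classes are supported in the discriminant step.
- Replicate groups must be duplicate pairs; designs with >2 work-ups per
  sample are out of scope.
- Weights for test samples are rebuilt from their measured intensities with
  frozen model parameters; the alternative (freezing training weights) is
  not implemented.
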