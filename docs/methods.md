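# Methods

This note documents the statistical model, the numerical choices, and the
limits of what the package's tests demonstrate.

## The spatially varying coefficient model

Mean species richness S_i at route start point s_i is modeled as

    S_i = α(s_i) + β(s_i) · PM_i + ε_i,      ε_i ~ N(0, τ_ε⁻¹),

with PM_i a standardized productivity covariate (one of the three dynamic
habitat indices summarized over a 39.4-km buffer). α and β are independent
Gaussian random fields with Matérn covariance of smoothness ν = 1 — the
standard choice of the SPDE framework in two dimensions — and range
convention ρ = √(8ν)/κ, under which the correlation at distance ρ is ≈ 0.13.
Each field is decomposed into a constant mean (a fixed effect with vague
Gaussian prior, precision 10⁻⁶) plus a zero-mean field, which keeps the
large-scale level out of the penalized field variance.

The fields are discretized by the SPDE/finite-element method on a
triangulated mesh: with lumped mass matrix C, stiffness matrix G and
κ = √8/ρ, the field weights form a GMRF with sparse precision

    Q = τ²(κ⁴C + 2κ²G + G C⁻¹ G),     τ = 1/(√(4π) κ σ),

so the stationary marginal variance equals σ². Barycentric interpolation
matrices project node weights to route and prediction locations; projector
rows are convex weights.

### Priors

* Spatial range (each field): 2-D penalized-complexity prior with CDF
  exp(−λ/ρ), calibrated by an exceedance statement P(ρ > ρ₀) = p. The
  defaults use ρ₀ = 2,243 km, p = 0.5 (half the maximum inter-route
  distance of the motivating continental study); the prior median then
  equals ρ₀ exactly.
* Marginal SD: exponential PC prior with P(σ > σ₀) = p, defaults σ₀ = 1,
  p = 0.5.
* Noise precision: Gamma(shape 1, rate 10⁻⁵) on τ_ε (equivalently a
  log-gamma prior on the log precision) — essentially flat over the
  relevant scale.

The range prior is parameterized by its *exceedance* probability because
the calibration statement is "the probability that the range exceeds the
threshold"; at p = 0.5 this coincides with the complementary convention.

## Inference

The latent vector (two fixed effects + two fields) is Gaussian given the
five hyperparameters (ρ_α, σ_α, ρ_β, σ_β, τ_ε), so it is integrated out
analytically; the resulting marginal likelihood is explored by an adaptive
random-walk Metropolis sampler on the log-hyperparameters (proposal scale
adapted toward ~30% acceptance during burn-in, with the proposal
covariance estimated from the early chain and frozen at the end of
burn-in, so post-burn-in draws are valid Metropolis output). For each
retained hyperparameter draw one exact joint latent sample is drawn from
its Gaussian full conditional, giving finite-sample-correct posterior
draws of the coefficient surfaces.

Numerical design, chosen for a single-CPU budget:

* The two fixed effects would insert dense rows into the joint precision;
  they are removed by a rank-2 Schur complement so only the sparse field
  block is factorized.
* The field block is factorized by banded Cholesky after a
  reverse-Cuthill-McKee reordering computed once per fit (the sparsity
  pattern does not depend on the hyperparameters).
* Field-prior log-determinants come from a one-time generalized
  eigendecomposition of (G, C): log det Q = 2m log τ + log det C +
  2 Σ log(κ² + w_i), evaluated in O(m) per iteration.
* Latent draws use the perturb-and-solve identity
  x = μ + Q⁻¹(τ Mᵀe + s), e ~ N(0, I/τ), s ~ N(0, Q_prior), which needs
  only solves; prior-field perturbations use Q = τ²B C⁻¹B with
  s = τ B C^{-1/2} u.
* A Cholesky failure at a proposed hyperparameter point rejects the move;
  a failure at the initial point raises with the offending values.
  Degenerate (near-zero-area) triangles are filtered during meshing
  because their stiffness entries destroy conditioning.
* Convergence is reported, never silent: acceptance rate and per-parameter
  effective sample sizes (Geyer initial positive sequence) are attached to
  every fit, with flags when they are poor.

### Mesh

The mesh domain is the concave hull of the route points dilated by a
buffer (default: the maximum edge length). Vertices are the route points,
boundary samples, and a quasi-regular interior lattice; any triangle edge
longer than the cap is split by a Steiner point pulled toward the adjacent
triangle's centroid (a point exactly on a convex-hull chord would be
silently dropped by Qhull, and a barely-displaced one would create a
sliver). Residual over-long hull chords bridging boundary concavities are
dropped. The default edge cap for continental-scale runs is 449 km; for
accuracy-sensitive analyses (oracle comparisons, recovery studies) a cap
of about one fifth of the field's range keeps the SPDE discretization
error small, and that is the setting the statistical tests use.

## Dynamic habitat indices

8-day composites are assigned to the month containing their start date and
scaled by days_in_month/8 to a monthly total (the monthly-aggregation
dialect is isolated behind `aggregate_to_monthly`; stacks flagged monthly
pass through). Per year and pixel: sum, minimum, and CV = sample SD (n−1)
over mean of the 12 monthly values, with CV defined as 0 where the mean is
0 (zero-productivity deserts are a real, finite case); the final index is
the plain mean across years. Buffer summaries average pixels whose centers
fall within the radius (the common zonal-statistics default, and exactly
reproducible by brute-force enumeration, which the tests do). Covariate
standardization uses the sample SD and returns the transform parameters.
Categorical land cover aggregates by majority class, ties to the smallest
class code.

## Route filters

The human-cover filter drops a route when human-dominated classes
(croplands, urban/built-up, cropland mosaics) reach 50% of valid buffer
pixels — the threshold is exclusive — or when the buffer holds no valid
pixel (separate reason code). The containment filter requires the full
buffer disk inside the boundary polygon, implemented as distance from the
point to the boundary edge ≥ radius with ties retained. Both filters
record reason codes and commute.

## The synthetic-data generator

The generator emulates the structure the analysis assumes, with one global
seed split into named sub-streams (routes, intercept field, slope field,
noise, GPP, land cover) so each stage is independently reproducible.

* **GPP**: per-pixel monthly series max(0, g(x,y)·(base + amp·sin(2πm/12))
  + noise) with a linear spatial gradient g; the noise-free series has
  closed-form DHI values used as test oracles. Non-negativity is enforced
  by clipping at zero, matching the physical floor of observed GPP minima.
* **Land cover**: a smooth human-dominance probability surface thinned
  into five classes, three of them human-dominated.
* **Routes and richness**: route locations uniform over the domain (the
  real survey's stratified placement along roads is not emulated; uniform
  placement reproduces the statistical structure that matters to the
  model). Richness is generated from the SVC equation with α and β drawn
  exactly (dense Matérn Cholesky) at the routes plus a truth grid, and
  homoscedastic Gaussian noise — the model's own error assumption.
* Defaults mirror the motivating study's conditions where stated: mean
  richness in the mid-50s, a continental (4,500 × 3,000 km) domain,
  spatial ranges of order 1,500 km, standardized covariates. Where the
  study reports no value (noise SD, field SDs) the defaults are set to
  give signal-to-noise comparable to a realistic richness regression
  (noise SD 1 species against field SDs of 3 and 0.5).

What the generator does *not* emulate: observer effort and detection
heterogeneity, road-network route placement, covariate measurement error,
non-Gaussian richness noise, and productivity–land-cover correlation.
Passing tests therefore demonstrate correctness of the machinery and
recoverability under the model's own assumptions, not robustness to their
violation.

## Form classification

A cell is positive if the 2.5% quantile of β exceeds 0, negative if the
97.5% quantile is below 0, otherwise non-existent; an interval touching
zero counts as non-existent (the conservative reading of "excludes
zero"), and "statistically important" is synonymous with "not
non-existent". Classification of fine (1-km-style) measure rasters can use
either the direct posterior projector at cell centers (default) or
nearest-cell lookup in a coarser form grid (a flag), because both
resolutions are legitimate readings of the workflow. Boxplot summaries
use 1.5·IQR whiskers with outliers flagged but counted, so per-form counts
partition the valid cells. No multiplicity correction is applied across
cells, by design.

## Problem sizes used by the test suite

The statistical tests run at sizes chosen to make each property decisive
on one CPU: oracle comparisons at n = 60 routes with a mesh edge of
range/5; parameter recovery with 20 replicates of n = 500 routes over a
4,500-km-square domain (true slope-field range 1,500 km, marginal SD
0.5); form-classification checks at n = 300; Monte-Carlo correlation
checks with 2,000 field draws. The recovery study checks that the 95%
credible interval covers the generating range in ≥ 80% of replicates and
that the posterior median lands within a factor of two of the truth in
≥ 80% — a deliberately coarse bar, because a domain three ranges wide
cannot identify a range sharply, and the wide credible intervals the fits
report are the honest description of that limit.

## Known limitations

* Smoothness is fixed at ν = 1; anisotropy and non-stationarity are out
  of scope, as are non-Gaussian likelihoods and multi-covariate models.
* Coordinates must arrive in a planar metric CRS; all distances are
  Euclidean kilometres. No geodesy.
* The random-walk sampler is adequate for the 5-dimensional
  hyperparameter posterior but mixes slowly when fields are weakly
  identified; effective sample sizes are reported so users can judge.
* Range estimates on domains only a few ranges wide are intrinsically
  uncertain; posterior medians can sit a factor of ~2 from the truth while
  the credible interval remains calibrated.
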