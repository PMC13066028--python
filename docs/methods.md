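# Methods

## Model

For each child aged 6–59 months the four malnutrition responses are modelled
jointly as a multivariate Gaussian,

    y_i = (Hb_i, HAZ_i, WAZ_i, WHZ_i)ᵀ ~ N(μ_i, Σ_i),

with the covariance expressed through the modified Cholesky decomposition
`T_i Σ_i T_iᵀ = D_i²`, `T_i = I − φ_i` unit lower triangular,
`D_i = diag(exp(λ_i))`.  The decomposition turns covariance modelling into a
sequence of regressions of each response on its predecessors (φ) plus log
innovation scales (λ), all unconstrained, so the 14 distributional
parameters — 4 means, 4 log scales, 6 Cholesky coefficients — can each carry
an additive predictor while Σ stays positive definite for any predictor
values.  The response ordering (Hb, HAZ, WAZ, WHZ) is fixed everywhere;
φ and λ values depend on that ordering, but the reconstructed Σ, its
correlations and all derived prevalences do not.

Links: identity for means and φ entries, log for scales (the predictor *is*
λ = log scale).  The log-density is evaluated directly from the factors,
`−(M/2)·log 2π − Σ_m λ_m − ½‖D⁻¹T(y−μ)‖²`, never forming Σ; `exp(λ)` is
floored at 1e−8 to guard against singular D during sampler excursions.

Clinical indicators are tail probabilities of the fitted Gaussian margins:
anemia P(Hb < 110 g/L), stunting P(HAZ < −2), underweight P(WAZ < −2),
wasting P(WHZ < −2), overweight P(WAZ > 2).  The anemia cutoff is the WHO
value for 6–59 months and assumes altitude/age/sex adjustment of Hb was
applied upstream.  Overweight is defined on WAZ by default but the indicator
set accepts `overweight_on="whz"` for the weight-for-height convention.

## Additive predictors

- P-splines: cubic B-splines, 20 basis functions, second-order difference
  penalty (Eilers–Marx defaults); knots equidistant over the observed range
  extended by `degree` knots per side; out-of-range prediction is clamped to
  the training boundary.
- Spatial term: tensor product of two marginal P-splines over (lon, lat),
  10×10 bases by default, Kronecker-sum penalty.
- Linear terms are standardized by the training mean/SD; factors are
  dummy-coded against the first sorted level, unpenalized.
- Penalized smooth designs are column-centred on the training data so the
  constant direction lives only in the intercept; under a second-order
  penalty this leaves the linear trend of each smooth likelihood-identified
  and makes the Bayesian posterior proper without extra constraints.

## Fitting pipeline

**Spatial split.**  Train/test splitting operates on whole clusters so no
cluster's children straddle the partitions.  The Delaunay triangulation of
cluster sites identifies interior (non-convex-hull) vertices; test clusters
are chosen among them by farthest-point sampling until the held-out share of
children reaches the 20% target.  Because hull vertices stay in training,
test clusters lie inside the convex hull of the training clusters —
prediction is interpolation, not extrapolation.  Degenerate (collinear)
geometry falls back to a seeded random split with a warning.  The split does
not stratify by country or survey wave; with multi-country data, users who
need per-country balance should split each country separately.

**Baseline.**  The intercept-only model is the closed-form Gaussian MLE
(sample mean, n-denominator covariance) transformed to (φ, λ) exactly.

**Boosting selection.**  Noncyclic componentwise gradient boosting over all
(parameter, term) candidates.  Per iteration, each candidate is scored on a
fresh random minibatch (half of the training rows): the candidate direction
is the ridge fit of the batch score ∂ℓ/∂η_k, and the score is the exact
batch log-likelihood gain of a line-maximized step shrunken by ν = 0.1.
Only the best pair is updated, with the step re-maximized on the full data
and applied only if it improves the full training likelihood (so the
training log-likelihood is non-decreasing).  Minibatch scoring follows the
batchwise-backfitting idea and keeps null-data selection close to uniform
across candidates instead of concentrating on whichever term fit noise
first.  Ridge weights are calibrated per learner to ~4 effective degrees of
freedom so smooths, linear terms and factors compete fairly.  Intercepts are
refreshed every iteration by exact (means, φ) or damped-Newton (λ)
coordinate steps and never counted as selections.  Selection frequencies are
selections per iteration; terms below a 5% frequency threshold (configurable)
are pruned before estimation.  An optional cluster-level internal holdout
(10% when enabled) records the log-likelihood trace to support choosing the
iteration count.

**MCMC.**  The sampler exploits the decomposition's structure: conditional
on λ, the likelihood is exactly Gaussian in the mean coefficients and in the
φ coefficients, so those blocks (one block per term) are drawn from their
exact Gaussian full conditionals.  λ blocks use random-walk Metropolis with
Robbins–Monro scale adaptation during burn-in (target acceptance 0.44 for
scalar blocks, 0.234 otherwise).  Penalized coefficients have partially
improper Gaussian priors with precision P/τ²; each smoothing variance τ²
carries an inverse-gamma(0.001, 0.001) hyperprior and is updated by
conjugate Gibbs using the penalty rank.  Unpenalized blocks (intercepts,
linear, factor) have flat priors.  Defaults: 2,000 iterations, 1,000
burn-in, thinning 10; chains are initialized from the baseline MLE and are
reproducible under a fixed seed.  Diagnostics record λ-block acceptance
rates and effective sample sizes (Geyer initial-positive-sequence estimator)
for all intercepts.

**Validation.**  With Gaussian margins the quantile residual
Φ⁻¹(F_m(y_m)) reduces to the standardized residual (y_m − μ_m)/σ_m; the
report summarizes its first four moments per response, the coverage of 90%
predictive intervals, and the mean held-out joint log-density against the
intercept-only baseline.  Full multivariate calibration transforms (e.g.
rotated PIT or energy scores) are deliberately out of scope; the per-margin
residuals plus the joint log-score cover the checks the pipeline needs.
Cross-validation partitions clusters into k spatially spread folds (k = 5
default) by dealing the farthest-point-sampling order round-robin, so each
fold covers the whole region.

## Derived surfaces

Prediction grids use pixel centres on a regular 0.18° step (≈ 20 km at the
equator); a true equal-area grid is out of scope and this is documented as
an approximation.  Pixels classed *Barren* or *Permanent Snow and Ice* and
pixels above 3000 m are flagged *not included* and carry no values (missing
elevation gets its own flag; land-cover reasons take precedence when rules
overlap).  Per pixel and posterior draw the 14 predictors are evaluated at
the pixel covariates with age and year fixed, (μ, Σ, ρ) reconstructed, and
the five indicator prevalences plus six pairwise correlations summarized by
the posterior mean and equal-tailed 95% interval.  Whether to fix a
reference age or average over an age distribution is left to the caller
(scalar age per call; profiles below give the full age dependence).  Age
profiles fix all other covariates at the median (numeric) or mode
(categorical, ties broken by first sorted level) observed within a 20 km
great-circle buffer of the chosen location.

## Synthetic data generator

The generator emulates the features of a multi-country DHS-style survey the
estimators rely on: uniform cluster locations in a lon/lat box with 15–30
children each (approximate PSU sizes); integer ages uniform on 6–59 months;
environmental covariates (temperature, malaria incidence, elevation) as
smooth random-cosine fields (a low-rank random Fourier approximation to a
Gaussian process, deterministic given the seed); a spatially correlated
categorical land cover including *Barren* and *Permanent Snow and Ice* at
configurable proportions; elevation calibrated so a configurable fraction of
the region exceeds 3000 m; and a 5-level wealth index from a spatial
gradient plus household noise, binned into approximate quintiles.

Responses are drawn from the model itself: configured effects perturb
individual distributional parameters around base intercepts obtained by
transforming a base covariance.  Default conditions: marginal SDs
(15 g/L, 1.1, 1.33, 1.1) — plausibility choices in the range typical of
child surveys; correlations ρ(HAZ,WAZ) = 0.68, ρ(WAZ,WHZ) = 0.70, small
Hb–anthropometry correlations (≤ 0.18), and ρ(HAZ,WHZ) = −0.02 — weakly
negative, as the admissible positive-definite range given the two strong
correlations is (−0.048, 0.9996), so raw-data HAZ–WHZ correlations of about
−0.10 sometimes seen in surveys are not jointly attainable here.  Base means
are back-solved from prevalence levels representative of recent sub-Saharan
surveys (anemia 69.6%, stunting 32.9%, underweight 14.8%, wasting 5.2%,
overweight 2.5%) under the Gaussian margins, with
μ_WAZ and σ_WAZ jointly solved from the underweight/overweight pair.  Age
effects reproduce the canonical profiles: anemia and wasting highest in
infancy and declining (saturating-ramp effects on μ_Hb and μ_WHZ), stunting
rising to a plateau at 36 months (smoothstep on μ_HAZ), plus spatial fields
on μ_Hb and μ_HAZ, modest wealth/sex/year effects, and an age-dependent
φ₄₃.  All effect shapes are centred over their reference distributions so
amplitudes change shape, not marginal levels.

What the generator does **not** emulate — and what passing tests therefore
do not establish for real data: survey sampling weights and non-response,
measurement error in Hb or anthropometry, non-Gaussian (skewed/heavy-tailed)
response distributions, country borders and country-level heterogeneity
beyond the smooth spatial fields.  Under the Gaussian model, |z| > 6 values
occur with probability ~1e−4 per child at the default scales;
`plausibility_check` reports the exceedance fractions rather than enforcing
a hard bound, since truncation would distort the likelihood the estimators
assume.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately scaled problem sizes chosen to
exercise each property with adequate power: correlation recovery uses 20
replicates of n = 5,000 children with a 1,000-iteration chain; selection
sanity uses n = 5,000/500 iterations for the signal case and 20 null
replicates of n ≈ 1,500; surface recovery uses n = 20,000 children, 8×8
spatial bases and a 0.25° grid.  Gaussian block draws add a 1e−10 relative
jitter to the conditional precision before Cholesky; weighted Gram matrices
collapse to a scalar multiple of the precomputed Gram when the weights are
constant across observations (exact in intercept-only scale models).  Ties
in the buffer mode are broken by the first sorted level; boosting iterations
whose best candidate cannot improve the training likelihood record no
selection.

## Known limitations

Single-chain MCMC (convergence judged by acceptance rates, ESS and the
likelihood trace); no country-level random effects or interaction smooths
beyond the lon/lat tensor; no aggregation of pixel surfaces to
administrative units; correlation parameters are regressions on the fixed
response ordering, so per-parameter interpretation of φ (unlike Σ) is
ordering-dependent.
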