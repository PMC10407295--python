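# Methods

This note documents the models, priors, sampler, synthetic-data generator
and the numerical choices behind `crpbayes`, in the spirit of a model
documentation page: what is computed, under which assumptions, and where
the genuinely open design decisions were resolved.

## Models

Both models regress natural-log CRP on a fixed-effect block and two
hierarchical grouping factors.

* Fixed effects **x** (13 columns, in design order): dummies for gender
  (reference male), house ownership (ref. owner), self-rated health
  (ref. excellent, 4 dummies), smoking (ref. current smoker, 2 dummies),
  then z-standardized sport activity (0–10 scale), age (years), equivalized
  household income and BMI (kg/m²).
* Hierarchical factors: education (6 qualification levels) and occupation
  (9 NS-SEC categories) enter as group deviations from the grand mean,
  not as dummies, so the groups partially pool toward each other.

**Model 1** — `y_i ~ StudentT(ν, μ_i, σ)` with
`μ_i = β₀ + x_iᵀβ + u_edu[e_i] + u_occ[o_i]`.

**Model 2** — identical mean structure, but the scale becomes log-linear:
`ln σ_i = γ₀ + x_iᵀγ + v_edu[e_i] + v_occ[o_i]`. This is a distributional
(location–scale) model: within-group dispersion differences are parameters,
not nuisance. Setting every scale-side coefficient to zero and
γ₀ = ln σ recovers Model 1 exactly at the likelihood level; the test suite
asserts this identity to 10⁻¹⁰.

The Student-t likelihood accommodates the extreme CRP values that survive
even the log transform. As ν → ∞ it converges to the Gaussian likelihood
(asserted to 10⁻³ at ν = 10⁶).

## Priors

With μ_y, σ_y the analytic sample's log-CRP mean and SD (data-dependent
constants computed once):

| parameter | prior | rationale |
|---|---|---|
| β₀ | N(μ_y, σ_y) | weakly centers the intercept on the outcome scale |
| β, γ (slopes) | N(0, 1) | covariates are centered/z-scored, unit effects are large |
| z = u/sd (deviations) | N(0, 1) | non-centered parameterization of u ~ N(0, sd²) |
| sd_edu, sd_occ | half-Cauchy(0, σ_y) | heavy-tailed, allows near-zero pooling |
| σ (Model 1) | half-Normal(0, σ_y) | scale must be positive; σ_y is the no-covariate bound |
| sd_v_edu, sd_v_occ (Model 2) | half-Normal(0, σ_y) | scale-side deviation SDs |
| γ₀ (Model 2) | N(0, σ_y) | centered at 0 on the log-σ scale (see open decisions) |
| ν − 1 | Exponential(rate 1/29) | prior mean 30: near-Gaussian unless data demand tails |

Open decisions resolved here:

* The half-Cauchy and half-Normal readings of the "N(0, σ_y)"-style scale
  priors truncate to positive support; untruncated normals on a scale
  parameter are not a density.
* The scale-model intercept prior is centered at 0 (log scale), not at
  μ_y: μ_y lives on the outcome scale and would be nonsensical for ln σ.
* The exponential ν prior uses RATE 1/29 (mean 29) on ν − 1, the standard
  robust-regression recommendation; `PriorConfig.nu_rate` exposes the
  choice for sensitivity analysis.

## Sampling

HMC on the unconstrained vector: log transforms (with Jacobians folded
into the target) for σ, the four group-SD parameters and ν − 1; the group
deviations are non-centered (u = sd·z), which removes the funnel geometry
that otherwise defeats fixed-step-size HMC in hierarchical models.
Gradients are analytic and checked against central finite differences to
10⁻⁵ relative error in the test suite.

The sampler is a static-path variant in the style of Stan's adaptive HMC:

* leapfrog integrator with a per-iteration step count drawn uniformly from
  {1, …, L_max} (default L_max = 32), which decorrelates trajectory
  lengths without tree building — adequate at this dimension (33 and 63
  parameters);
* dual-averaging step-size adaptation toward 0.8 acceptance
  (γ = 0.05, t₀ = 10, κ = 0.75);
* windowed diagonal mass-matrix estimation (initial 75-iteration
  step-size-only buffer, doubling windows, 50-iteration terminal buffer),
  with the Stan-style shrinkage `(w/(w+5))·var + 10⁻³·(5/(w+5))`;
* energy errors beyond 10³ (or non-finite) count as divergences and are
  rejected; more than 10% post-warmup divergences raises a warning flag
  on the ChainSet (not an exception).

Protocol defaults mirror the analysis: 4 chains × 2000 iterations, first
1000 discarded, warmup doubling as the adaptation window. Per-chain RNG
streams derive from the master seed via seed-sequence keys (seed, chain),
so runs are bit-for-bit reproducible and chains are exchangeable.

Correctness evidence beyond unit tests: on known normal targets the
sampler recovers moments to ±0.05 and passes a Kolmogorov–Smirnov check at
distance < 0.02 on 4000 draws; on a 3-row toy posterior with only the
intercept and scale free, MCMC means agree with brute-force 2-d grid
quadrature of the same unnormalised target within 0.02.

## Diagnostics and reporting

* Split-chain R-hat (each chain halved before the between/within variance
  comparison, so within-chain drift is caught). The pipeline gates every
  reported parameter at R-hat < 1.05 and aborts with a distinct exit code
  on failure.
* ESS via chain-averaged autocovariances and Geyer's initial monotone
  positive sequence, with the between-chain term included; cross-checked
  against arviz in the test suite.
* Summaries report pooled posterior mean, SD, and 2.5/50/97.5% quantiles
  (median-unbiased quantile estimator).
* Group contrasts are per-draw differences `deviation[level] −
  deviation[reference]`; the 65% bands around them are central
  (equal-tail) intervals by default — the thick-bar convention is not
  otherwise pinned down — with an HPD option (`method="hpd"`).
* Posterior regression lines: 20 (intercept, slope) pairs sampled without
  replacement from pooled draws, each pair from a single draw.

## Synthetic data

The generator emulates the restricted survey sample. Covariates are drawn
from a Gaussian copula:

* latent 10-dimensional normal with the published covariate correlation
  matrix (the CRP row is carried but never used for covariate generation —
  CRP is produced only by the response models);
* printed 2-d.p. correlation matrices are often slightly indefinite, so
  eigenvalues are clipped at 10⁻⁸ and the matrix rescaled to unit
  diagonal; repairs that would move any entry by more than 0.15 are
  refused;
* continuous margins are truncated normals whose underlying (μ, σ) are
  moment-matched by root-finding so the *truncated* mean/SD hit the
  published targets — age on [16, 98] (the published mean 52.1/SD 16.7 are
  inconsistent with a narrower working-age range, and survey eligibility
  started at 16), BMI on [13, 60], sport activity on [−0.5, 10.5] rounded
  to integers 0–10;
* income is lognormal matched to the published mean/SD: right-skewed and
  strictly positive, as household income is;
* categoricals are thresholded at cumulative published proportions in
  their listed order, giving ordinal-style latent correlations;
* height is drawn independently (truncated normal, 168 ± 9.5 cm) and
  weight backed out from the copula-generated BMI, so the BMI formula
  reproduces the generated value exactly;
* household adult/child counts are independent categoricals (1–3 adults,
  0–2 children) whose only job is to exercise income equivalization.

Responses are simulated from Model 1 or 2 at configurable "true"
parameters; the shipped reference truths are the published posterior means
of both fitted models, so synthetic outcome distributions resemble the
real one (marginal log-CRP ≈ 0.46 ± 1.09 at large n vs the published
0.444/1.093). The raw fixture blanks three disjoint row sets — 521 CRP,
283 height/weight, 132 one-covariate — leaving 8960 complete rows.

What the generator does **not** emulate: survey weights, the two-stage
PSU/address sampling design, household clustering, item-missingness that
correlates with covariates (missingness is assigned completely at random),
and any direct marginal law for CRP (the models define it). Passing
recovery tests therefore show the estimation machinery is correct under
the models' own assumptions, not that the models are correct for the real
survey.

## Data preparation

* Exclusion cascade, in fixed order with one reason per row: missing CRP →
  inapplicable height/weight → non-positive CRP (log undefined; the source
  is silent, treated as missing) → any missing covariate. The audit log
  satisfies `rows_out + Σcounts = rows_in` on every input and the cascade
  is idempotent.
* BMI = weight / (height/100)²; log-CRP = ln(mg/L); high-risk flag strictly
  CRP > 3 mg/L.
* Income is equivalized by the OECD-modified scale (1.0/0.5/0.3 for first
  adult / additional adults / children — the contemporary UK convention),
  configurable to the original Oxford scale (1.0/0.7/0.5); equivalization
  precedes z-standardization.
* z-standardization uses the post-exclusion sample's moments with the n−1
  SD: the moments must describe the modelled sample, and prior scales
  assume unit-variance covariates.
* Descriptive correlations: product-moment between continuous pairs,
  Spearman on integer level codes when a categorical is involved.

## Problem sizes and tolerances

Parameter-recovery studies run at n = 2000 with the full 4 × 2000/1000
protocol (≈ 25–30 s per model); recovery is asserted within
max(0.06, 3 × posterior SD) of the generating value, reflecting both the
sampling noise of one synthetic dataset and Monte-Carlo error. Generator
calibration checks use n = 10⁵ (continuous moments within 2% relative,
proportions within ±0.01). Gradient checks use 10⁻⁶ central differences at
interior points; constrained-transform round-trips are exact to machine
precision.

## Known limitations

* Static-path HMC with a jittered step count is less efficient than NUTS
  on strongly correlated posteriors; at these dimensions it achieves
  R-hat < 1.01 and ESS in the hundreds-to-thousands per fit, which is
  sufficient here.
* The ν posterior is weakly identified at moderate n; its recovery is
  correspondingly loose (it is not an acceptance quantity).
* Age enters linearly; no survey weights; no imputation (complete-case
  analysis by design, mirroring the source analysis).
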