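# Methods

## Model

`fireocc` fits single-season, single-species occupancy models to nightly
acoustic detection/non-detection data. The unit of occupancy is the survey
period — one site × year combination — with the closure assumption that
the true occurrence state `z_i` is constant across the nights of a period
and re-drawn across years. Nightly detections are conditionally
independent Bernoulli trials given `z_i`:

- `z_i ~ Bernoulli(ψ_i)`, `y_ij ~ Bernoulli(p_ij · z_i)`;
- `logit(p_ij)` is linear in day-of-season, its square, canopy cover,
  ambient noise rate, nightly mean temperature and a microphone-model
  indicator;
- `logit(ψ_i)` is linear in elevation, distance to water, buffer-mean burn
  severity, its square and pyrodiversity, plus Gaussian random intercepts
  for site (shared across years, encoding between-year correlation of
  occupancy at a site) and wildfire area.

The latent `z_i` is marginalized analytically rather than sampled:
`L_i = ψ_i Π_j Bern(y_ij|p_ij) + (1−ψ_i) 1{Σy=0}`. This keeps the
posterior a smooth function of continuous parameters, makes the likelihood
directly testable against two-term enumeration over `z`, and allows any
continuous-parameter sampler. When posterior occurrence states are needed
(beta diversity), they are recovered exactly from the conditional
`P(z=1|y,ψ,p) = ψq / (ψq + 1 − ψ)` with `q = Π_j (1 − p_ij)` for all-zero
histories, and 1 otherwise.

Each species is fitted independently; community quantities are assembled
from the per-species posteriors draw by draw.

## Covariates

Severity statistics are computed over raster cells whose centers fall
within circular buffers of radius 50, 100, 250 and 500 m (cell-center
membership: simple and exactly testable). Pyrodiversity is the residual
from an intercept-included OLS fit of the buffer severity SD on buffer
mean severity and its square, fitted across all survey periods entering a
given model scale (unburned periods included with sev = sev_sd = 0); the
intercept is required for residuals to sum to zero. All continuous
predictors are standardized to mean 0, SD 1; quadratic terms (`day²`,
`severity²`) are squares of the standardized variable rather than
standardized squares — both conventions appear in practice, this one keeps
the linear and quadratic regressors on a common scale and is fixed as a
module constant (`SQUARE_AFTER_STANDARDIZE`). Every SD in the package
(buffer SD, standardization) is the sample SD (`ddof=1`, `SD_DDOF`).
Centers and scales are stored so predictions can be mapped back to
natural units. The binary microphone indicator is not standardized.

## Priors

The priors are deliberately config-visible (`PriorConfig`) because only
their qualitative role — weak regularization — is fixed by the analysis
design:

- fixed effects: Normal(0, 1.5) on the logit scale, wide enough to be
  weakly informative for probabilities in (0.02, 0.98);
- random intercepts: hierarchical Normal(0, σ) with σ ~ HalfNormal(1),
  sampled on log σ with the Jacobian included.

## Sampler

Inference uses a self-contained blockwise adaptive random-walk Metropolis
sampler (an external HMC backend is unnecessary for these model sizes):

- detection and occurrence fixed-effect blocks: joint multivariate normal
  proposals; proposal covariance re-estimated from warmup draws every 200
  iterations, scalar step size tuned by Robbins–Monro toward 28%
  acceptance;
- site and area random intercepts: elementwise proposals accepted or
  rejected per group. Because each survey period belongs to exactly one
  site and one area, the per-group acceptance decisions are independent
  given the other blocks — one vectorized likelihood evaluation updates
  all intercepts;
- log σ: scalar Metropolis steps, plus a non-centered "rescale" move that
  proposes log σ while holding b/σ fixed. The rescale move is what breaks
  the funnel coupling between intercepts and their SD; without it σ mixes
  an order of magnitude more slowly;
- all adaptation stops at the end of warmup, so retained draws come from a
  fixed kernel. Defaults are 3 chains × 2000 iterations with 1000 warmup.

Initialization: fixed effects at 0 with the intercepts at the logit of
naive detection/occupancy rates clipped to [−3, 3], plus a small random
jitter per chain so split R-hat can detect mixing failures. R-hat > 1.1 on
any monitored parameter raises a runtime warning and is recorded in the
posterior object — never silently. Constant chains make R-hat undefined;
the diagnostic returns NaN as a flagged sentinel.

Per fit, the posterior object stores coefficient draws, per-period ψ
draws, per-period `q = Π(1−p)` draws and pointwise marginal
log-likelihoods — everything model comparison and community diversity
need, without retaining the full night-level `p` array.

## Scale selection

Models fitted at the four radii are compared by PSIS-LOO. Importance
weights are Pareto-smoothed per period (the generalized-Pareto fit to the
largest ratios uses arviz's `psislw`; aggregation, diagnostics and
degenerate-weight fallback are this package's code), elpd is summed over
periods with an SE from the pointwise spread, and LOOIC = −2·elpd. Pareto
k > 0.7 flags periods with unreliable estimates. Periods whose
log-likelihood draws are numerically constant fall back to a plain
log-mean-exp with a warning. Selection is the LOOIC argmin; exact ties
break toward the smaller radius (parsimony of spatial extent) and are
flagged; missing radii produce a partial-comparison warning. Community
diversity uses a single common radius (250 m, the median selected scale)
rather than per-species scales, which are still reported.

## Community diversity

Richness is `Σ_s ψ_s` on a severity grid × pyrodiversity ∈ {−2, 0, +2} SD,
with elevation and water distance at their standardized means (0) and
random intercepts at 0 — a population-level prediction, consistent with
"other covariates at their means". Jaccard dissimilarity is
`1 − |A∩B|/|A∪B|` on detection-corrected occurrence matrices, one drawn
per posterior draw; the both-empty pair is defined as 0 (identical, empty
communities — conventions differ, so this is called out here). Severity
classes are unchanged (exactly 0), low (0, 25], moderate (25, 75] and
high (75, 100], with the boundary value 25 assigned to "low". The
correlation between dissimilarity and severity distance treats all pairs
as independent (no Mantel permutation test; only the coefficient is
reported), and is reported both as the posterior mean over draws and as
the correlation of the draw-averaged dissimilarity matrix, since the two
conventions differ.

## Synthetic data

The generator emulates the structure of a multi-year acoustic monitoring
program, not its physics:

- Landscape: smoothed Gaussian noise rescaled to a target mean/SD of
  percent basal-area mortality, clipped to [0, 100], zeroed outside an
  irregular perimeter blob. Only the marginal and buffer statistics matter
  downstream, so no fire-spread model is used. Defaults: 25 m cells,
  100 m correlation length, mean 45, SD 30, perimeter covering ~65% of a
  5 km square (10 km for full-community defaults so 122 sites fit at the
  500 m minimum spacing).
- Design: sites placed by rejection sampling at ≥ 500 m spacing; three
  wildfire areas assigned by vertical bands (the nearest-fire analogue for
  unburned sites); years-surveyed per site drawn from (52%, 31%, 15%, 2%)
  for 1–4 years; nights per period from a rounded lognormal with median 6
  truncated to [1, 17]. Night/period covariates use documented config
  distributions (noise ~ Beta(1.5, 8), temperature ~ Normal(15, 5) °C,
  canopy ~ Uniform(0, 90)%, microphone indicator Bernoulli(0.5), elevation
  ~ Uniform(1150, 2150) m, water distance ~ Exponential(300 m) capped at
  3 km) — these are design choices, not protocol claims.
- Detections: `z` once per period, `y` per night, exactly the fitted
  model. Default per-species coefficients are Normal(0, 0.5) on the logit
  scale with σ_site = σ_area = 0.3 — modest, mixed-sign effects of the
  size occupancy studies report.

What the generator does *not* emulate: acoustic call structure and
classifier behaviour (detection error enters only through p), spatial
autocorrelation of occupancy beyond the site/area intercepts, temporal
trends across years, severity maps with real fire geometry. Passing
recovery tests therefore demonstrates correctness and calibration of the
estimator under the model's own assumptions, not robustness to
misspecification.

All randomness flows from one seed through named `SeedSequence`
substreams (landscape / design / parameters / per-species detections), so
any stage is reproducible independently of the others.

## Simulation-study conditions

- Parameter recovery: 20 replicates of 500 periods (100 sites × 5 years)
  × 6 nights, fixed mixed-sign coefficients (`studies.RECOVERY_ALPHA/BETA`),
  σ = 0.3; full 3 × 2000 chains. Checks that 90% credible intervals cover
  each true coefficient in ≥ 70% of replicates (a conservative band around
  the nominal 90%).
- Scale selection: 20 replicates, 50 sites × 3 years on a landscape with
  75 m correlation length, occupancy generated from 250 m covariates with
  a strong severity response (+2.0 linear, −0.8 quadratic, +0.6
  pyrodiversity); 2 × 1500 chains per radius. Checks that LOOIC picks
  250 m in a majority of replicates — buffer means at neighbouring radii
  correlate at 0.9+, so this is intentionally a signal-versus-collinearity
  test, not a formality.
- The acceptance script's community analysis uses 8 species × 60 sites ×
  2 years at the 250 m scale with 200 community draws; these sizes keep
  the whole script near 3 minutes on one CPU while exercising every
  pipeline stage.

## Numerical choices and degenerate inputs

- Bernoulli log-terms computed as `−log(1 + exp(∓η))` for stability.
- `period_loglik` requires ψ, p in the open interval (0, 1); boundary
  values raise domain errors (certainty belongs in the data, not the
  parameters).
- Constant covariates refuse standardization; rank-deficient pyrodiversity
  designs (fewer than three distinct severities) raise a collinearity
  error; empty buffers raise rather than returning NaN.
- A single-cell buffer has SD 0 by convention (the sample SD is undefined
  at n = 1).
- Residual orthogonality holds to ~1e−8·n on realistic designs; on
  adversarially ill-conditioned severity vectors the attainable bound
  scales with the condition number of the quadratic design, which is how
  the property tests assert it.

## Limitations

- The sampler is random-walk Metropolis: effective sample sizes per
  iteration are far below HMC's, which the defaults compensate for with
  cheap vectorized likelihood evaluations. Very large site counts (≫ 10³)
  would warrant a gradient-based backend.
- No false-positive detection model: misclassified calls that create
  spurious detections violate the model's assumptions.
- Exact prior families used in any particular field analysis vary; ours
  are explicit defaults, overridable per fit.
- Multi-season (dynamic) occupancy, spatially correlated random effects
  and model stacking/averaging are out of scope.
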