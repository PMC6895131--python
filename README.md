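# fireocc

Bayesian occupancy modelling of wildfire effects on acoustic bat-survey
data: burn severity and pyrodiversity covariates at multiple spatial
scales, single-season occupancy models with imperfect detection,
LOOIC-based scale selection, and detection-corrected community diversity
(species richness and Jaccard beta diversity) with full posterior
propagation.

## The problem

Acoustic bat surveys record which species were detected on each survey
night at each monitoring point, but a species that is present is not
always recorded: calls go unrecorded or unclassified, so raw
detection/non-detection data confound occurrence with detectability.
`fireocc` implements the standard fix — a hierarchical occupancy model.
For species *s*, survey period *i* (one site × year combination, with the
community assumed closed within a season) and survey night *j*:

```
z_i  ~ Bernoulli(ψ_i)          true occurrence (latent)
y_ij ~ Bernoulli(p_ij · z_i)   nightly detection

logit(p_ij) = α0 + α1·day_ij + α2·day²_ij + α3·canopy_i
              + α4·noise_ij + α5·temperature_ij + α6·smm_i
logit(ψ_i)  = β0 + βsite[i] + βarea[i] + β1·elevation_i
              + β2·water.distance_i + β3·severity_i + β4·severity²_i
              + β5·pyrodiversity_i
```

with Gaussian random intercepts for site and wildfire area. Burn severity
is percent basal-area mortality summarized inside circular buffers (50,
100, 250, 500 m) around each point; *pyrodiversity* is the residual of
the buffer severity SD regressed on mean severity and its square — spatial
heterogeneity of fire effects, decorrelated from mean severity by
construction. The latent occurrence state is marginalized analytically,

```
L_i = ψ_i · Π_j Bern(y_ij | p_ij) + (1 − ψ_i) · 1{Σ_j y_ij = 0},
```

so the likelihood is exact and the posterior continuous. Inference uses a
self-contained blockwise adaptive random-walk Metropolis sampler (3 chains
× 2000 iterations with 1000 warmup by default, split R-hat convergence
checks). Per-species models fitted at the four buffer radii are compared
by PSIS-LOO (reported as LOOIC); community richness is `Σ_s ψ_s` over a
severity × pyrodiversity grid, and beta diversity is pairwise Jaccard
dissimilarity on occurrence matrices drawn from the conditional
`P(z | y, ψ, p)`, one per posterior draw.

A synthetic-data module generates landscapes, multi-year survey designs
(sites ≥ 500 m apart, 1–17 nights per period with median 6) and detection
histories under exactly this model with known parameters, so sampler
calibration and scale selection can be tested by simulation.

## Worked example

```python
import numpy as np
from fireocc import community, occupancy, selection, synthetic

dataset = synthetic.simulate_community(seed=1, species=("MYCA", "EPFU", "TABR"),
                                       n_sites=40, n_years=2)
dm = dataset.design_matrices                   # 250 m covariates, standardized
spec = occupancy.ModelSpec.from_design(dm)
post = occupancy.fit(spec, dataset.histories["MYCA"], chains=3,
                     iterations=2000, warmup=1000, seed=2)
print(post.summary().loc[["beta[severity]", "beta[pyrodiversity]"]].round(2))
print("true severity effect:", round(dataset.truths["MYCA"].params.beta[3], 2))
loo = selection.psis_loo(post.log_lik)
print(f"elpd_loo = {loo.elpd_loo:.1f} (SE {loo.se:.1f}), LOOIC = {loo.looic:.1f}")
```

prints

```
                     mean    sd    q5   q95  rhat
parameter
beta[severity]      -1.13  0.47 -1.97 -0.42  1.03
beta[pyrodiversity] -0.35  0.46 -1.14  0.42  1.09
true severity effect: -1.02
elpd_loo = -159.0 (SE 13.1), LOOIC = 318.0
```

The species was simulated with a severity coefficient of −1.02 on the
logit scale; the fitted posterior mean is −1.13 with a 90% credible
interval [−1.97, −0.42] that covers the truth, and R-hat near 1 indicates
the chains mixed. `community.richness_curve` and `community.beta_summary`
then aggregate per-species posteriors into richness surfaces and
severity-stratified Jaccard dissimilarities.

A thin CLI wraps the same functions:

```sh
fireocc simulate --seed 4 --out data/          # 17 species, 122 sites
fireocc fit --data-dir data/ --species MYCA --radius 250 --seed 9
```

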