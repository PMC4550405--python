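# multicity

Multilevel Bayesian ecological regression for small areas nested within
non-adjacent cities: disease mapping within each city, spatially varying
covariate effects *between* cities, and kriged relative-risk surfaces at
places with no data.

## Who this is for

Spatial epidemiologists analysing an area-level exposure (deprivation,
unemployment, pollution) against health outcomes across the census tracts
of many cities at once.  City-by-city analyses yield unrelated, noisy
estimates; `multicity` fits all cities jointly so they share information,
and — when the effects are spatially structured — exploits intercity
geography to sharpen them further and to predict the association where no
city was observed.

## The model

For tract *i* = 1..n_j of city *j* = 1..J, with observed counts O,
expected counts E (given, or from indirect standardization) and covariate
X in percentage units:

    O_ij ~ Poisson(E_ij θ_ij)
    log θ_ij = b1_j + b2_j X_ij + S_ij + H_ij

`S_j` is an intrinsic-CAR spatial field on the city's tract-adjacency
graph and `H_j` iid heterogeneity (the BYM pair), each with per-city SDs
under Uniform(0, l) priors.  Three nested variants for the city
coefficients:

| variant | prior on (b1_j, b2_j) | interpretation |
|---|---|---|
| M1 | flat | independent fixed effects per city |
| M2 | N(α, σ²_b1), N(β, σ²_b2) | exchangeable random effects; exp(β) is the pooled RR |
| M3 | MVN(α·1, σ₁²e^(−φ₁D)), MVN(β·1, σ₂²e^(−φ₂D)) | geostatistical: nearby cities have similar effects |

Under M3 the effective range R = −ln(0.05)/φ₂ (km) summarizes how far the
spatial dependence of the covariate effect reaches, and Bayesian kriging
predicts exp(b₂) — the RR per 1% covariate increase — on any grid, with
posterior mean, SD and P(RR > 1) per location.

Inference is MCMC (elliptical slice + Gibbs + adaptive Metropolis within a
componentwise sweep), with Brooks–Gelman–Rubin R-hat and effective sample
size gates (R-hat < 1.1, n.eff > 100) and DIC model comparison.  See
`docs/methods.md` for the full account.

## Worked example

Simulate an eight-city study from the spatial generative model (pooled RR
1.025 per 1% covariate, 400 km effective range), fit all three variants,
compare by DIC, and krige the slope surface:

```python
import numpy as np
from multicity import (
    ModelSpec, PriorConfig, preset, run_mcmc, dic, compare_models,
    pooled_rr, make_grid, krige_coefficient, predict_surface,
)
from multicity.priors import range_to_decay_bounds, decay_to_range
from multicity.synthetic import simulate_layout, simulate_dataset

layout = simulate_layout(J=8, n_per_city=25, region_km=1000.0, seed=11)
data = simulate_dataset(layout, seed=12)

bounds = range_to_decay_bounds(50.0, 2000.0)
fits, dics = {}, []
for variant in ("M1", "M2", "M3"):
    spec = ModelSpec(variant, PriorConfig(), bounds if variant == "M3" else None)
    fits[variant] = run_mcmc(data.table, data.adjacency, spec,
                             preset("desk", seed=1),
                             D=data.geo.D if variant == "M3" else None)
    dics.append((variant, dic(fits[variant], data.table)))

print(compare_models(dics).round(1).to_string(index=False))
rr = pooled_rr(fits["M3"].get("beta", flat=True), "M3")
print(f"pooled RR per 1% covariate (M3): {rr['rr']:.3f} "
      f"(95% CI {rr['lo']:.3f}-{rr['hi']:.3f})")
r = decay_to_range(fits["M3"].get("phi2", flat=True))
print(f"effective range: {r.mean():.0f} km "
      f"(95% CI {np.quantile(r, 0.025):.0f}-{np.quantile(r, 0.975):.0f})")

grid = make_grid((0, 1000, 0, 1000), 250.0, 250.0)
coef = krige_coefficient(fits["M3"], data.geo, grid, which="slope", seed=2)
print(predict_surface(coef, grid).frame.head(3).round(3).to_string(index=False))
```

Output:

```
model   dic  dbar  p_d  delta_dic       band
   M3 847.5 783.5 64.0        0.0          -
   M2 847.6 782.4 65.2        0.1 negligible
   M1 848.5 781.6 66.9        0.9 negligible
pooled RR per 1% covariate (M3): 1.030 (95% CI 1.001-1.059)
effective range: 192 km (95% CI 51-1067)
    x   y  rr_mean  rr_sd  prob_gt1
  0.0 0.0    1.033  0.036     0.854
250.0 0.0    1.032  0.036     0.851
500.0 0.0    1.033  0.035     0.860
```

Reading it: the pooled-RR interval excludes 1, i.e. the covariate is
associated with excess risk (truth 1.025 is well inside the CI).  With
only eight cities the three variants fit this dataset near-identically
(DIC differences under 3 are negligible) and the effective-range posterior
is wide — a small J carries little information about φ₂; the 31-city
studies in the test suite pin it down better.  The kriged surface reports,
for each grid point, the RR a comparable city would be expected to show
there, with its uncertainty and the probability the association is
adverse.

The same workflow is available from the shell via the `multicity` CLI
(`simulate`, `fit`, `predict`, `compare`), driven by YAML configs; run
directories contain draws, convergence reports, DIC, and RR tables, and
every command is reproducible from its persisted config and seed.

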