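# Methods

## The model family

`multicity` fits ecological Poisson regressions for census-tract counts in
several cities at once.  For tract *i* of city *j*:

    O_ij ~ Poisson(E_ij * theta_ij)
    log(theta_ij) = b1_j + b2_j * X_ij + S_ij + H_ij

where `O` are observed and `E` expected counts (supplied directly or
computed by indirect standardization against the pooled study population),
`X` is an area-level covariate in percentage units, `S_j` is an
intrinsic-CAR (ICAR) spatial field over the city's tract adjacency graph
and `H_j` is iid Gaussian heterogeneity — the Besag–York–Mollié
decomposition, with a separate `sigma_Sj`, `sigma_Hj` per city.
`exp(b2_j)` is the relative risk per one-point covariate increase in city
*j*.

The three variants differ only in the second level:

* **M1** — flat priors on every `(b1_j, b2_j)`: each city is analysed as
  if alone (fixed effects).
* **M2** — `b1_j ~ N(alpha, sigma_b1^2)`, `b2_j ~ N(beta, sigma_b2^2)`,
  conditionally independent: cities exchange information but geography is
  ignored.  `exp(beta)` is the pooled RR.
* **M3** — `b1 ~ MVN(alpha 1, sigma_1^2 exp(-phi_1 D))` and similarly for
  `b2`: nearby cities borrow more.  `D` is the intercity distance matrix
  in km.  The derived *effective range* `R = -ln(0.05)/phi_2` is the
  distance at which the slope-field correlation drops to 0.05.

All standard deviations get `Uniform(0, l)` priors with `l = 10` by
default — vague on the log-RR scale, where realistic values are well below
1.  `alpha` and `beta` are flat by default; `PriorConfig.coef_prior_sd`
optionally makes them proper Gaussians, which exists for prior-predictive
and sampler-calibration runs, not for data analysis.  The decay parameters
`phi_1, phi_2` get `Uniform(a, b)` priors.  Two helpers construct `(a, b)`:

* `decay_bounds(D, rho_lo, rho_hi)` keeps the closest-pair correlation at
  most `rho_hi` and the farthest-pair correlation at least `rho_lo`
  (defaults 0.99 / 0.01).  Note that with very spread-out cities the
  `rho_lo` constraint forbids short effective ranges; for a region
  1000 km across it cannot represent ranges below roughly two-thirds of
  the region size.
* `range_to_decay_bounds(r_min_km, r_max_km)` states the support directly
  as an effective-range interval and is what the synthetic studies use
  (50–2000 km), so that any range from the city-separation scale to
  beyond the region diagonal is representable.

ICAR conventions: the improper density uses the rank `n - c` of the graph
Laplacian (`c` connected components) in its normalizing exponent, and
every field is identified by a sum-to-zero constraint per component.
Isolated tracts contribute nothing to the ICAR quadratic form and their
`S` value is pinned at zero; the loaders flag them loudly because census
tracts within a city are normally contiguous.  The `S`/`H` split itself is
not an inferential target (the classic BYM aliasing); reported quantities
are `log theta`, RRs and variance components.

## Sampling

`run_mcmc` runs a componentwise sweep whose stationary distribution is the
joint posterior; one master seed spawns an independent stream per chain.
The sweep combines:

* **Elliptical slice sampling** for the Gaussian-prior blocks: the fields
  `S` and `H` (one ellipse per city, vectorized across cities with masked
  bracket shrinking — cities are conditionally independent given the
  rest), and the coefficient vectors `b1`, `b2` under M2/M3 (one joint
  ellipse using the prior covariance).  Rejection-free and tuning-free.
* **Exact Gibbs draws** where conditionals are closed-form: `alpha`,
  `beta` (Gaussian, generalized-least-squares form under M3); every SD
  with a `Uniform(0, l)` prior, whose conditional in `1/sigma^2` is a
  truncated Gamma when the effective dimension is at least 2, and is
  otherwise drawn by inverse CDF on a dense log grid.
* **Adaptive random-walk Metropolis** for the rest: per-city `(b1_j,
  b2_j)` pairs (vectorized under M1's flat priors; a sequential scan with
  exact precision-matrix prior deltas under M2/M3) and the M3 covariance
  parameters, proposed jointly on `(log sigma, phi)`.  The intercept
  component of each pair proposal is `d1 = s1 z1 - Xbar_j d2`, following
  the intercept/slope collinearity an uncentered covariate induces.
* **Interweaving moves** that break the slow couplings of the centered
  parameterization: an exact Gibbs rebalancing between each city
  intercept and its heterogeneity-field mean (the likelihood sees only
  their sum); translation Metropolis moves of `(alpha, b1)` and
  `(beta, b2)` holding the deviations fixed; and a joint log-scale
  rescaling of each city field with its SD, whose acceptance is the
  likelihood ratio plus the log-uniform Jacobian.

Proposal scales adapt by Robbins–Monro only during burn-in and are frozen
afterwards, so retained draws come from a fixed kernel.  The kernel was
validated by a successive-conditional (Geweke-style) simulation: data
re-simulated each sweep must leave the parameters distributed by their
prior, which the acceptance suite checks with ESS-scaled quantile bands.
That check is configured with a weakly informative dataset (small expected
counts, small covariate range): with strongly informative data the
successive-conditional chain is valid but mixes too slowly to test
anything within a sensible budget.

Presets: `desk` (4 chains × 3000 iterations, burn-in 1000, thin 2 — 4000
retained draws) is the default used by every synthetic study in the test
suite and the acceptance script; `paper-protocol` (7 × 100 000, burn-in
10 000, thin 126) is a heavyweight protocol of the kind publication-grade
real-data analyses in this field run.

## Diagnostics and model comparison

`rhat` is the plain Brooks–Gelman–Rubin between/within form,
`sqrt(((n-1)/n W + B/n)/W)`, without rank normalization or chain
splitting — matching the diagnostic of the WinBUGS/R2WinBUGS era this
model family comes from.  Two identical chains therefore give
`sqrt((n-1)/n)`, marginally below 1.  `effective_sample_size` is a Geyer
initial-positive-sequence estimator on pooled chains.  The convergence
gates are R-hat < 1.1 and n.eff > 100 per monitored parameter.

DIC is `Dbar + p_D` with `p_D = Dbar − D(plug-in)`; the plug-in deviance
is evaluated at the posterior mean of each tract's `log theta` (the
linear-predictor scale), the WinBUGS convention for this class — `p_D` is
plug-in-dependent, so this choice is part of the reported definition.
Differences are annotated negligible (<3), moderate (3–7), clear (>7).

## Kriging

Under M3 the city coefficients are a finite sample of a stationary
Gaussian field, so for each retained draw `(b, beta, sigma, phi)` the
field at any grid of locations is an exact conditional MVN; sampling one
realization per draw yields predictive RR draws integrating over posterior
uncertainty.  There is no nugget — the model defines no micro-scale
variance — so the field interpolates city values exactly, and a grid point
within 1e-9 km of a city returns that city's draw directly rather than
inverting a near-singular system.  The per-location summaries (posterior
mean RR, posterior SD, `P(RR > 1)`, with strict inequality) depend only on
marginals, so the default path samples each location from its conditional
marginal; `joint=True` draws through the conditional Cholesky for
functionals that couple locations.

## The synthetic generator

`simulate_layout` scatters city centroids uniformly over a square region
with a minimum-separation rule and gives each city a rook-adjacency grid
lattice of tracts — the ICAR prior consumes topology, not geometry, so no
tract shapes are generated.  `simulate_dataset` then draws from the M3
generative model exactly as written above.

Default truth: `beta = 0.025` (pooled RR ≈ 1.025 per 1% covariate),
`sigma_2 = 0.02` so city RRs spread over roughly 0.96–1.04 with
informative but overlapping intervals, `sigma_1 = 0.2`, both decay
parameters set to a 400 km effective range inside a 1000 km region,
`sd_icar = 0.2`, `sd_het = 0.1`, `X ~ Uniform(5, 30)` percent and
`E ~ Uniform(0.5, 5)` — the scale of a six-year mortality series over
census tracts of a few hundred to a couple of thousand men.

What the generator does *not* emulate: real census-tract geographies and
their very uneven sizes, covariate spatial autocorrelation within cities,
and misspecification of any kind (the fitted model is exactly the
generative one).  Passing recovery tests therefore demonstrate the
estimator and sampler are correct and calibrated under the model, not
robustness to real-data violations of it.

Study sizes used by the test suite: recovery runs 20 replicates of
31 × 36 tracts; the DIC-ordering study uses 15 cities × 9 tracts with a
strong slope field (`sigma_2 = 0.1`, range = half the region); the
interval-shrinkage study uses 10 cities with one 6-tract city.  These are
the package's default desk-scale study sizes.

## Numerical choices and edge cases

* Likelihood evaluations clip nothing; overflowing `exp` yields `-inf`
  log-likelihood and the move is rejected.
* `Cholesky` failures of a proposed correlation matrix reject the move.
* SD conditionals with zero quadratic form fall back to the flat
  `Uniform(0, l)` draw.
* Expected counts must be strictly positive; zero-population strata get a
  zero rate with a warning, but nonzero deaths in a zero-population
  stratum are an error.
* Distances are km everywhere (projected coordinates, or haversine from
  lon/lat), so effective ranges read directly in km.

## Known limitations

* With ~30 cities a single realization carries limited information about
  `phi_2`; the posterior of the effective range remains noticeably
  prior-dependent, and its posterior mean is only a rough estimate of the
  generative range (the recovery study quantifies this).
* `sigma_Sj`/`sigma_Hj` are weakly identified in small cities (BYM
  aliasing); their chains are the slowest-mixing quantities and may need
  longer runs than the desk preset to clear the n.eff gate city-by-city.
* The sampler is sequential; chains are not parallelized.
* Adjacency must be supplied (or generated); the package does not derive
  it from polygon shapefiles.
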