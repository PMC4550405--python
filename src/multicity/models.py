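"""The three nested model variants and their joint log-posterior.

All variants share the first level: tract counts ``O_ij ~ Poisson(E_ij *
theta_ij)`` with ``log(theta_ij) = b1_j + b2_j * X_ij + S_ij + H_ij``, where
S is an ICAR spatial field and H iid Gaussian heterogeneity, each with its
own per-city standard deviation (the BYM decomposition).  The variants
differ only in the second level, the prior on the city coefficients:

* M1 — independent fixed effects: flat priors on every ``b1_j, b2_j``.
* M2 — exchangeable random effects: ``b1_j ~ N(alpha, sigma_b1^2)``,
  ``b2_j ~ N(beta, sigma_b2^2)``, conditionally independent across cities.
* M3 — geostatistical: ``b1 ~ MVN(alpha * 1, sigma1^2 exp(-phi1 D))`` and
  ``b2 ~ MVN(beta * 1, sigma2^2 exp(-phi2 D))``, so nearby cities borrow
  strength through the exponential distance-decay covariance.

``exp(b2_j)`` is the relative risk per one-point increase of the covariate
in city j; ``exp(beta)`` (M2/M3) is the pooled RR across cities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import lgamma

import numpy as np
from scipy import linalg

from .data import Adjacency, TractTable
from .priors import (
    ExpCovParams,
    IcarStructure,
    PriorConfig,
    exponential_covariance,
    icar_log_density,
    icar_structure,
)

__all__ = [
    "ModelSpec",
    "ModelState",
    "build_structures",
    "linear_predictor",
    "poisson_log_likelihood",
    "log_posterior",
    "city_rr",
    "pooled_rr",
]

VARIANTS = ("M1", "M2", "M3")


@dataclass(frozen=True)
class ModelSpec:
    """Which variant to fit, plus every prior hyperparameter."""

    variant: str
    prior_config: PriorConfig = field(default_factory=PriorConfig)
    decay_bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.variant == "M3" and self.decay_bounds is None:
            raise ValueError("M3 requires decay_bounds (a, b) for the phi priors")
        if self.variant != "M3" and self.decay_bounds is not None:
            raise ValueError(f"decay_bounds only apply to M3, not {self.variant}")


@dataclass
class ModelState:
    """One point in parameter space.

    ``icar`` and ``het`` are flat vectors aligned to TractTable rows;
    ``sd_icar`` / ``sd_het`` hold one SD per city.  ``cov1`` / ``cov2``
    (M3) carry the exponential-covariance parameters of the intercept and
    slope fields; ``sd_b1`` / ``sd_b2`` are their M2 counterparts.
    """

    b1: np.ndarray
    b2: np.ndarray
    icar: np.ndarray
    het: np.ndarray
    sd_icar: np.ndarray
    sd_het: np.ndarray
    alpha: float = 0.0
    beta: float = 0.0
    sd_b1: float | None = None
    sd_b2: float | None = None
    cov1: ExpCovParams | None = None
    cov2: ExpCovParams | None = None

    def copy(self) -> "ModelState":
        return replace(
            self,
            b1=self.b1.copy(),
            b2=self.b2.copy(),
            icar=self.icar.copy(),
            het=self.het.copy(),
            sd_icar=self.sd_icar.copy(),
            sd_het=self.sd_het.copy(),
        )


def build_structures(table: TractTable, adjacency: Adjacency) -> list[IcarStructure]:
    """One ICAR structure per city, node order matching the table's rows."""
    structures = []
    for city in table.cities:
        nodes = list(table.frame.loc[table.frame["city"] == city, "tract"])
        structures.append(icar_structure(adjacency.graphs[city], nodes))
    return structures


def linear_predictor(state: ModelState, table: TractTable) -> np.ndarray:
    """log theta_ij = b1_j + b2_j * X_ij + S_ij + H_ij, aligned to rows."""
    ci = table.city_index()
    J = table.n_cities
    if state.b1.shape[0] != J or state.b2.shape[0] != J:
        raise ValueError(f"coefficient vectors must have length J={J}")
    if state.icar.shape[0] != table.n_tracts or state.het.shape[0] != table.n_tracts:
        raise ValueError("field vectors must have one entry per tract")
    return state.b1[ci] + state.b2[ci] * table.covariate + state.icar + state.het


def poisson_log_likelihood(log_theta: np.ndarray, table: TractTable) -> float:
    """Full Poisson log likelihood sum_ij log Poisson(O_ij; E_ij theta_ij)."""
    O = table.observed
    E = table.expected
    if np.any(E <= 0):
        raise ValueError("expected counts must be > 0")
    log_theta = np.asarray(log_theta, dtype=float)
    if log_theta.shape[0] != O.shape[0]:
        raise ValueError("log_theta not aligned with table rows")
    log_mu = np.log(E) + log_theta
    const = sum(lgamma(o + 1.0) for o in O)
    return float(np.sum(O * log_mu - np.exp(log_mu)) - const)


def _mvn_logpdf(x: np.ndarray, mean: float, cov: np.ndarray) -> float:
    """Dense MVN log density via Cholesky (used for the M3 coefficient prior)."""
    dev = np.asarray(x, dtype=float) - mean
    L = linalg.cholesky(cov, lower=True)
    u = linalg.solve_triangular(L, dev, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return float(-0.5 * (u @ u) - 0.5 * logdet - 0.5 * len(dev) * np.log(2 * np.pi))


def _coef_prior_logdens(state: ModelState, spec: ModelSpec, D: np.ndarray | None) -> float:
    """Second-level prior on (b1, b2) plus (alpha, beta), variant-specific."""
    pc = spec.prior_config
    lp = 0.0
    if pc.coef_prior_sd is not None and spec.variant in ("M2", "M3"):
        s0 = pc.coef_prior_sd
        lp += -0.5 * (state.alpha**2 + state.beta**2) / s0**2 - 2 * np.log(s0)
    if spec.variant == "M1":
        return lp  # flat coefficient priors
    if spec.variant == "M2":
        for b, m, sd in ((state.b1, state.alpha, state.sd_b1), (state.b2, state.beta, state.sd_b2)):
            if sd is None:
                raise ValueError("M2 state requires sd_b1 and sd_b2")
            if not 0 < sd < pc.sd_upper:
                return -np.inf
            lp += float(
                -0.5 * np.sum((b - m) ** 2) / sd**2
                - len(b) * np.log(sd)
                - 0.5 * len(b) * np.log(2 * np.pi)
            )
        return lp
    # M3
    a, bnd = spec.decay_bounds
    for b, m, cov in ((state.b1, state.alpha, state.cov1), (state.b2, state.beta, state.cov2)):
        if cov is None:
            raise ValueError("M3 state requires cov1 and cov2")
        if not 0 < cov.sd < pc.sd_upper or not a < cov.decay < bnd:
            return -np.inf
        lp += _mvn_logpdf(b, m, exponential_covariance(D, cov))
    return lp


def log_posterior(
    state: ModelState,
    spec: ModelSpec,
    table: TractTable,
    structures: list[IcarStructure],
    D: np.ndarray | None = None,
) -> float:
    """Unnormalized joint log posterior; ``-inf`` outside the prior support."""
    if spec.variant == "M3" and D is None:
        raise ValueError("M3 requires the intercity distance matrix D")
    l = spec.prior_config.sd_upper
    if np.any(state.sd_icar <= 0) or np.any(state.sd_icar >= l):
        return -np.inf
    if np.any(state.sd_het <= 0) or np.any(state.sd_het >= l):
        return -np.inf

    lp = _coef_prior_logdens(state, spec, D)
    if not np.isfinite(lp):
        return -np.inf

    slices = list(table.city_slices().values())
    for j, (st, sl) in enumerate(zip(structures, slices)):
        s_j = state.icar[sl]
        lp += icar_log_density(s_j, st, state.sd_icar[j])
        h_j = state.het[sl]
        lp += float(
            -0.5 * np.sum(h_j**2) / state.sd_het[j] ** 2 - st.n * np.log(state.sd_het[j])
        )
    lp += poisson_log_likelihood(linear_predictor(state, table), table)
    return float(lp)


def _rr_summary(draws: np.ndarray) -> dict:
    rr = np.exp(np.asarray(draws, dtype=float))
    return {
        "rr": float(rr.mean()),
        "lo": float(np.quantile(rr, 0.025)),
        "hi": float(np.quantile(rr, 0.975)),
    }


def city_rr(b2_draws: np.ndarray, city_ids=None):
    """Posterior mean and equal-tailed 95% CI of exp(b2_j) per city.

    ``b2_draws`` has shape (n_draws, J); returns a DataFrame with one row
    per city (columns rr, lo, hi).
    """
    import pandas as pd

    b2_draws = np.atleast_2d(np.asarray(b2_draws, dtype=float))
    if b2_draws.shape[0] == 0:
        raise ValueError("no posterior draws")
    rows = [_rr_summary(b2_draws[:, j]) for j in range(b2_draws.shape[1])]
    idx = city_ids if city_ids is not None else list(range(b2_draws.shape[1]))
    return pd.DataFrame(rows, index=pd.Index(idx, name="city"))


def pooled_rr(beta_draws: np.ndarray, variant: str) -> dict:
    """Overall pooled RR exp(beta) with 95% CI; defined for M2/M3 only."""
    if variant == "M1":
        raise ValueError("M1 has no pooled effect: city coefficients are unrelated fixed effects")
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    beta_draws = np.asarray(beta_draws, dtype=float).ravel()
    if beta_draws.size == 0:
        raise ValueError("no posterior draws")
    return _rr_summary(beta_draws)
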