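"""MCMC inference, convergence diagnostics and DIC model comparison.

The sampler is a componentwise Gibbs sweep with three kinds of updates:

* elliptical slice sampling for every block with a Gaussian prior — the
  ICAR fields S (per-city covariance ``sigma_Sj^2 L_j^+`` on the
  sum-to-zero subspace), the heterogeneity fields H, and the city
  coefficient vectors b1, b2 under M2/M3 (rejection-free, no tuning);
* exact Gibbs draws where the full conditional is available in closed
  form — the second-level means alpha/beta (Gaussian, flat or normal
  prior) and every standard deviation with its Uniform(0, l) prior
  (truncated inverse-gamma);
* adaptive random-walk Metropolis for what remains — the flat-prior city
  coefficients of M1 (per-city proposals, conditionally independent) and
  the M3 covariance parameters (sigma, phi) jointly on the
  (log sigma, phi) scale.  Proposal scales adapt only during burn-in and
  are frozen afterwards, so the retained draws come from a fixed-kernel
  chain with the posterior invariant.

Convergence uses the plain Brooks-Gelman-Rubin potential scale reduction
factor (between/within variance form, no rank normalization) and an
initial-positive-sequence effective sample size, with the usual gates
R-hat < 1.1 and n.eff > 100 per monitored parameter.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, sparse, special

from ._samplers import ess_step, sample_sd_conditional
from .data import Adjacency, TractTable
from .models import (
    ModelSpec,
    ModelState,
    build_structures,
    linear_predictor,
    poisson_log_likelihood,
)
from .priors import ExpCovParams

__all__ = [
    "McmcSettings",
    "PosteriorDraws",
    "ConvergenceReport",
    "DicResult",
    "GibbsSampler",
    "run_mcmc",
    "rhat",
    "effective_sample_size",
    "check_convergence",
    "dic",
    "compare_models",
    "preset",
]


@dataclass(frozen=True)
class McmcSettings:
    """Chain-length bookkeeping; retained per chain = (n_iter - n_burnin) // thin."""

    n_chains: int = 4
    n_iter: int = 3000
    n_burnin: int = 1000
    thin: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.n_iter < 1 or self.thin < 1:
            raise ValueError("n_chains, n_iter and thin must be positive")
        if not 0 <= self.n_burnin < self.n_iter:
            raise ValueError("need 0 <= n_burnin < n_iter")
        if self.n_retained < 1:
            raise ValueError("settings retain zero draws per chain")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.n_burnin) // self.thin


#: Desk-scale default and the study protocol (7 x 100k, burn-in 10k, thin 126).
_PRESETS = {
    "desk": dict(n_chains=4, n_iter=3000, n_burnin=1000, thin=2),
    "paper-protocol": dict(n_chains=7, n_iter=100_000, n_burnin=10_000, thin=126),
}


def preset(name: str, seed: int = 0) -> McmcSettings:
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; have {sorted(_PRESETS)}")
    return McmcSettings(seed=seed, **_PRESETS[name])


@dataclass
class PosteriorDraws:
    """Thinned multi-chain draws plus what DIC and kriging need.

    ``params`` maps parameter family names to arrays of shape
    (n_chains, n_draws) for scalars or (n_chains, n_draws, J) for per-city
    vectors.  ``mean_log_theta`` is the posterior mean of the linear
    predictor per tract over all retained draws (the DIC plug-in point).
    """

    params: dict
    deviance: np.ndarray
    mean_log_theta: np.ndarray
    variant: str
    settings: McmcSettings
    city_ids: list
    fingerprint: str = ""

    def get(self, name: str, flat: bool = False) -> np.ndarray:
        arr = self.params[name]
        if flat:
            return arr.reshape(-1, *arr.shape[2:])
        return arr

    def scalar_draws(self) -> dict:
        """Expand vector families to scalar series '<family>[<city>]'."""
        out = {}
        for name, arr in self.params.items():
            if arr.ndim == 2:
                out[name] = arr
            else:
                for j in range(arr.shape[2]):
                    out[f"{name}[{self.city_ids[j]}]"] = arr[:, :, j]
        return out

    def save(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, arr in self.params.items():
            nc, nd = arr.shape[:2]
            idx = pd.MultiIndex.from_product([range(nc), range(nd)], names=["chain", "draw"])
            if arr.ndim == 2:
                df = pd.DataFrame({"value": arr.reshape(-1)}, index=idx)
            else:
                df = pd.DataFrame(
                    arr.reshape(nc * nd, -1), index=idx, columns=[str(c) for c in self.city_ids]
                )
            df.to_csv(outdir / f"{name}.csv")
        nc, nd = self.deviance.shape
        idx = pd.MultiIndex.from_product([range(nc), range(nd)], names=["chain", "draw"])
        pd.DataFrame({"value": self.deviance.reshape(-1)}, index=idx).to_csv(
            outdir / "deviance.csv"
        )
        pd.DataFrame({"mean_log_theta": self.mean_log_theta}).to_csv(
            outdir / "mean_log_theta.csv", index_label="row"
        )
        meta = {
            "variant": self.variant,
            "settings": {
                "n_chains": self.settings.n_chains,
                "n_iter": self.settings.n_iter,
                "n_burnin": self.settings.n_burnin,
                "thin": self.settings.thin,
                "seed": self.settings.seed,
            },
            "city_ids": [str(c) for c in self.city_ids],
            "fingerprint": self.fingerprint,
            "params": {k: list(v.shape) for k, v in self.params.items()},
        }
        (outdir / "meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, outdir) -> "PosteriorDraws":
        from pathlib import Path

        outdir = Path(outdir)
        meta = json.loads((outdir / "meta.json").read_text())
        settings = McmcSettings(**meta["settings"])
        params = {}
        for name, shape in meta["params"].items():
            df = pd.read_csv(outdir / f"{name}.csv", index_col=[0, 1])
            params[name] = df.to_numpy().reshape(shape)
        dev = pd.read_csv(outdir / "deviance.csv", index_col=[0, 1])["value"].to_numpy()
        nc = meta["settings"]["n_chains"]
        mlt = pd.read_csv(outdir / "mean_log_theta.csv", index_col=0)[
            "mean_log_theta"
        ].to_numpy()
        return cls(
            params=params,
            deviance=dev.reshape(nc, -1),
            mean_log_theta=mlt,
            variant=meta["variant"],
            settings=settings,
            city_ids=meta["city_ids"],
            fingerprint=meta.get("fingerprint", ""),
        )


@dataclass
class ConvergenceReport:
    table: pd.DataFrame  # index: parameter; columns: rhat, ess, pass
    rhat_max: float
    ess_min: float

    @property
    def all_pass(self) -> bool:
        return bool(self.table["pass"].all())

    def failures(self) -> list:
        return list(self.table.index[~self.table["pass"]])

    def to_text(self) -> str:
        head = f"convergence gates: rhat < {self.rhat_max}, ess > {self.ess_min}\n"
        verdict = "PASS" if self.all_pass else f"FAIL ({len(self.failures())} parameter(s))"
        return head + self.table.to_string() + f"\noverall: {verdict}\n"


@dataclass(frozen=True)
class DicResult:
    dbar: float
    d_at_mean: float

    @property
    def p_d(self) -> float:
        return self.dbar - self.d_at_mean

    @property
    def dic(self) -> float:
        return self.dbar + self.p_d


class GibbsSampler:
    """Single-chain sampler for one model variant on one dataset.

    Exposed (rather than hidden inside :func:`run_mcmc`) so that
    simulation-based calibration checks can interleave ``sweep`` with
    re-simulation of the data.
    """

    def __init__(
        self,
        table: TractTable,
        adjacency: Adjacency,
        spec: ModelSpec,
        D: np.ndarray | None = None,
        rng: np.random.Generator | int | None = None,
        prior_only: bool = False,
    ):
        if spec.variant == "M3" and D is None:
            raise ValueError("M3 requires the intercity distance matrix D")
        if prior_only:
            if spec.variant == "M1" or spec.prior_config.coef_prior_sd is None:
                raise ValueError(
                    "prior-only runs need a proper coefficient prior "
                    "(M2/M3 with coef_prior_sd set)"
                )
        self.table = table
        self.spec = spec
        self.D = None if D is None else np.asarray(D, dtype=float)
        self.rng = np.random.default_rng(rng)
        self.prior_only = prior_only

        self.structures = build_structures(table, adjacency)
        self.O = table.observed.astype(float)
        self.E = table.expected
        self.X = table.covariate
        self.ci = table.city_index()
        self.J = table.n_cities
        self.ntot = table.n_tracts
        self.slices = list(table.city_slices().values())
        self.nj = np.array([st.n for st in self.structures])
        self.icar_dof = np.array([st.rank for st in self.structures], dtype=float)
        self._lgamma_const = float(special.gammaln(self.O + 1.0).sum())
        self._logE = np.log(self.E)

        # sparse basis mapping standard normals to a unit-SD ICAR draw per city
        blocks = [st._eigvecs / np.sqrt(st._eigvals) for st in self.structures]
        self._icar_basis = sparse.block_diag(blocks, format="csr")
        self._n_eig = self._icar_basis.shape[1]
        # global block-diagonal Laplacian for fast per-city quadratic forms
        self._laplacian = sparse.block_diag(
            [st.laplacian for st in self.structures], format="csr"
        )

        l = spec.prior_config.sd_upper
        self.sd_upper = l
        self._coef_prior_sd = spec.prior_config.coef_prior_sd
        # adaptive RW scales
        self._scale_cov = np.full((2, 2), 0.1)  # M3: rows (cov1, cov2), cols (log sd, phi)
        if spec.variant == "M3":
            a, b = spec.decay_bounds
            self._scale_cov[:, 1] = (b - a) / 20.0
        self._adapt_t = 0
        self._chol_r = [None, None]  # cached Cholesky of exp(-phi D) for M3
        self._scale_shift = np.array([0.05, 0.005])  # translation moves on (alpha, beta)
        self._scale_rescale = np.full((2, self.J), 0.3)  # field/SD joint rescaling
        # per-city coefficient-pair proposals; the intercept component is
        # proposed as d1 = s1 z1 - xbar_j d2 to follow the intercept/slope
        # collinearity induced by an uncentered covariate
        self._scale_pair = np.vstack([np.full(self.J, 0.05), np.full(self.J, 0.01)])
        self._xbar = np.array(
            [self.X[sl].mean() for sl in self.slices]
        )
        self._rows = [
            (self.O[sl], self.E[sl], self.X[sl]) for sl in self.slices
        ]
        self._starts = np.array([sl.start for sl in self.slices], dtype=np.intp)

    # ---------------- likelihood helpers ----------------

    def set_observed(self, O: np.ndarray) -> None:
        """Replace the observed counts (simulation-based calibration hook)."""
        self.O = np.asarray(O, dtype=float)
        self._lgamma_const = float(special.gammaln(self.O + 1.0).sum())

    def _ll(self, eta: np.ndarray) -> float:
        if self.prior_only:
            return 0.0
        with np.errstate(over="ignore"):
            val = float(np.sum(self.O * eta - self.E * np.exp(eta)))
        return val if np.isfinite(val) else -np.inf

    def _ll_pointwise(self, eta: np.ndarray) -> np.ndarray:
        # exp overflow gives -inf terms directly (O*eta stays finite), so a
        # diverging proposal is rejected without a separate finiteness pass
        if self.prior_only:
            return np.zeros_like(eta)
        with np.errstate(over="ignore"):
            return self.O * eta - self.E * np.exp(eta)

    def _city_sums(self, t: np.ndarray) -> np.ndarray:
        # rows are grouped by city, so reduceat over block starts
        return np.add.reduceat(t, self._starts)

    def deviance(self, state: ModelState) -> float:
        eta = self._eta(state)
        ll = float(np.sum(self.O * (self._logE + eta) - self.E * np.exp(eta)))
        return -2.0 * (ll - self._lgamma_const)

    def _eta(self, state: ModelState) -> np.ndarray:
        return state.b1[self.ci] + state.b2[self.ci] * self.X + state.icar + state.het

    # ---------------- initialization ----------------

    def initial_state(self) -> ModelState:
        rng = self.rng
        if self.prior_only:
            return self._prior_state()
        sumO = np.bincount(self.ci, weights=self.O, minlength=self.J)
        sumE = np.bincount(self.ci, weights=self.E, minlength=self.J)
        b1 = np.log((sumO + 0.5) / sumE) + 0.2 * rng.standard_normal(self.J)
        b2 = 0.01 * rng.standard_normal(self.J)
        state = ModelState(
            b1=b1,
            b2=b2,
            icar=np.zeros(self.ntot),
            het=np.zeros(self.ntot),
            sd_icar=rng.uniform(0.05, 0.3, self.J),
            sd_het=rng.uniform(0.05, 0.3, self.J),
            alpha=float(b1.mean()),
            beta=float(b2.mean()),
        )
        if self.spec.variant == "M2":
            state.sd_b1 = float(rng.uniform(0.1, 0.5))
            state.sd_b2 = float(rng.uniform(0.02, 0.1))
        elif self.spec.variant == "M3":
            a, b = self.spec.decay_bounds
            state.cov1 = ExpCovParams(float(rng.uniform(0.1, 0.5)), float(rng.uniform(a, b)))
            state.cov2 = ExpCovParams(float(rng.uniform(0.02, 0.1)), float(rng.uniform(a, b)))
            self._refresh_chol(state)
        return state

    def _prior_state(self) -> ModelState:
        """Exact draw from the (proper) prior — seeds calibration runs."""
        rng = self.rng
        l = self.sd_upper
        s0 = self._coef_prior_sd
        alpha = float(rng.normal(0.0, s0))
        beta = float(rng.normal(0.0, s0))
        sd_icar = rng.uniform(0.0, l, self.J)
        sd_het = rng.uniform(0.0, l, self.J)
        icar = np.empty(self.ntot)
        for j, (st, sl) in enumerate(zip(self.structures, self.slices)):
            from .priors import sample_icar

            icar[sl] = sample_icar(st, max(sd_icar[j], 1e-12), rng)
        het = rng.standard_normal(self.ntot) * sd_het[self.ci]
        state = ModelState(
            b1=np.empty(self.J),
            b2=np.empty(self.J),
            icar=icar,
            het=het,
            sd_icar=sd_icar,
            sd_het=sd_het,
            alpha=alpha,
            beta=beta,
        )
        if self.spec.variant == "M2":
            state.sd_b1 = float(rng.uniform(0.0, l))
            state.sd_b2 = float(rng.uniform(0.0, l))
            state.b1 = alpha + state.sd_b1 * rng.standard_normal(self.J)
            state.b2 = beta + state.sd_b2 * rng.standard_normal(self.J)
        else:  # M3
            a, b = self.spec.decay_bounds
            state.cov1 = ExpCovParams(float(rng.uniform(0.0, l)), float(rng.uniform(a, b)))
            state.cov2 = ExpCovParams(float(rng.uniform(0.0, l)), float(rng.uniform(a, b)))
            self._refresh_chol(state)
            state.b1 = alpha + state.cov1.sd * (self._chol_r[0] @ rng.standard_normal(self.J))
            state.b2 = beta + state.cov2.sd * (self._chol_r[1] @ rng.standard_normal(self.J))
        return state

    def simulate_counts(self, state: ModelState, rng=None) -> np.ndarray:
        rng = self.rng if rng is None else rng
        return rng.poisson(self.E * np.exp(self._eta(state)))

    def _refresh_chol(self, state: ModelState) -> None:
        for k, cov in enumerate((state.cov1, state.cov2)):
            R = np.exp(-cov.decay * self.D)
            self._chol_r[k] = linalg.cholesky(R, lower=True)

    # ---------------- individual updates ----------------

    def _ess_field_percity(self, field: np.ndarray, nu: np.ndarray, base: np.ndarray) -> np.ndarray:
        """Elliptical slice update of a zero-mean field, one ellipse per city.

        Cities are conditionally independent in the likelihood, so each
        city runs its own bracket; the shrinking loop is vectorized with a
        mask over the cities still searching.  Guaranteed to terminate (the
        current point is always acceptable as the angle shrinks to zero).
        """
        rng = self.rng
        ll_cur = self._city_sums(self._ll_pointwise(base + field))
        logy = ll_cur + np.log(rng.uniform(size=self.J))
        theta = rng.uniform(0.0, 2.0 * np.pi, self.J)
        lo, hi = theta - 2.0 * np.pi, theta.copy()
        out = field.copy()
        active = np.ones(self.J, dtype=bool)
        rows = np.ones(self.ntot, dtype=bool)
        ci_a, field_a, nu_a, base_a = self.ci, field, nu, base
        O_a, E_a = self.O, self.E
        for _ in range(200):
            # evaluate only the rows of cities still searching
            ang = theta[ci_a]
            cand = field_a * np.cos(ang) + nu_a * np.sin(ang)
            eta = base_a + cand
            with np.errstate(over="ignore"):
                pt = O_a * eta - E_a * np.exp(eta)
            pt = np.where(np.isfinite(pt), pt, -np.inf)
            if self.prior_only:
                pt = np.zeros_like(pt)
            if ci_a is self.ci:
                ll = self._city_sums(pt)
            else:
                ll = np.bincount(ci_a, weights=pt, minlength=self.J)
            with np.errstate(invalid="ignore"):
                acc = active & (ll > logy)
            if acc.any():
                hit = acc[ci_a]
                idx = np.flatnonzero(rows)[hit] if rows is not None else hit
                out[idx] = cand[hit]
                active &= ~acc
            if not active.any():
                break
            neg = theta < 0
            lo = np.where(active & neg, theta, lo)
            hi = np.where(active & ~neg, theta, hi)
            theta = np.where(active, rng.uniform(size=self.J) * (hi - lo) + lo, theta)
            rows = active[self.ci]
            ci_a = self.ci[rows]
            field_a = field[rows]
            nu_a = nu[rows]
            base_a = base[rows]
            O_a = self.O[rows]
            E_a = self.E[rows]
        return out

    def _update_icar(self, state: ModelState) -> None:
        base = state.b1[self.ci] + state.b2[self.ci] * self.X + state.het
        z = self.rng.standard_normal(self._n_eig)
        nu = (self._icar_basis @ z) * state.sd_icar[self.ci]
        state.icar = self._ess_field_percity(state.icar, nu, base)

    def _update_het(self, state: ModelState) -> None:
        base = state.b1[self.ci] + state.b2[self.ci] * self.X + state.icar
        nu = self.rng.standard_normal(self.ntot) * state.sd_het[self.ci]
        state.het = self._ess_field_percity(state.het, nu, base)

    def _update_b_m1(self, state: ModelState, adapt: bool) -> None:
        """Vectorized per-city pair update of (b1_j, b2_j) under flat priors.

        Cities are conditionally independent given the fields, so per-city
        accept/reject decisions in parallel leave the posterior invariant.
        """
        base = state.icar + state.het
        d2 = self._scale_pair[1] * self.rng.standard_normal(self.J)
        d1 = self._scale_pair[0] * self.rng.standard_normal(self.J) - self._xbar * d2
        eta_old = state.b1[self.ci] + state.b2[self.ci] * self.X + base
        eta_new = eta_old + d1[self.ci] + d2[self.ci] * self.X
        with np.errstate(invalid="ignore"):
            d = self._ll_pointwise(eta_new) - self._ll_pointwise(eta_old)
            delta = self._city_sums(d)
        acc = np.log(self.rng.uniform(size=self.J)) < delta
        state.b1[acc] += d1[acc]
        state.b2[acc] += d2[acc]
        if adapt:
            g = 1.0 / np.sqrt(1.0 + self._adapt_t)
            self._scale_pair *= np.exp(g * (acc.astype(float) - 0.35))

    def _coef_precisions(self, state: ModelState):
        """Prior precision matrices of b1 and b2 (dense for M3, diagonal for M2)."""
        if self.spec.variant == "M2":
            P1 = np.diag(np.full(self.J, 1.0 / state.sd_b1**2))
            P2 = np.diag(np.full(self.J, 1.0 / state.sd_b2**2))
        else:
            I = np.eye(self.J)
            P1 = linalg.cho_solve((self._chol_r[0], True), I) / state.cov1.sd**2
            P2 = linalg.cho_solve((self._chol_r[1], True), I) / state.cov2.sd**2
        return P1, P2

    def _update_b_pairs(self, state: ModelState, adapt: bool) -> None:
        """Sequential per-city Metropolis scan of (b1_j, b2_j) for M2/M3.

        The Gaussian coefficient prior couples cities (M3), so cities are
        visited in order with the prior change computed exactly through the
        precision matrix (rank-one running updates of P (b - mean)).
        Complements the global ESS move, which by itself travels slowly for
        cities whose likelihood is much tighter than the prior.
        """
        P1, P2 = self._coef_precisions(state)
        r1 = P1 @ (state.b1 - state.alpha)
        r2 = P2 @ (state.b2 - state.beta)
        rng = self.rng
        d2 = self._scale_pair[1] * rng.standard_normal(self.J)
        d1 = self._scale_pair[0] * rng.standard_normal(self.J) - self._xbar * d2
        # likelihood deltas are per-city independent: vectorize them upfront
        eta = state.b1[self.ci] + state.b2[self.ci] * self.X + state.icar + state.het
        de = d1[self.ci] + d2[self.ci] * self.X
        with np.errstate(over="ignore", invalid="ignore"):
            t = self.O * de - self.E * (np.exp(eta + de) - np.exp(eta))
            dlik = self._city_sums(t)
        lu = np.log(rng.uniform(size=self.J))
        accs = np.zeros(self.J)
        for j in range(self.J):
            dprior = -(d1[j] * r1[j] + 0.5 * d1[j] ** 2 * P1[j, j]) - (
                d2[j] * r2[j] + 0.5 * d2[j] ** 2 * P2[j, j]
            )
            if lu[j] < dlik[j] + dprior:
                state.b1[j] += d1[j]
                state.b2[j] += d2[j]
                r1 += d1[j] * P1[:, j]
                r2 += d2[j] * P2[:, j]
                accs[j] = 1.0
        if adapt:
            g = 1.0 / np.sqrt(1.0 + self._adapt_t)
            self._scale_pair *= np.exp(g * (accs - 0.35))

    def _update_b_gauss(self, state: ModelState) -> None:
        """ESS update of b1, b2 under their Gaussian (M2/M3) priors."""
        base = state.icar + state.het
        if self.spec.variant == "M2":
            noises = (
                lambda: self.rng.standard_normal(self.J) * state.sd_b1,
                lambda: self.rng.standard_normal(self.J) * state.sd_b2,
            )
        else:
            noises = (
                lambda: state.cov1.sd * (self._chol_r[0] @ self.rng.standard_normal(self.J)),
                lambda: state.cov2.sd * (self._chol_r[1] @ self.rng.standard_normal(self.J)),
            )
        ll_b1 = lambda b: self._ll(b[self.ci] + state.b2[self.ci] * self.X + base)
        state.b1, _ = ess_step(state.b1, state.alpha, noises[0], ll_b1, self.rng)
        ll_b2 = lambda b: self._ll(state.b1[self.ci] + b[self.ci] * self.X + base)
        state.b2, _ = ess_step(state.b2, state.beta, noises[1], ll_b2, self.rng)

    def _update_means(self, state: ModelState) -> None:
        """Exact Gibbs draw of alpha and beta from their Gaussian conditionals."""
        prior_prec = 0.0 if self._coef_prior_sd is None else self._coef_prior_sd**-2
        for k, (b, attr) in enumerate(((state.b1, "alpha"), (state.b2, "beta"))):
            if self.spec.variant == "M2":
                sd = state.sd_b1 if k == 0 else state.sd_b2
                prec = self.J / sd**2 + prior_prec
                num = b.sum() / sd**2
            else:
                cov = state.cov1 if k == 0 else state.cov2
                L = self._chol_r[k]
                w = linalg.solve_triangular(L, np.ones(self.J), lower=True)
                v = linalg.solve_triangular(L, b, lower=True)
                prec = (w @ w) / cov.sd**2 + prior_prec
                num = (w @ v) / cov.sd**2
            mean = num / prec
            setattr(state, attr, float(self.rng.normal(mean, 1.0 / np.sqrt(prec))))

    def _rebalance_intercepts(self, state: ModelState) -> None:
        """Exact Gibbs move between each city intercept and its H-field mean.

        b1_j and the per-city mean of H are aliased (the likelihood sees
        only their sum), which stalls the centered sampler.  Shifting
        ``b1_j += delta_j, H_j -= delta_j`` leaves the likelihood invariant
        and the conditional of delta_j under the two Gaussian priors is
        itself Gaussian, so it can be drawn exactly (sequentially over
        cities for M3, whose coefficient prior couples them).
        """
        if self.spec.variant == "M1":
            # flat b1 prior: the conditional shift is exactly the H mean
            # plus Gaussian noise, independent across cities
            hbar = self._city_sums(state.het) / self.nj
            delta = hbar + state.sd_het / np.sqrt(self.nj) * self.rng.standard_normal(self.J)
            state.b1 += delta
            state.het -= delta[self.ci]
            return
        if self.spec.variant == "M2":
            prec_b = np.full(self.J, 1.0 / state.sd_b1**2)
            r = (state.b1 - state.alpha) / state.sd_b1**2
            P = None
        else:
            L = self._chol_r[0]
            Rinv = linalg.cho_solve((L, True), np.eye(self.J))
            P = Rinv / state.cov1.sd**2
            prec_b = np.diag(P)
            r = P @ (state.b1 - state.alpha)
        hsum = self._city_sums(state.het)
        z = self.rng.standard_normal(self.J)
        for j, sl in enumerate(self.slices):
            prec_h = self.nj[j] / state.sd_het[j] ** 2
            prec = prec_h + prec_b[j]
            mean = (hsum[j] / state.sd_het[j] ** 2 - r[j]) / prec
            delta = mean + z[j] / np.sqrt(prec)
            state.b1[j] += delta
            state.het[sl] -= delta
            if P is None:
                r[j] += delta * prec_b[j]
            else:
                r += delta * P[:, j]

    def _update_shifts(self, state: ModelState, adapt: bool) -> None:
        """Non-centered translation Metropolis on alpha and beta (M2/M3).

        Holding the deviations b - mean fixed, a shift of the mean moves
        every city coefficient with it; the prior of the deviations is
        unchanged and acceptance is governed by the likelihood (and the
        optional proper prior on the mean).  This breaks the slow coupling
        between the mean and its field in the centered sweep.
        """
        base = state.icar + state.het
        eta = state.b1[self.ci] + state.b2[self.ci] * self.X + base
        ll_cur = self._ll(eta)
        for k in range(2):
            delta = self._scale_shift[k] * self.rng.standard_normal()
            if k == 0:
                ll_new = self._ll(eta + delta)
            else:
                ll_new = self._ll(eta + delta * self.X)
            logr = ll_new - ll_cur
            if self._coef_prior_sd is not None:
                m = state.alpha if k == 0 else state.beta
                s0 = self._coef_prior_sd
                logr += (m**2 - (m + delta) ** 2) / (2 * s0**2)
            accepted = np.log(self.rng.uniform()) < logr
            if accepted:
                if k == 0:
                    state.alpha += delta
                    state.b1 += delta
                    eta = eta + delta
                else:
                    state.beta += delta
                    state.b2 += delta
                    eta = eta + delta * self.X
                ll_cur = ll_new
            if adapt:
                g = 1.0 / np.sqrt(1.0 + self._adapt_t)
                self._scale_shift[k] *= np.exp(g * (float(accepted) - 0.44))

    def _rescale_fields(self, state: ModelState, adapt: bool) -> None:
        """Joint rescaling of each city's field and its SD (ancillary move).

        In the non-centered parameterization (U = field / sd, sd) the
        Uniform(0, l) prior on the SD and the unit-scale field prior are
        both invariant under ``sd' = sd e^eps, field' = field e^eps``; a
        log-scale random walk there has acceptance  Delta loglik + eps
        (the +eps being the log-uniform Jacobian), vectorized over cities,
        which are conditionally independent in the likelihood.  Breaks the
        tight coupling between each field and its SD that stalls the
        centered Gibbs draw.
        """
        base_b = state.b1[self.ci] + state.b2[self.ci] * self.X
        for which in range(2):
            field = state.icar if which == 0 else state.het
            sds = state.sd_icar if which == 0 else state.sd_het
            other = state.het if which == 0 else state.icar
            eps = self._scale_rescale[which] * self.rng.standard_normal(self.J)
            new_sd = sds * np.exp(eps)
            eta_old = base_b + field + other
            eta_new = base_b + field * np.exp(eps)[self.ci] + other
            with np.errstate(invalid="ignore"):
                d = self._ll_pointwise(eta_new) - self._ll_pointwise(eta_old)
                delta = self._city_sums(d)
            ok = new_sd < self.sd_upper
            acc = ok & (np.log(self.rng.uniform(size=self.J)) < delta + eps)
            if acc.any():
                field *= np.where(acc, np.exp(eps), 1.0)[self.ci]
                sds[acc] = new_sd[acc]
            if adapt:
                g = 1.0 / np.sqrt(1.0 + self._adapt_t)
                self._scale_rescale[which] *= np.exp(g * (acc.astype(float) - 0.44))

    def _update_field_sds(self, state: ModelState) -> None:
        Ls = self._laplacian @ state.icar
        q_icar = np.bincount(self.ci, weights=state.icar * Ls, minlength=self.J)
        q_icar = np.maximum(q_icar, 0.0)
        state.sd_icar = sample_sd_conditional(q_icar, self.icar_dof, self.sd_upper, self.rng)
        q_het = np.bincount(self.ci, weights=state.het**2, minlength=self.J)
        state.sd_het = sample_sd_conditional(
            q_het, self.nj.astype(float), self.sd_upper, self.rng
        )

    def _update_hyper_m2(self, state: ModelState) -> None:
        q1 = float(np.sum((state.b1 - state.alpha) ** 2))
        q2 = float(np.sum((state.b2 - state.beta) ** 2))
        state.sd_b1 = float(sample_sd_conditional(q1, self.J, self.sd_upper, self.rng))
        state.sd_b2 = float(sample_sd_conditional(q2, self.J, self.sd_upper, self.rng))

    def _cov_logtarget(self, b, mean, sd, chol_r) -> float:
        u = linalg.solve_triangular(chol_r, b - mean, lower=True)
        return float(
            -0.5 * (u @ u) / sd**2
            - self.J * np.log(sd)
            - np.sum(np.log(np.diag(chol_r)))
        )

    def _update_cov_m3(self, state: ModelState, adapt: bool) -> None:
        a, bnd = self.spec.decay_bounds
        for k in range(2):
            cov = state.cov1 if k == 0 else state.cov2
            b = state.b1 if k == 0 else state.b2
            mean = state.alpha if k == 0 else state.beta
            s_log_sd, s_phi = self._scale_cov[k]
            new_sd = cov.sd * np.exp(s_log_sd * self.rng.standard_normal())
            new_phi = cov.decay + s_phi * self.rng.standard_normal()
            accepted = False
            if 0.0 < new_sd < self.sd_upper and a < new_phi < bnd:
                try:
                    Lnew = linalg.cholesky(np.exp(-new_phi * self.D), lower=True)
                except linalg.LinAlgError:
                    Lnew = None
                if Lnew is not None:
                    # Jacobian of the log-sd proposal under the uniform prior on sd
                    cur = self._cov_logtarget(b, mean, cov.sd, self._chol_r[k]) + np.log(cov.sd)
                    new = self._cov_logtarget(b, mean, new_sd, Lnew) + np.log(new_sd)
                    if np.log(self.rng.uniform()) < new - cur:
                        accepted = True
                        newcov = ExpCovParams(float(new_sd), float(new_phi), cov.bounds)
                        if k == 0:
                            state.cov1 = newcov
                        else:
                            state.cov2 = newcov
                        self._chol_r[k] = Lnew
            if adapt:
                g = 1.0 / np.sqrt(1.0 + self._adapt_t)
                self._scale_cov[k] *= np.exp(g * (float(accepted) - 0.3))

    # ---------------- the sweep ----------------

    def sweep(self, state: ModelState, adapt: bool = False) -> None:
        self._adapt_t += 1
        self._update_icar(state)
        self._update_het(state)
        if self.spec.variant == "M1":
            self._update_b_m1(state, adapt)
        else:
            # the global prior-ellipse move complements the per-city scan;
            # alternating sweeps halves its cost at no mixing loss
            if self.prior_only or self._adapt_t % 2 == 0:
                self._update_b_gauss(state)
            if not self.prior_only:
                self._update_b_pairs(state, adapt)
            self._update_means(state)
            if not self.prior_only:
                self._update_shifts(state, adapt)
        if not self.prior_only:
            self._rebalance_intercepts(state)
        self._update_field_sds(state)
        if not self.prior_only:
            self._rescale_fields(state, adapt)
        if self.spec.variant == "M2":
            self._update_hyper_m2(state)
        elif self.spec.variant == "M3":
            self._update_cov_m3(state, adapt)


def _alloc(variant: str, nc: int, nd: int, J: int) -> dict:
    out = {
        "b1": np.empty((nc, nd, J)),
        "b2": np.empty((nc, nd, J)),
        "sd_icar": np.empty((nc, nd, J)),
        "sd_het": np.empty((nc, nd, J)),
    }
    if variant in ("M2", "M3"):
        out["alpha"] = np.empty((nc, nd))
        out["beta"] = np.empty((nc, nd))
    if variant == "M2":
        out["sd_b1"] = np.empty((nc, nd))
        out["sd_b2"] = np.empty((nc, nd))
    if variant == "M3":
        for nm in ("sigma1", "phi1", "sigma2", "phi2"):
            out[nm] = np.empty((nc, nd))
    return out


def run_mcmc(
    table: TractTable,
    adjacency: Adjacency,
    spec: ModelSpec,
    settings: McmcSettings,
    D: np.ndarray | None = None,
    prior_only: bool = False,
    progress: callable | None = None,
) -> PosteriorDraws:
    """Sample the posterior of one model variant; deterministic given the seed.

    A single master seed spawns one independent stream per chain; chains run
    sequentially.  Retained draws per chain = (n_iter - n_burnin) // thin.
    """
    nd = settings.n_retained
    nc = settings.n_chains
    J = table.n_cities
    params = _alloc(spec.variant, nc, nd, J)
    deviance = np.empty((nc, nd))
    sum_log_theta = np.zeros(table.n_tracts)

    streams = np.random.SeedSequence(settings.seed).spawn(nc)
    for c in range(nc):
        sampler = GibbsSampler(
            table, adjacency, spec, D=D, rng=np.random.default_rng(streams[c]),
            prior_only=prior_only,
        )
        state = sampler.initial_state()
        k = 0
        for t in range(1, settings.n_iter + 1):
            sampler.sweep(state, adapt=t <= settings.n_burnin)
            if t > settings.n_burnin and (t - settings.n_burnin) % settings.thin == 0:
                params["b1"][c, k] = state.b1
                params["b2"][c, k] = state.b2
                params["sd_icar"][c, k] = state.sd_icar
                params["sd_het"][c, k] = state.sd_het
                if spec.variant in ("M2", "M3"):
                    params["alpha"][c, k] = state.alpha
                    params["beta"][c, k] = state.beta
                if spec.variant == "M2":
                    params["sd_b1"][c, k] = state.sd_b1
                    params["sd_b2"][c, k] = state.sd_b2
                if spec.variant == "M3":
                    params["sigma1"][c, k] = state.cov1.sd
                    params["phi1"][c, k] = state.cov1.decay
                    params["sigma2"][c, k] = state.cov2.sd
                    params["phi2"][c, k] = state.cov2.decay
                deviance[c, k] = sampler.deviance(state)
                sum_log_theta += sampler._eta(state)
                k += 1
        if progress is not None:
            progress(c + 1, nc)

    return PosteriorDraws(
        params=params,
        deviance=deviance,
        mean_log_theta=sum_log_theta / (nc * nd),
        variant=spec.variant,
        settings=settings,
        city_ids=table.cities,
        fingerprint=table.fingerprint(),
    )


# ---------------- diagnostics ----------------


def rhat(chains: np.ndarray) -> float:
    """Brooks-Gelman-Rubin potential scale reduction factor.

    Plain between/within form: with m chains of n draws,
    ``sqrt(((n-1)/n W + B/n) / W)``.  Identical chains give
    ``sqrt((n-1)/n)`` (marginally below 1); no rank normalization or
    chain splitting is applied.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need at least 2 chains (rows)")
    if chains.shape[1] < 2:
        raise ValueError("need at least 2 draws per chain")
    n = chains.shape[1]
    W = chains.var(axis=1, ddof=1).mean()
    B_over_n = chains.mean(axis=1).var(ddof=1)
    var_plus = (n - 1) / n * W + B_over_n
    if W == 0:
        return 1.0 if var_plus == 0 else np.inf
    return float(np.sqrt(var_plus / W))


def effective_sample_size(chains: np.ndarray) -> float:
    """Autocorrelation-adjusted ESS (Geyer initial positive sequence).

    Accepts (n,) or (m, n).  A constant input is degenerate for the
    estimator; it is reported as the total draw count with a warning.
    """
    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    m, n = chains.shape
    total = m * n
    if np.ptp(chains) == 0:
        warnings.warn("degenerate (constant) chain; reporting ESS = total draws", stacklevel=2)
        return float(total)
    # per-chain autocovariances via FFT
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    dev = chains - chains.mean(axis=1, keepdims=True)
    f = np.fft.rfft(dev, nfft, axis=1)
    acov = np.fft.irfft(f * np.conj(f), nfft, axis=1)[:, :n].real / n
    W = chains.var(axis=1, ddof=1).mean()
    var_plus = (n - 1) / n * W + (chains.mean(axis=1).var(ddof=1) if m > 1 else 0.0)
    if var_plus == 0:
        return float(total)
    rho = 1.0 - (W - acov.mean(axis=0)) / var_plus  # rho[0] == acov0/var_plus-ish
    # Geyer: sum rho_t over pairs (rho_{2k}+rho_{2k+1}) while the pair sum > 0
    tau = 1.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        tau += 2.0 * pair
        t += 2
    return float(total / max(tau, 1e-12))


def check_convergence(
    draws: PosteriorDraws, rhat_max: float = 1.1, ess_min: float = 100.0
) -> ConvergenceReport:
    """Per-parameter R-hat / ESS verdicts over every monitored scalar."""
    rows = {}
    for name, series in draws.scalar_draws().items():
        if series.shape[0] >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = rhat(series) if np.ptp(series) > 0 else 1.0
                e = effective_sample_size(series)
        else:
            r, e = np.nan, effective_sample_size(series)
        rows[name] = {"rhat": r, "ess": e, "pass": bool(r < rhat_max and e > ess_min)}
    return ConvergenceReport(
        table=pd.DataFrame.from_dict(rows, orient="index"), rhat_max=rhat_max, ess_min=ess_min
    )


def dic(draws: PosteriorDraws, table: TractTable) -> DicResult:
    """Deviance information criterion with the linear-predictor plug-in.

    ``Dbar`` is the mean of the per-draw deviances; the plug-in deviance is
    evaluated at the posterior mean of each tract's log relative risk
    (WinBUGS's convention for this model class, on which p_D depends).
    """
    if draws.deviance.size == 0:
        raise ValueError("no deviance draws available")
    dbar = float(draws.deviance.mean())
    d_at_mean = -2.0 * poisson_log_likelihood(draws.mean_log_theta, table)
    return DicResult(dbar=dbar, d_at_mean=d_at_mean)


_BANDS = ((3.0, "negligible"), (7.0, "moderate"), (np.inf, "clear"))


def dic_difference_band(delta: float) -> str:
    """Qualitative support bands: <3 negligible, 3-7 moderate, >7 clear."""
    delta = abs(delta)
    for cut, name in _BANDS:
        if delta < cut or (name == "moderate" and delta <= cut):
            return name
    return "clear"


def compare_models(results: list) -> pd.DataFrame:
    """Rank (label, DicResult) pairs by DIC with difference bands vs the best."""
    if len(results) < 2:
        raise ValueError("need at least two models to compare")
    rows = []
    for label, res in results:
        rows.append(
            {"model": label, "dic": res.dic, "dbar": res.dbar, "p_d": res.p_d}
        )
    df = pd.DataFrame(rows).sort_values("dic", kind="stable").reset_index(drop=True)
    best = df.loc[0, "dic"]
    df["delta_dic"] = df["dic"] - best
    df["band"] = [dic_difference_band(d) for d in df["delta_dic"]]
    df.loc[0, "band"] = "-"
    return df
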