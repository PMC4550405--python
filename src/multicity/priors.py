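"""Spatial prior building blocks.

Two kinds of spatial structure coexist in the model.  Within each city the
tract-level field S follows an intrinsic conditional autoregressive (ICAR)
prior: an improper Gaussian whose quadratic form penalizes squared
differences between adjacent tracts.  It is invariant to level shifts, so it
is identified by a sum-to-zero constraint per connected component, and its
normalizing exponent uses the rank ``n - c`` of the graph Laplacian (``c``
connected components).  Between cities, coefficients follow a stationary
Gaussian field with exponential distance-decay covariance
``sigma^2 * exp(-phi * d)``; the effective range ``R = -ln(0.05)/phi`` is
the distance at which correlation falls to 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "PriorConfig",
    "ExpCovParams",
    "IcarStructure",
    "icar_structure",
    "icar_log_density",
    "sample_icar",
    "exponential_covariance",
    "effective_range",
    "decay_to_range",
    "decay_bounds",
    "range_to_decay_bounds",
]


@dataclass(frozen=True)
class PriorConfig:
    """Hyperparameters shared by all model variants.

    ``sd_upper`` is ``l``, the common upper limit of the Uniform(0, l)
    priors on every standard deviation; it must be vague relative to the
    log-relative-risk scale (default 10).  ``coef_prior_sd``, if set,
    replaces the flat prior on the second-level means alpha and beta with a
    proper Normal(0, coef_prior_sd^2) — used for prior-predictive and
    sampler-validation runs, never needed for data analysis.
    """

    sd_upper: float = 10.0
    coef_prior_sd: float | None = None

    def __post_init__(self) -> None:
        if self.sd_upper <= 0:
            raise ValueError("sd_upper (l) must be > 0")
        if self.coef_prior_sd is not None and self.coef_prior_sd <= 0:
            raise ValueError("coef_prior_sd must be > 0 when set")


@dataclass(frozen=True)
class ExpCovParams:
    """Marginal SD and distance-decay rate of an exponential covariance."""

    sd: float
    decay: float
    bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be > 0")
        if self.decay <= 0:
            raise ValueError("decay must be > 0")
        if self.bounds is not None:
            a, b = self.bounds
            if not (0 < a < b):
                raise ValueError("decay bounds must satisfy 0 < a < b")


class IcarStructure:
    """Precomputed graph quantities for one city's ICAR field.

    Holds the Laplacian, component labels, rank ``n - c``, and the
    eigen-basis of the Laplacian restricted to its row space — enough to
    evaluate the (improper) log density and to draw constrained samples.
    Node order follows the ``nodes`` list passed at construction so that
    vector entries align with tract rows.
    """

    def __init__(self, graph: nx.Graph, nodes: list | None = None):
        self.nodes = list(nodes) if nodes is not None else sorted(graph.nodes())
        if set(self.nodes) != set(graph.nodes()):
            raise ValueError("node list does not match graph nodes")
        n = len(self.nodes)
        idx = {t: i for i, t in enumerate(self.nodes)}
        L = np.zeros((n, n))
        for a, b in graph.edges():
            i, j = idx[a], idx[b]
            L[i, i] += 1.0
            L[j, j] += 1.0
            L[i, j] -= 1.0
            L[j, i] -= 1.0
        self.n = n
        self.laplacian = L
        comps = list(nx.connected_components(graph))
        self.n_components = len(comps)
        self.component_of = np.empty(n, dtype=np.int64)
        for k, comp in enumerate(comps):
            for t in comp:
                self.component_of[idx[t]] = k
        self.rank = n - self.n_components
        # eigen-basis of the positive eigenspace (for sampling / oracle-free density)
        w, V = np.linalg.eigh(L)
        pos = w > 1e-10 * max(1.0, w.max() if n else 1.0)
        self._eigvals = w[pos]
        self._eigvecs = V[:, pos]

    def quadratic_form(self, s: np.ndarray) -> float:
        s = np.asarray(s, dtype=float)
        return float(s @ self.laplacian @ s)

    def center(self, s: np.ndarray) -> np.ndarray:
        """Remove the per-component mean (the ICAR null space)."""
        s = np.asarray(s, dtype=float).copy()
        for k in range(self.n_components):
            m = self.component_of == k
            s[m] -= s[m].mean()
        return s


def icar_structure(graph: nx.Graph, nodes: list | None = None) -> IcarStructure:
    return IcarStructure(graph, nodes)


def icar_log_density(s: np.ndarray, structure: IcarStructure, sd: float) -> float:
    """ICAR log density up to the improper prior's constant.

    ``-(1/(2 sd^2)) * sum_{i~k} (s_i - s_k)^2 - ((n - c)/2) * log(sd^2)``
    with one term per undirected edge and ``c`` connected components
    (isolated tracts contribute nothing).
    """
    if sd <= 0:
        raise ValueError("sd must be > 0")
    s = np.asarray(s, dtype=float)
    if s.shape[0] != structure.n:
        raise ValueError(f"vector length {s.shape[0]} != {structure.n} tracts")
    q = structure.quadratic_form(s)
    return -q / (2.0 * sd**2) - 0.5 * structure.rank * np.log(sd**2)


def sample_icar(
    structure: IcarStructure, sd: float, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Draw an ICAR field constrained to sum to zero per connected component.

    The draw is Gaussian with covariance ``sd^2 * pinv(L)`` on the
    orthogonal complement of the Laplacian null space: ``s = sd * V
    Lambda^{-1/2} z`` over the positive eigenpairs.
    """
    if sd <= 0:
        raise ValueError("sd must be > 0")
    rng = np.random.default_rng(rng)
    z = rng.standard_normal(structure._eigvals.shape[0])
    s = structure._eigvecs @ (z / np.sqrt(structure._eigvals)) * sd
    # exact re-centering guards against eigvec round-off
    return structure.center(s)


def exponential_covariance(D: np.ndarray, params: ExpCovParams) -> np.ndarray:
    """Covariance matrix ``sd^2 * exp(-decay * D)`` elementwise."""
    D = np.asarray(D, dtype=float)
    if not np.all(np.isfinite(D)):
        raise ValueError("distance matrix contains non-finite entries")
    if D.ndim != 2 or D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("D must be square and symmetric")
    return params.sd**2 * np.exp(-params.decay * D)


def effective_range(decay: float) -> float:
    """Distance (km) at which exponential correlation decays to 0.05."""
    if decay <= 0:
        raise ValueError("decay must be > 0")
    return -np.log(0.05) / decay


def decay_to_range(decay):
    """Vectorized alias of :func:`effective_range` for posterior draws."""
    decay = np.asarray(decay, dtype=float)
    if np.any(decay <= 0):
        raise ValueError("decay must be > 0")
    return -np.log(0.05) / decay


def range_to_decay_bounds(range_min_km: float, range_max_km: float) -> tuple[float, float]:
    """Uniform phi support expressed as an effective-range interval.

    Returns (a, b) such that phi in (a, b) corresponds to effective ranges
    between ``range_min_km`` and ``range_max_km``.  This is the natural
    parameterization when prior knowledge is about how far spatial
    dependence should reach (e.g. "anywhere from the closest city pair to
    the region diameter"); :func:`decay_bounds` instead constrains the
    extreme pairwise correlations directly.
    """
    if not 0 < range_min_km < range_max_km:
        raise ValueError("need 0 < range_min_km < range_max_km")
    return (-np.log(0.05) / range_max_km, -np.log(0.05) / range_min_km)


def decay_bounds(
    D: np.ndarray, rho_lo: float = 0.01, rho_hi: float = 0.99
) -> tuple[float, float]:
    """Support (a, b) for the uniform prior on the decay parameter phi.

    Chosen so that across phi in (a, b) the correlation between the closest
    city pair stays at most ``rho_hi`` and between the farthest pair at
    least ``rho_lo`` — keeping the covariance away from singular (all
    correlations ~1) and from numerically irrelevant (all ~0) regimes.
    When the two requirements conflict (very disparate distances), the
    interval is clamped to the widest one in which each constraint is met
    by at least one pair, with a warning.
    """
    if not (0 < rho_lo < rho_hi < 1):
        raise ValueError("need 0 < rho_lo < rho_hi < 1")
    D = np.asarray(D, dtype=float)
    off = D[~np.eye(D.shape[0], dtype=bool)]
    if off.size == 0 or np.all(off <= 0):
        raise ValueError("degenerate distance matrix: no positive intercity distances")
    d_min, d_max = float(off.min()), float(off.max())
    a = -np.log(rho_hi) / d_min
    b = -np.log(rho_lo) / d_max
    if not a < b:
        a2 = -np.log(rho_hi) / d_max
        b2 = -np.log(rho_lo) / d_min
        warnings.warn(
            "decay bounds jointly infeasible for this distance spread; "
            f"clamping to ({a2:.3g}, {b2:.3g})",
            stacklevel=2,
        )
        a, b = a2, b2
    return float(a), float(b)
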