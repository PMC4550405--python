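"""Bayesian kriging of city-level coefficients onto a prediction grid.

Under M3 the city slopes b2 (and intercepts b1) are a finite sample of a
stationary Gaussian random field with mean beta (alpha) and exponential
distance-decay covariance.  For every retained posterior draw, the field at
unobserved locations given that draw's city values is an exact conditional
multivariate normal; sampling one realization per draw yields predictive
draws that integrate over the posterior uncertainty of (b, beta, sigma,
phi).  There is no nugget: the model defines no micro-scale variance, so
the predictive field interpolates the city coefficients exactly.

Per-location summaries (posterior mean RR, posterior SD of the RR, and
P(RR > 1)) depend only on the per-location marginals, so the default path
samples each grid point from its conditional marginal; ``joint=True``
draws jointly via the conditional Cholesky (needed only for functionals
coupling several locations, and what the exactness tests exercise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .data import CityGeo
from .inference import PosteriorDraws

__all__ = [
    "PredictionGrid",
    "SurfaceSummary",
    "make_grid",
    "conditional_moments",
    "krige_coefficient",
    "predict_surface",
]

ZERO_DIST_KM = 1e-9  # grid points closer than this to a city reuse the city draw


@dataclass(frozen=True)
class PredictionGrid:
    """Prediction locations in the same coordinate system as the cities."""

    locations: np.ndarray  # (G, 2)
    dx: float | None = None
    dy: float | None = None

    def __post_init__(self) -> None:
        loc = np.asarray(self.locations, dtype=float)
        if loc.ndim != 2 or loc.shape[1] != 2 or loc.shape[0] == 0:
            raise ValueError("locations must be a nonempty (G, 2) array")
        if not np.all(np.isfinite(loc)):
            raise ValueError("locations must be finite")
        object.__setattr__(self, "locations", loc)

    @property
    def n_points(self) -> int:
        return self.locations.shape[0]


@dataclass(frozen=True)
class SurfaceSummary:
    """Per-location posterior summaries of the predicted relative risk."""

    frame: pd.DataFrame  # columns: x, y, rr_mean, rr_sd, prob_gt1

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def to_geojson(self, path) -> None:
        import json

        feats = []
        for _, row in self.frame.iterrows():
            feats.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [row["x"], row["y"]]},
                    "properties": {
                        "rr_mean": row["rr_mean"],
                        "rr_sd": row["rr_sd"],
                        "prob_gt1": row["prob_gt1"],
                    },
                }
            )
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)


def make_grid(
    bbox: tuple[float, float, float, float],
    dx: float,
    dy: float,
    mask=None,
) -> PredictionGrid:
    """Regular lattice over a bounding box, row-major, optionally masked.

    ``mask`` is any shapely polygon (or object with ``contains``); points
    outside it are dropped.  An empty result raises.
    """
    xmin, xmax, ymin, ymax = bbox
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("bounding box is degenerate")
    if dx <= 0 or dy <= 0:
        raise ValueError("grid spacings must be positive")
    xs = np.arange(xmin, xmax + dx * 1e-9, dx)
    ys = np.arange(ymin, ymax + dy * 1e-9, dy)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    if mask is not None:
        from shapely.geometry import Point

        keep = np.array([mask.contains(Point(x, y)) for x, y in pts])
        pts = pts[keep]
        if pts.shape[0] == 0:
            raise ValueError("mask excludes every grid point")
    return PredictionGrid(locations=pts, dx=dx, dy=dy)


def _cross_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    diff = a[:, None, :] - b[None, :, :]
    return np.sqrt((diff**2).sum(-1))


def conditional_moments(
    b: np.ndarray,
    mean: float,
    sd: float,
    decay: float,
    D_cc: np.ndarray,
    d_gc: np.ndarray,
    D_gg: np.ndarray | None = None,
):
    """Conditional mean and covariance of the field at grid points.

    Given city values ``b`` under a stationary field with constant mean,
    marginal SD ``sd`` and correlation ``exp(-decay * d)``:
    ``mu = mean + C_gc C_cc^{-1} (b - mean)`` and
    ``Sigma = C_gg - C_gc C_cc^{-1} C_cg``.  Returns (mu, Sigma) when
    ``D_gg`` is given, else (mu, marginal variances).
    """
    var = sd**2
    C_cc = var * np.exp(-decay * D_cc)
    C_gc = var * np.exp(-decay * d_gc)
    L = linalg.cholesky(C_cc, lower=True)
    A = linalg.solve_triangular(L, C_gc.T, lower=True)  # (J, G)
    w = linalg.solve_triangular(L, b - mean, lower=True)
    mu = mean + A.T @ w
    if D_gg is not None:
        Sigma = var * np.exp(-decay * D_gg) - A.T @ A
        return mu, Sigma
    mvar = np.maximum(var - np.einsum("jg,jg->g", A, A), 0.0)
    return mu, mvar


def krige_coefficient(
    draws: PosteriorDraws,
    geo: CityGeo,
    grid: PredictionGrid,
    which: str = "slope",
    seed: int | None = None,
    joint: bool = False,
) -> np.ndarray:
    """Posterior-predictive draws of a city coefficient at grid locations.

    For each retained draw of (b, mean, sigma, phi), samples one
    realization of the exact conditional Gaussian at the grid.  Returns an
    array of shape (n_draws_total, G).  Grid points within
    ``ZERO_DIST_KM`` of a city reuse that city's coefficient draw directly
    (the no-nugget field interpolates, and this avoids inverting a
    near-singular system).
    """
    if draws.variant != "M3":
        raise ValueError(
            f"kriging requires an M3 fit (got {draws.variant}): "
            "M1/M2 define no between-city spatial field"
        )
    if which not in ("slope", "intercept"):
        raise ValueError("which must be 'slope' or 'intercept'")
    b_all = draws.get("b2" if which == "slope" else "b1", flat=True)
    mean_all = draws.get("beta" if which == "slope" else "alpha", flat=True)
    sd_all = draws.get("sigma2" if which == "slope" else "sigma1", flat=True)
    phi_all = draws.get("phi2" if which == "slope" else "phi1", flat=True)
    if b_all.shape[0] == 0:
        raise ValueError("no posterior draws")

    rng = np.random.default_rng(seed)
    D_cc = geo.D
    d_gc = _cross_distances(grid.locations, geo.coords)
    at_city = d_gc < ZERO_DIST_KM  # (G, J)
    free = ~at_city.any(axis=1)
    G = grid.n_points
    D_gg = _cross_distances(grid.locations[free], grid.locations[free]) if joint else None

    n_draws = b_all.shape[0]
    out = np.empty((n_draws, G))
    for t in range(n_draws):
        b, m, sd, phi = b_all[t], mean_all[t], sd_all[t], phi_all[t]
        # exact interpolation at (numerically) coincident locations
        for g, j in zip(*np.nonzero(at_city)):
            out[t, g] = b[j]
        if not free.any():
            continue
        if joint:
            mu, Sigma = conditional_moments(b, m, sd, phi, D_cc, d_gc[free], D_gg)
            # guard the PSD square root against round-off
            w, V = np.linalg.eigh(Sigma)
            root = V * np.sqrt(np.maximum(w, 0.0))
            out[t, free] = mu + root @ rng.standard_normal(free.sum())
        else:
            mu, mvar = conditional_moments(b, m, sd, phi, D_cc, d_gc[free])
            out[t, free] = mu + np.sqrt(mvar) * rng.standard_normal(free.sum())
    return out


def predict_surface(coef_draws: np.ndarray, grid: PredictionGrid) -> SurfaceSummary:
    """Summarize RR = exp(coefficient) draws per location.

    ``prob_gt1`` uses the strict inequality RR > 1; draws exactly at 0 on
    the log scale count as not exceeding.
    """
    coef_draws = np.atleast_2d(np.asarray(coef_draws, dtype=float))
    if coef_draws.shape[0] == 0:
        raise ValueError("no coefficient draws")
    if coef_draws.shape[1] != grid.n_points:
        raise ValueError("draws not aligned with grid locations")
    rr = np.exp(coef_draws)
    frame = pd.DataFrame(
        {
            "x": grid.locations[:, 0],
            "y": grid.locations[:, 1],
            "rr_mean": rr.mean(axis=0),
            "rr_sd": rr.std(axis=0, ddof=0),
            "prob_gt1": (coef_draws > 0).mean(axis=0),
        }
    )
    return SurfaceSummary(frame=frame)
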