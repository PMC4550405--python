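"""Domain types and data ingestion for multi-city small-area studies.

The central container is :class:`TractTable`: one row per census tract with
observed counts ``O``, expected counts ``E``, a covariate ``X`` (percentage
units, e.g. an unemployment rate) and (city, tract) identifiers.  Tracts are
nested within cities; cities are geographically separated points with a
distance matrix in kilometres.  Tract adjacency within each city feeds the
intrinsic-CAR spatial prior; cities are never adjacent to each other.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "TractTable",
    "Adjacency",
    "CityGeo",
    "StratifiedCounts",
    "load_tract_table",
    "load_city_geo",
    "build_adjacency",
    "load_adjacency_edgelist",
    "write_adjacency_edgelist",
    "read_geobugs_adjacency",
    "distance_matrix",
    "indirect_standardization",
]

EARTH_RADIUS_KM = 6371.0088


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """An input value violates a domain invariant."""


@dataclass(frozen=True)
class TractTable:
    """Validated tract-level table, grouped by city then tract.

    Attributes
    ----------
    frame : pandas.DataFrame
        Columns ``city``, ``tract``, ``observed``, ``expected``,
        ``covariate``; sorted by city (first-appearance order) then tract.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        required = ["city", "tract", "observed", "expected", "covariate"]
        for col in required:
            if col not in df.columns:
                raise SchemaError(f"tract table missing column {col!r}")
        if len(df) == 0:
            raise ValidationError("tract table is empty")
        obs = df["observed"].to_numpy()
        if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
            bad = int(np.flatnonzero((obs < 0) | (obs != np.round(obs)))[0])
            raise ValidationError(f"observed must be a nonnegative integer (row {bad})")
        exp = df["expected"].to_numpy(dtype=float)
        if np.any(~np.isfinite(exp)) or np.any(exp <= 0):
            bad = int(np.flatnonzero(~np.isfinite(exp) | (exp <= 0))[0])
            raise ValidationError(f"expected must be finite and > 0 (row {bad})")
        if not np.all(np.isfinite(df["covariate"].to_numpy(dtype=float))):
            raise ValidationError("covariate contains non-finite values")
        dup = df.duplicated(subset=["city", "tract"])
        if dup.any():
            pair = df.loc[dup.idxmax(), ["city", "tract"]].tolist()
            raise ValidationError(f"duplicated (city, tract) pair {tuple(pair)}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TractTable":
        df = df.copy()
        # preserve first-appearance order of cities, sort tracts within city
        order = {c: k for k, c in enumerate(df["city"].drop_duplicates())}
        df["_ck"] = df["city"].map(order)
        df = df.sort_values(["_ck", "tract"], kind="stable").drop(columns="_ck")
        df = df.reset_index(drop=True)
        df["observed"] = df["observed"].astype(np.int64)
        df["expected"] = df["expected"].astype(float)
        df["covariate"] = df["covariate"].astype(float)
        return cls(df)

    @property
    def cities(self) -> list:
        return list(self.frame["city"].drop_duplicates())

    @property
    def n_cities(self) -> int:
        return len(self.cities)

    @property
    def n_tracts(self) -> int:
        return len(self.frame)

    def tracts_per_city(self) -> dict:
        return self.frame.groupby("city", sort=False).size().to_dict()

    def city_slices(self) -> dict:
        """Map city -> slice of row positions (rows are grouped by city)."""
        out = {}
        codes = self.frame["city"].to_numpy()
        for c in self.cities:
            idx = np.flatnonzero(codes == c)
            out[c] = slice(int(idx[0]), int(idx[-1]) + 1)
        return out

    @property
    def observed(self) -> np.ndarray:
        return self.frame["observed"].to_numpy()

    @property
    def expected(self) -> np.ndarray:
        return self.frame["expected"].to_numpy()

    @property
    def covariate(self) -> np.ndarray:
        return self.frame["covariate"].to_numpy()

    def city_index(self) -> np.ndarray:
        """Integer city index (0..J-1) per row."""
        order = {c: k for k, c in enumerate(self.cities)}
        return self.frame["city"].map(order).to_numpy()

    def fingerprint(self) -> str:
        """Stable hash of the numeric content, for run provenance."""
        import hashlib

        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.observed).tobytes())
        h.update(np.ascontiguousarray(self.expected).tobytes())
        h.update(np.ascontiguousarray(self.covariate).tobytes())
        h.update(",".join(map(str, self.frame["city"])).encode())
        return h.hexdigest()[:16]


@dataclass
class Adjacency:
    """Per-city undirected tract graphs for the ICAR prior.

    ``graphs[city]`` is a :class:`networkx.Graph` whose node set is exactly
    the city's tract labels; isolated tracts are permitted but flagged in
    ``isolated`` because an isolated tract contributes nothing to the ICAR
    quadratic form.
    """

    graphs: dict = field(default_factory=dict)
    isolated: list = field(default_factory=list)

    def neighbor_counts(self, city) -> dict:
        return dict(self.graphs[city].degree())

    def edges(self, city) -> list:
        return sorted(tuple(sorted(e)) for e in self.graphs[city].edges())


@dataclass(frozen=True)
class CityGeo:
    """City point locations plus the intercity distance matrix in km."""

    city_ids: list
    coords: np.ndarray  # (J, 2)
    D: np.ndarray  # (J, J) km

    def __post_init__(self) -> None:
        D = self.D
        if D.shape[0] != D.shape[1] or D.shape[0] != len(self.city_ids):
            raise ValidationError("distance matrix shape mismatch")
        if not np.allclose(D, D.T):
            raise ValidationError("distance matrix must be symmetric")
        if np.any(np.diag(D) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        off = D[~np.eye(D.shape[0], dtype=bool)]
        if np.any(off <= 0):
            raise ValidationError("off-diagonal distances must be strictly positive")


@dataclass(frozen=True)
class StratifiedCounts:
    """Deaths and population per (city, tract, age-group) stratum."""

    frame: pd.DataFrame  # columns: city, tract, age_group, deaths, population

    def __post_init__(self) -> None:
        for col in ("city", "tract", "age_group", "deaths", "population"):
            if col not in self.frame.columns:
                raise SchemaError(f"stratified counts missing column {col!r}")
        if (self.frame["deaths"] < 0).any():
            raise ValidationError("deaths must be nonnegative")
        if (self.frame["population"] < 0).any():
            raise ValidationError("population must be nonnegative")


def load_tract_table(path, columns: dict | None = None, sep: str = ",") -> TractTable:
    """Read a delimited tract table.

    Parameters
    ----------
    columns
        Optional mapping from canonical names (``city``, ``tract``,
        ``observed``, ``expected``, ``covariate``) to the file's column
        names.  Unmapped canonical names are looked up verbatim.
    """
    df = pd.read_csv(path, sep=sep)
    columns = columns or {}
    rename = {}
    for canon in ("city", "tract", "observed", "expected", "covariate"):
        src = columns.get(canon, canon)
        if src not in df.columns:
            raise SchemaError(f"column {src!r} (for {canon!r}) not found in {path}")
        rename[src] = canon
    df = df.rename(columns=rename)[list(rename.values())]
    return TractTable.from_frame(df)


def build_adjacency(edges, table: TractTable) -> Adjacency:
    """Build validated per-city tract graphs from (city, tract_a, tract_b) triples.

    Edges are undirected and deduplicated; self-loops and references to
    unknown tracts raise.  Cities given no edges end up with all their
    tracts isolated (flagged, not fatal).
    """
    known = {}
    for c in table.cities:
        known[c] = set(table.frame.loc[table.frame["city"] == c, "tract"])
    graphs = {c: nx.Graph() for c in table.cities}
    for c, tracts in known.items():
        graphs[c].add_nodes_from(tracts)
    for city, a, b in edges:
        if city not in known:
            raise ValidationError(f"edge references unknown city {city!r}")
        if a == b:
            raise ValidationError(f"self-loop on tract {a!r} in city {city!r}")
        for t in (a, b):
            if t not in known[city]:
                raise ValidationError(f"edge references unknown tract {t!r} in city {city!r}")
        graphs[city].add_edge(a, b)
    isolated = []
    for c, g in graphs.items():
        for t in sorted(nx.isolates(g)):
            isolated.append((c, t))
    if isolated:
        warnings.warn(
            f"{len(isolated)} isolated tract(s); their ICAR contribution is zero: "
            f"{isolated[:5]}{'...' if len(isolated) > 5 else ''}",
            stacklevel=2,
        )
    return Adjacency(graphs=graphs, isolated=isolated)


def load_adjacency_edgelist(path, table: TractTable) -> Adjacency:
    """Read an edge-list CSV with columns city,tract_a,tract_b."""
    df = pd.read_csv(path)
    for col in ("city", "tract_a", "tract_b"):
        if col not in df.columns:
            raise SchemaError(f"adjacency edge list missing column {col!r}")
    edges = list(df[["city", "tract_a", "tract_b"]].itertuples(index=False, name=None))
    return build_adjacency(edges, table)


def write_adjacency_edgelist(adj: Adjacency, path) -> None:
    rows = []
    for city in adj.graphs:
        for a, b in adj.edges(city):
            rows.append((city, a, b))
    pd.DataFrame(rows, columns=["city", "tract_a", "tract_b"]).to_csv(path, index=False)


_NUM_RE = re.compile(r"num\s*=\s*c\(([^)]*)\)", re.S)
_ADJ_RE = re.compile(r"adj\s*=\s*c\(([^)]*)\)", re.S)


def read_geobugs_adjacency(text_or_path, table: TractTable, city) -> Adjacency:
    """Read a GeoBUGS-style adjacency list (``num``/``adj`` vectors) for one city.

    The format lists, for tract i = 1..n in order, the count of neighbours
    ``num[i]`` followed (in ``adj``) by the neighbour indices themselves,
    1-based — the convention of WinBUGS's ``car.normal``.  Accepts either a
    path or the raw text.
    """
    try:
        with open(text_or_path) as fh:
            text = fh.read()
    except (OSError, TypeError):
        text = str(text_or_path)
    m_num, m_adj = _NUM_RE.search(text), _ADJ_RE.search(text)
    if not (m_num and m_adj):
        raise SchemaError("could not find num=c(...) and adj=c(...) vectors")
    num = [int(x) for x in re.split(r"[,\s]+", m_num.group(1).strip()) if x]
    adj = [int(x) for x in re.split(r"[,\s]+", m_adj.group(1).strip()) if x]
    if sum(num) != len(adj):
        raise ValidationError(f"sum(num)={sum(num)} != len(adj)={len(adj)}")
    tracts = list(table.frame.loc[table.frame["city"] == city, "tract"])
    if len(num) != len(tracts):
        raise ValidationError(
            f"num has {len(num)} entries but city {city!r} has {len(tracts)} tracts"
        )
    edges = []
    pos = 0
    for i, k in enumerate(num):
        for j in adj[pos : pos + k]:
            a, b = tracts[i], tracts[j - 1]
            if a != b and (city, b, a) not in edges:
                edges.append((city, a, b))
        pos += k
    # deduplicate symmetric pairs
    seen, uniq = set(), []
    for c, a, b in edges:
        key = (c, *sorted((a, b), key=str))
        if key not in seen:
            seen.add(key)
            uniq.append((c, a, b))
    return build_adjacency(uniq, table)


def _haversine(coords_deg: np.ndarray) -> np.ndarray:
    lon = np.radians(coords_deg[:, 0])[:, None]
    lat = np.radians(coords_deg[:, 1])[:, None]
    dlon = lon - lon.T
    dlat = lat - lat.T
    h = np.sin(dlat / 2) ** 2 + np.cos(lat) * np.cos(lat.T) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def distance_matrix(city_ids, coords, metric: str = "euclidean_km") -> CityGeo:
    """Intercity distance matrix in km.

    ``metric='euclidean_km'`` treats coords as projected km; ``'haversine'``
    treats them as (lon, lat) degrees on a spherical Earth.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValidationError("coords must be (J, 2)")
    if coords.shape[0] < 2:
        raise ValidationError("need at least 2 cities")
    if not np.all(np.isfinite(coords)):
        raise ValidationError("coordinates must be finite")
    if metric == "euclidean_km":
        diff = coords[:, None, :] - coords[None, :, :]
        D = np.sqrt((diff**2).sum(-1))
    elif metric == "haversine":
        D = _haversine(coords)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(D, 0.0)
    off = D[~np.eye(len(D), dtype=bool)]
    if np.any(off <= 0):
        i, j = np.argwhere((D <= 0) & ~np.eye(len(D), dtype=bool))[0]
        raise ValidationError(
            f"cities {city_ids[i]!r} and {city_ids[j]!r} share coordinates (zero distance)"
        )
    return CityGeo(city_ids=list(city_ids), coords=coords, D=D)


def load_city_geo(path, crs: str = "projected_km") -> CityGeo:
    """Read a city coordinate CSV (city_id,x,y) and build the distance matrix."""
    df = pd.read_csv(path)
    for col in ("city_id", "x", "y"):
        if col not in df.columns:
            raise SchemaError(f"city coordinate file missing column {col!r}")
    metric = {"projected_km": "euclidean_km", "lonlat": "haversine"}.get(crs)
    if metric is None:
        raise ValueError(f"unknown crs {crs!r}")
    return distance_matrix(list(df["city_id"]), df[["x", "y"]].to_numpy(), metric=metric)


def indirect_standardization(strata: StratifiedCounts) -> pd.DataFrame:
    """Expected counts per tract by indirect standardization.

    Reference rates are computed from the pooled study population: for each
    age group ``a``, ``rate_a = sum(deaths_a) / sum(pop_a)`` over all tracts
    of all cities; then ``E_ij = sum_a rate_a * pop_ija``.  With this
    internal reference the expected counts conserve the total,
    ``sum(E) == sum(O)``, exactly (up to float round-off).

    Returns a DataFrame with columns city, tract, expected.
    """
    df = strata.frame
    pooled = df.groupby("age_group", sort=False).agg(
        deaths=("deaths", "sum"), population=("population", "sum")
    )
    rates = {}
    for a, row in pooled.iterrows():
        if row["population"] == 0:
            if row["deaths"] > 0:
                raise ValidationError(
                    f"age group {a!r} has zero pooled population but {row['deaths']} deaths"
                )
            warnings.warn(f"age group {a!r} empty; rate set to 0", stacklevel=2)
            rates[a] = 0.0
        else:
            rates[a] = row["deaths"] / row["population"]
    tmp = df.assign(_e=df["age_group"].map(rates) * df["population"])
    out = tmp.groupby(["city", "tract"], sort=False)["_e"].sum().reset_index()
    return out.rename(columns={"_e": "expected"})
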