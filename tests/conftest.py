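import networkx as nx
import numpy as np
import pandas as pd
import pytest

from multicity.data import Adjacency, TractTable, build_adjacency


@pytest.fixture
def tiny_table() -> TractTable:
    """Two cities, two tracts each, unit expected counts."""
    return TractTable.from_frame(
        pd.DataFrame(
            {
                "city": ["a", "a", "b", "b"],
                "tract": [1, 2, 1, 2],
                "observed": [1, 0, 2, 3],
                "expected": [1.0, 1.0, 1.0, 1.0],
                "covariate": [10.0, 12.0, 8.0, 9.0],
            }
        )
    )


@pytest.fixture
def tiny_adjacency(tiny_table) -> Adjacency:
    return build_adjacency([("a", 1, 2), ("b", 1, 2)], tiny_table)


def random_connected_graph(n: int, rng: np.random.Generator) -> nx.Graph:
    """Random spanning tree plus a few extra edges — always connected."""
    g = nx.Graph()
    g.add_nodes_from(range(n))
    order = rng.permutation(n)
    for i in range(1, n):
        g.add_edge(int(order[i]), int(order[rng.integers(0, i)]))
    for _ in range(n // 2):
        a, b = rng.integers(0, n, 2)
        if a != b:
            g.add_edge(int(a), int(b))
    return g


def make_table(J: int, n_j: int, rng: np.random.Generator) -> tuple[TractTable, Adjacency]:
    """Path-graph cities with Poisson-ish counts, for sampler plumbing tests."""
    rows = []
    edges = []
    for j in range(J):
        city = f"c{j}"
        for i in range(1, n_j + 1):
            rows.append((city, i, int(rng.integers(0, 6)), float(rng.uniform(0.5, 3.0)),
                         float(rng.uniform(5, 30))))
            if i > 1:
                edges.append((city, i - 1, i))
    table = TractTable.from_frame(
        pd.DataFrame(rows, columns=["city", "tract", "observed", "expected", "covariate"])
    )
    return table, build_adjacency(edges, table)
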