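"""Shared fixtures: seeded random-graph pools and distance-matrix oracles.

The oracle route is deliberately independent of the package's own path:
distances come from scipy's Floyd-Warshall on the dense adjacency matrix,
and every descriptor is re-derived from that matrix with direct double
loops over the printed formulas.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest
from scipy.sparse.csgraph import floyd_warshall

from eczagreb.io import RandomGraphSpec, random_graph


def fw_distance_matrix(G: nx.Graph):
    """All-pairs distances via scipy Floyd-Warshall; rows follow sorted nodes."""
    nodes = sorted(G.nodes)
    A = nx.to_numpy_array(G, nodelist=nodes)
    return nodes, floyd_warshall(A, directed=False, unweighted=True)


def naive_descriptors(G: nx.Graph) -> dict[str, int]:
    """All seven descriptors from the distance matrix, by direct loops."""
    nodes, D = fw_distance_matrix(G)
    pos = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    ecc = {v: int(D[pos[v]].max()) for v in nodes} if n > 1 else {nodes[0]: 0}
    deg = dict(G.degree())
    delta = {v: sum(ecc[u] for u in G[v]) for v in nodes}
    edges = list(G.edges())
    return {
        "enm1": sum(delta[v] ** 2 for v in nodes),
        "enm2": sum(delta[u] * delta[v] for u, v in edges),
        "enm3": sum(delta[u] + delta[v] for u, v in edges),
        "wiener": int(D.sum()) // 2,
        "xi_c": sum(deg[v] * ecc[v] for v in nodes),
        "m1": sum(deg[v] ** 2 for v in nodes),
        "m2": sum(deg[u] * deg[v] for u, v in edges),
        "ecc": ecc,
        "delta": delta,
    }


def _pool(count: int, nmin: int, nmax: int, seed0: int) -> list[nx.Graph]:
    """Seeded mix of connected graphs: ER at two densities, random trees,
    and dense/complete members so both empty and non-empty universal-vertex
    sets are exercised."""
    graphs = []
    for i in range(count):
        n = nmin + i % (nmax - nmin + 1)
        kind = i % 4
        if kind == 0:
            g = random_graph(RandomGraphSpec("er", n, seed=seed0 + i, p=0.5))
        elif kind == 1:
            g = random_graph(RandomGraphSpec("er", n, seed=seed0 + i, p=0.85))
        elif kind == 2:
            g = random_graph(RandomGraphSpec("tree", n, seed=seed0 + i))
        else:
            g = nx.complete_graph(range(1, n + 1)) if i % 8 == 3 else nx.star_graph(n - 1)
            g = nx.relabel_nodes(g, {v: v + 1 for v in g.nodes}) if 0 in g else g
        graphs.append(g)
    return graphs


@pytest.fixture(scope="session")
def random_connected_graphs() -> list[nx.Graph]:
    """200 seeded connected graphs with n <= 12."""
    return _pool(200, 2, 12, seed0=20_000)


@pytest.fixture(scope="session")
def factor_pairs() -> list[tuple[nx.Graph, nx.Graph]]:
    """100+ seeded connected factor pairs with 2 <= n <= 7 per factor."""
    left = _pool(104, 2, 7, seed0=31_000)
    right = _pool(104, 2, 7, seed0=47_000)
    return list(zip(left, right[::-1]))
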