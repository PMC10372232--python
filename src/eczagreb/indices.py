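"""The seven scalar descriptors.

Degree-based:  first and second Zagreb indices

    M1 = sum d(v)^2          M2 = sum over edges uv of d(u) d(v)

distance-based:  Wiener index W (half-sum of all pairwise distances) and the
eccentric connectivity index xi_c = sum d(v) ecc(v), and the three
eccentric-neighborhood Zagreb indices built on delta_en:

    ENM1 = sum_v delta_en(v)^2
    ENM2 = sum_{uv in E} delta_en(u) delta_en(v)
    ENM3 = sum_{uv in E} (delta_en(u) + delta_en(v))  =  sum_v d(v) delta_en(v)

All values are exact non-negative integers; no floating point enters this
module.  Distance-based descriptors require a connected graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .graph_core import (
    DeltaEnProfile,
    EccProfile,
    delta_en_profile,
    eccentricities,
    require_connected,
)

__all__ = [
    "IndexBundle",
    "zagreb_m1",
    "zagreb_m2",
    "wiener",
    "eccentric_connectivity",
    "enm1",
    "enm2",
    "enm3",
    "index_bundle",
]

#: Column order used by every tabular output in the package.
INDEX_ORDER = ("enm1", "enm2", "enm3", "wiener", "xi_c", "m1", "m2")


@dataclass(frozen=True)
class IndexBundle:
    """All seven descriptor values for one graph."""

    enm1: int
    enm2: int
    enm3: int
    wiener: int
    xi_c: int
    m1: int
    m2: int

    def as_tuple(self) -> tuple[int, ...]:
        return (self.enm1, self.enm2, self.enm3, self.wiener,
                self.xi_c, self.m1, self.m2)


def zagreb_m1(G: nx.Graph) -> int:
    """First Zagreb index: sum of squared degrees."""
    return sum(d * d for _, d in G.degree())


def zagreb_m2(G: nx.Graph) -> int:
    """Second Zagreb index: sum over edges of degree products."""
    return sum(G.degree(u) * G.degree(v) for u, v in G.edges())


def wiener(G: nx.Graph) -> int:
    """Wiener index: half-sum of all ordered pairwise distances.

    Accumulated by one BFS per source; an n x n distance matrix is never
    materialized.
    """
    require_connected(G)
    total = 0
    for _, dist in nx.all_pairs_shortest_path_length(G):
        total += sum(dist.values())
    return total // 2


def eccentric_connectivity(G: nx.Graph, profile: EccProfile | None = None) -> int:
    """Eccentric connectivity index xi_c = sum d(v) ecc(v)."""
    if profile is None:
        profile = eccentricities(G)
    return sum(G.degree(v) * profile.ecc[v] for v in G)


def enm1(G: nx.Graph, dprof: DeltaEnProfile | None = None) -> int:
    """First eccentric-neighborhood Zagreb index: sum of squared delta_en."""
    if dprof is None:
        dprof = delta_en_profile(G)
    return sum(x * x for x in dprof.delta_en.values())


def enm2(G: nx.Graph, dprof: DeltaEnProfile | None = None) -> int:
    """Second eccentric-neighborhood Zagreb index: edge-wise delta_en products."""
    if dprof is None:
        dprof = delta_en_profile(G)
    d = dprof.delta_en
    return sum(d[u] * d[v] for u, v in G.edges())


def enm3(G: nx.Graph, dprof: DeltaEnProfile | None = None) -> int:
    """Third eccentric-neighborhood Zagreb index: edge-wise delta_en sums.

    Equals sum_v d(v) delta_en(v) (each vertex term appears once per
    incident edge).
    """
    if dprof is None:
        dprof = delta_en_profile(G)
    d = dprof.delta_en
    return sum(d[u] + d[v] for u, v in G.edges())


def index_bundle(G: nx.Graph) -> IndexBundle:
    """All seven descriptors in one pass over a shared eccentricity profile."""
    profile = eccentricities(G)
    dprof = delta_en_profile(G, profile)
    return IndexBundle(
        enm1=enm1(G, dprof),
        enm2=enm2(G, dprof),
        enm3=enm3(G, dprof),
        wiener=wiener(G),
        xi_c=eccentric_connectivity(G, profile),
        m1=zagreb_m1(G),
        m2=zagreb_m2(G),
    )
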