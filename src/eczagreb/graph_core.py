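"""Graph substrate: eccentricities and the eccentricity neighborhood degree.

The descriptors in this package are built on one per-vertex quantity, the
*eccentricity neighborhood degree*

    delta_en(v) = sum of ecc(u) over the neighbors u of v,

where ecc(u) is the usual eccentricity, the largest shortest-path distance
from u to any other vertex.  Graphs are undirected, simple and (for every
distance-based quantity) connected; vertices carry positive integer labels.

:class:`networkx.Graph` is the in-memory container throughout; this module
adds construction with validation, the eccentricity/radius/diameter profile,
universal-vertex detection, and the delta_en profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "GraphError",
    "DisconnectedGraphError",
    "ParameterError",
    "NoClosedFormError",
    "EccProfile",
    "DeltaEnProfile",
    "build_graph",
    "require_connected",
    "eccentricities",
    "universal_vertices",
    "delta_en_profile",
]


class GraphError(ValueError):
    """Invalid graph input (self-loop, empty vertex set, bad label...)."""


class DisconnectedGraphError(GraphError):
    """Raised by distance-based operations on a disconnected graph."""


class ParameterError(ValueError):
    """A family/product parameter outside its admissible range."""


class NoClosedFormError(ValueError):
    """No closed-form expression covers the requested case."""


@dataclass(frozen=True)
class EccProfile:
    """Per-vertex eccentricities with the derived radius and diameter."""

    ecc: Mapping[int, int]
    radius: int
    diameter: int

    def __post_init__(self) -> None:
        if not self.radius <= self.diameter <= 2 * self.radius and self.radius > 0:
            raise GraphError(
                f"inconsistent profile: r={self.radius}, D={self.diameter}"
            )


@dataclass(frozen=True)
class DeltaEnProfile:
    """Per-vertex eccentricity neighborhood degrees delta_en(v)."""

    delta_en: Mapping[int, int]

    def total(self) -> int:
        """Sum of delta_en over all vertices (equals the eccentric
        connectivity index of the graph)."""
        return sum(self.delta_en.values())


def build_graph(edge_list: Iterable[tuple[int, int]], n: int | None = None) -> nx.Graph:
    """Build a simple undirected graph from an edge list.

    Parameters
    ----------
    edge_list
        Pairs of positive integer vertex labels.  Duplicate edges (in either
        orientation) are collapsed; the number collapsed is recorded in
        ``G.graph["duplicates"]``.
    n
        Optional vertex count.  Vertices ``1..n`` are created even when
        isolated; must be at least the largest label used.

    Raises
    ------
    GraphError
        On a self-loop, a non-positive label, or an empty vertex set.
    """
    G = nx.Graph(duplicates=0)
    for pair in edge_list:
        u, v = pair
        if not (isinstance(u, int) and isinstance(v, int)) or u < 1 or v < 1:
            raise GraphError(f"vertex labels must be positive integers, got {pair!r}")
        if u == v:
            raise GraphError(f"self-loop at vertex {u} not allowed")
        if G.has_edge(u, v):
            G.graph["duplicates"] += 1
        else:
            G.add_edge(u, v)
    if n is not None:
        if G.number_of_nodes() and max(G.nodes) > n:
            raise GraphError(f"label {max(G.nodes)} exceeds declared n={n}")
        G.add_nodes_from(range(1, n + 1))
    if G.number_of_nodes() == 0:
        raise GraphError("empty vertex set")
    return G


def require_connected(G: nx.Graph) -> None:
    """Raise :class:`DisconnectedGraphError` unless ``G`` is connected."""
    if G.number_of_nodes() == 0:
        raise GraphError("empty vertex set")
    if not nx.is_connected(G):
        raise DisconnectedGraphError("eccentricity undefined on disconnected graph")


def eccentricities(G: nx.Graph) -> EccProfile:
    """Eccentricity profile of a connected graph (one BFS per vertex).

    The single-vertex graph K1 gets ecc = 0 by convention.
    """
    require_connected(G)
    if G.number_of_nodes() == 1:
        (v,) = G.nodes
        return EccProfile(ecc={v: 0}, radius=0, diameter=0)
    ecc = nx.eccentricity(G)
    return EccProfile(ecc=dict(ecc), radius=min(ecc.values()), diameter=max(ecc.values()))


def universal_vertices(G: nx.Graph) -> frozenset[int]:
    """Vertices adjacent to every other vertex (eccentricity 1).

    Defined purely from adjacency, so it is also meaningful for disconnected
    graphs (where it is empty unless n = 1... a disconnected graph has none).
    K1 has no universal vertex by convention.
    """
    n = G.number_of_nodes()
    if n < 2:
        return frozenset()
    return frozenset(v for v in G if G.degree(v) == n - 1)


def delta_en_profile(G: nx.Graph, profile: EccProfile | None = None) -> DeltaEnProfile:
    """Eccentricity neighborhood degree delta_en(v) for every vertex.

    ``profile`` may supply a precomputed :class:`EccProfile` to avoid
    repeating the BFS sweep.
    """
    if profile is None:
        profile = eccentricities(G)
    ecc = profile.ecc
    return DeltaEnProfile(
        delta_en={v: sum(ecc[u] for u in G[v]) for v in G}
    )
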