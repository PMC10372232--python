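"""Four graph products and their closed-form ENM index expressions.

Products on factors G, H (product vertex (u, v), u from G):

join ``G + H``
    disjoint union plus every cross edge.
disjunction ``G | H``
    (a,b) ~ (c,d) iff ac in E(G) or bd in E(H).
composition (lexicographic) ``G[H]``
    (a,b) ~ (c,d) iff ac in E(G), or a = c and bd in E(H).
symmetric difference ``G (+) H``
    (a,b) ~ (c,d) iff exactly one of ac in E(G), bd in E(H).

The point of this module is that eccentricities, delta_en profiles and the
three ENM indices of a product are determined by *factor* data alone: factor
degrees, vertex counts, and the universal-vertex counts r = |Vw(G)|,
s = |Vw(H)|.  Nothing here runs a BFS on the product; the direct route
(:func:`eczagreb.indices.index_bundle` on :func:`product_graph`) is the
independent check used in the test suite.

Product vertices are canonically indexed: for the join, G keeps 1..|V(G)|
and H is shifted; for the pair products, (u, v) -> (u-1)|V(H)| + v
(row-major).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum

import networkx as nx

from .graph_core import (
    DeltaEnProfile,
    EccProfile,
    GraphError,
    NoClosedFormError,
    delta_en_profile,
    eccentricities,
    universal_vertices,
)
from .indices import zagreb_m1, zagreb_m2

__all__ = [
    "ProductKind",
    "JoinEdgePartition",
    "ProductEdgePartition",
    "product_graph",
    "product_eccentricities",
    "product_delta_en",
    "join_edge_partition",
    "product_enm_closed",
]


class ProductKind(str, Enum):
    JOIN = "join"
    DISJUNCTION = "disjunction"
    COMPOSITION = "composition"
    SYMMETRIC_DIFFERENCE = "symmetric_difference"


def _join_universal(F: nx.Graph) -> frozenset:
    """Vertices of a factor that become universal in any join containing it.

    Same as :func:`universal_vertices` except that the single vertex of K1
    counts (it is vacuously adjacent to all other factor vertices, and gains
    eccentricity 1 in the join - e.g. the hub of K1 + C_{n-1} = W_n).
    """
    n = F.number_of_nodes()
    return frozenset(v for v in F if F.degree(v) == n - 1)


def _pair_index(H: nx.Graph):
    nH = H.number_of_nodes()
    hs = sorted(H.nodes)
    pos = {v: i for i, v in enumerate(hs)}

    def idx(u: int, v: int) -> int:
        return (u - 1) * nH + pos[v] + 1

    return idx


def _check_factors(kind: ProductKind, G: nx.Graph, H: nx.Graph) -> None:
    if G.number_of_nodes() == 0 or H.number_of_nodes() == 0:
        raise GraphError("product factors must be nonempty")
    if kind is not ProductKind.JOIN:
        if G.number_of_nodes() < 2 or H.number_of_nodes() < 2:
            raise GraphError(
                f"{kind.value} requires both factors to have >= 2 vertices"
            )


def product_graph(kind: ProductKind, G: nx.Graph, H: nx.Graph) -> nx.Graph:
    """Construct the product graph with canonical integer labels."""
    kind = ProductKind(kind)
    _check_factors(kind, G, H)
    nG, nH = G.number_of_nodes(), H.number_of_nodes()
    P = nx.Graph()
    if kind is ProductKind.JOIN:
        gs, hs = sorted(G.nodes), sorted(H.nodes)
        gmap = {u: i + 1 for i, u in enumerate(gs)}
        hmap = {v: nG + i + 1 for i, v in enumerate(hs)}
        P.add_nodes_from(range(1, nG + nH + 1))
        P.add_edges_from((gmap[u], gmap[v]) for u, v in G.edges())
        P.add_edges_from((hmap[u], hmap[v]) for u, v in H.edges())
        P.add_edges_from((gmap[u], hmap[v]) for u in gs for v in hs)
        return P

    idx = _pair_index(H)
    P.add_nodes_from(idx(u, v) for u in sorted(G.nodes) for v in sorted(H.nodes))
    pairs = list(itertools.product(sorted(G.nodes), sorted(H.nodes)))
    for (a, b), (c, d) in itertools.combinations(pairs, 2):
        eg = G.has_edge(a, c)
        eh = H.has_edge(b, d)
        if kind is ProductKind.DISJUNCTION:
            adj = eg or eh
        elif kind is ProductKind.COMPOSITION:
            adj = eg or (a == c and eh)
        else:  # symmetric difference
            adj = eg != eh
        if adj:
            P.add_edge(idx(a, b), idx(c, d))
    return P


def _product_degrees(kind: ProductKind, G: nx.Graph, H: nx.Graph) -> dict[int, int]:
    """Product degrees from the standard factor-degree formulas."""
    nG, nH = G.number_of_nodes(), H.number_of_nodes()
    if kind is ProductKind.JOIN:
        deg = {}
        gs, hs = sorted(G.nodes), sorted(H.nodes)
        for i, u in enumerate(gs):
            deg[i + 1] = G.degree(u) + nH
        for i, v in enumerate(hs):
            deg[nG + i + 1] = H.degree(v) + nG
        return deg
    idx = _pair_index(H)
    deg = {}
    for u in G:
        for v in H:
            du, dv = G.degree(u), H.degree(v)
            if kind is ProductKind.DISJUNCTION:
                d = nH * du + nG * dv - du * dv
            elif kind is ProductKind.COMPOSITION:
                d = nH * du + dv
            else:
                d = nH * du + nG * dv - 2 * du * dv
            deg[idx(u, v)] = d
    return deg


def product_eccentricities(kind: ProductKind, G: nx.Graph, H: nx.Graph) -> EccProfile:
    """Eccentricity profile of a product from factor eccentricities alone.

    Join: a vertex keeps eccentricity 1 iff it was universal in its factor,
    otherwise 2.  Disjunction: 1 iff both coordinates universal, else 2.
    Composition: 1 iff both universal; 2 if the G-coordinate is universal
    and the H-coordinate is not; otherwise the G-coordinate's eccentricity.
    Symmetric difference: constant 2.
    """
    kind = ProductKind(kind)
    _check_factors(kind, G, H)
    nG = G.number_of_nodes()
    if kind is ProductKind.JOIN:
        # factor eccentricity only enters through universality, which is an
        # adjacency property - disconnected (e.g. edgeless) factors are fine
        uG, uH = _join_universal(G), _join_universal(H)
        ecc = {}
        for i, u in enumerate(sorted(G.nodes)):
            ecc[i + 1] = 1 if u in uG else 2
        for i, v in enumerate(sorted(H.nodes)):
            ecc[nG + i + 1] = 1 if v in uH else 2
    else:
        eG = eccentricities(G).ecc
        eH = eccentricities(H).ecc
        idx = _pair_index(H)
        ecc = {}
        for u in G:
            for v in H:
                if kind is ProductKind.SYMMETRIC_DIFFERENCE:
                    e = 2
                elif kind is ProductKind.DISJUNCTION:
                    e = 1 if eG[u] == eH[v] == 1 else 2
                else:  # composition
                    if eG[u] == 1:
                        e = 1 if eH[v] == 1 else 2
                    else:
                        e = eG[u]
                ecc[idx(u, v)] = e
    return EccProfile(ecc=ecc, radius=min(ecc.values()), diameter=max(ecc.values()))


def product_delta_en(kind: ProductKind, G: nx.Graph, H: nx.Graph) -> DeltaEnProfile:
    """delta_en profile of a product from factor data (no product BFS).

    Join with r = |Vw(G)|, s = |Vw(H)|: every vertex has
    delta_en = 2 d - (r + s) + [vertex universal in its factor], with d the
    product degree; when r = s = 0 this is just 2d.  Disjunction and
    composition with rs > 0: delta_en = 2d - rs + [product eccentricity 1];
    with rs = 0 the disjunction gives 2d.  Composition with Vw(G) empty has
    product eccentricities equal to the G-coordinate's, giving
    delta_en(u,v) = |V(H)| delta_en_G(u) + ecc_G(u) d_H(v).
    Symmetric difference: always 2d.
    """
    kind = ProductKind(kind)
    _check_factors(kind, G, H)
    deg = _product_degrees(kind, G, H)
    if kind is ProductKind.JOIN:
        uG, uH = _join_universal(G), _join_universal(H)
    else:
        uG, uH = universal_vertices(G), universal_vertices(H)
    r, s = len(uG), len(uH)
    nG, nH = G.number_of_nodes(), H.number_of_nodes()

    if kind is ProductKind.JOIN:
        prof = {}
        for i, u in enumerate(sorted(G.nodes)):
            prof[i + 1] = 2 * deg[i + 1] - (r + s) + (1 if u in uG else 0)
        for i, v in enumerate(sorted(H.nodes)):
            prof[nG + i + 1] = 2 * deg[nG + i + 1] - (r + s) + (1 if v in uH else 0)
        return DeltaEnProfile(delta_en=prof)

    idx = _pair_index(H)
    if kind is ProductKind.SYMMETRIC_DIFFERENCE:
        return DeltaEnProfile(
            delta_en={idx(u, v): 2 * deg[idx(u, v)] for u in G for v in H}
        )
    if kind is ProductKind.DISJUNCTION:
        rs = r * s
        prof = {}
        for u in G:
            for v in H:
                one = 1 if (u in uG and v in uH) else 0
                prof[idx(u, v)] = 2 * deg[idx(u, v)] - rs + one
        return DeltaEnProfile(delta_en=prof)

    # composition
    if r > 0:
        rs = r * s  # s may be 0: then ecc is constantly 2 and rs = 0
        prof = {}
        for u in G:
            for v in H:
                one = 1 if (u in uG and v in uH) else 0
                prof[idx(u, v)] = 2 * deg[idx(u, v)] - rs + one
        return DeltaEnProfile(delta_en=prof)
    # Vw(G) empty: product eccentricity of (u,v) is ecc_G(u) (>= 2); a
    # neighbor is (u', *) with uu' in E(G), or (u, v') with vv' in E(H)
    eG = eccentricities(G).ecc
    dG = delta_en_profile(G).delta_en
    prof = {}
    for u in G:
        for v in H:
            prof[idx(u, v)] = nH * dG[u] + eG[u] * H.degree(v)
    return DeltaEnProfile(delta_en=prof)


@dataclass(frozen=True)
class JoinEdgePartition:
    """The ten-way classification of join edges by factor of origin and
    universality of the endpoints.

    E11/E12/E13: edges of G with neither/both/one endpoint universal in G;
    E21/E22/E23: the same for H; E31..E34: cross edges with (neither,
    H-endpoint only, G-endpoint only, both) endpoints universal.  Edges are
    stored as pairs in product labeling; for E13/E23/E32/E33 the ordering
    within each pair follows the class definition (non-universal endpoint
    first for E13/E23/E32, universal G-endpoint first for E33).
    """

    E11: tuple; E12: tuple; E13: tuple
    E21: tuple; E22: tuple; E23: tuple
    E31: tuple; E32: tuple; E33: tuple; E34: tuple

    def classes(self) -> dict[str, tuple]:
        return {k: getattr(self, k) for k in
                ("E11", "E12", "E13", "E21", "E22", "E23",
                 "E31", "E32", "E33", "E34")}


@dataclass(frozen=True)
class ProductEdgePartition:
    """Disjunction/composition edges split by the endpoints' product
    eccentricity: E1 both 1, E2 neither 1, E3 mixed (ecc-1 endpoint first)."""

    E1: tuple
    E2: tuple
    E3: tuple


def join_edge_partition(G: nx.Graph, H: nx.Graph) -> JoinEdgePartition:
    """Classify every edge of G + H into the ten classes."""
    _check_factors(ProductKind.JOIN, G, H)
    nG = G.number_of_nodes()
    gs, hs = sorted(G.nodes), sorted(H.nodes)
    gmap = {u: i + 1 for i, u in enumerate(gs)}
    hmap = {v: nG + i + 1 for i, v in enumerate(hs)}
    uG, uH = _join_universal(G), _join_universal(H)
    cls: dict[str, list] = {k: [] for k in
                            ("E11", "E12", "E13", "E21", "E22", "E23",
                             "E31", "E32", "E33", "E34")}
    for u, v in G.edges():
        a, b = u in uG, v in uG
        if a and b:
            cls["E12"].append((gmap[u], gmap[v]))
        elif a or b:
            out, inn = (v, u) if a else (u, v)  # non-universal first
            cls["E13"].append((gmap[out], gmap[inn]))
        else:
            cls["E11"].append((gmap[u], gmap[v]))
    for u, v in H.edges():
        a, b = u in uH, v in uH
        if a and b:
            cls["E22"].append((hmap[u], hmap[v]))
        elif a or b:
            out, inn = (v, u) if a else (u, v)
            cls["E23"].append((hmap[out], hmap[inn]))
        else:
            cls["E21"].append((hmap[u], hmap[v]))
    for u in gs:
        for v in hs:
            a, b = u in uG, v in uH
            key = "E34" if (a and b) else "E33" if a else "E32" if b else "E31"
            cls[key].append((gmap[u], hmap[v]))
    return JoinEdgePartition(**{k: tuple(v) for k, v in cls.items()})


def _pair_partition(kind: ProductKind, G: nx.Graph, H: nx.Graph) -> ProductEdgePartition:
    """E1/E2/E3 of the disjunction or composition, from factor universality."""
    uG, uH = universal_vertices(G), universal_vertices(H)
    idx = _pair_index(H)
    one = {idx(u, v) for u in uG for v in uH}
    P = product_graph(kind, G, H)
    e1, e2, e3 = [], [], []
    for a, b in P.edges():
        ia, ib = a in one, b in one
        if ia and ib:
            e1.append((a, b))
        elif ia or ib:
            e3.append((a, b) if ia else (b, a))  # ecc-1 endpoint first
        else:
            e2.append((a, b))
    return ProductEdgePartition(E1=tuple(e1), E2=tuple(e2), E3=tuple(e3))


def _join_enm_closed(G: nx.Graph, H: nx.Graph) -> tuple[int, int, int]:
    nG, nH = G.number_of_nodes(), H.number_of_nodes()
    eg, eh = G.number_of_edges(), H.number_of_edges()
    uG, uH = _join_universal(G), _join_universal(H)
    r, s = len(uG), len(uH)
    deg = _product_degrees(ProductKind.JOIN, G, H)
    m1 = sum(d * d for d in deg.values())

    if r + s == 0:
        # every join vertex has delta_en = 2d: ENM1 = 4 M1, ENM2 = 4 M2,
        # ENM3 = 2 M1 of the join
        part = join_edge_partition(G, H)
        m2 = sum(deg[a] * deg[b] for cl in part.classes().values() for a, b in cl)
        return 4 * m1, 4 * m2, 2 * m1

    part = join_edge_partition(G, H)
    rpl = r + s

    # ENM1: expanded closed form (with the (|V(G)| - r) factor forced by the
    # worked join example)
    sum_du_uni = sum(G.degree(u) for u in uG) + sum(H.degree(v) for v in uH)
    e1 = (
        4 * m1
        - 8 * rpl * (eg + eh)
        + 4 * sum_du_uni
        + rpl * (rpl**2 - 2 * rpl - 4 * (r * nH + s * nG))
        + rpl * ((rpl - 4 * nH) * (nG - r) + (rpl - 4 * nG) * (nH - s))
        + (4 * nH + 1) * r + (4 * nG + 1) * s
    )

    # ENM2: term-by-term over the ten classes, each endpoint contributing its
    # closed delta_en linear form 2d +/- correction
    uni = {i + 1 for i, u in enumerate(sorted(G.nodes)) if u in uG}
    uni |= {nG + i + 1 for i, v in enumerate(sorted(H.nodes)) if v in uH}

    def dlt(x: int) -> int:
        return 2 * deg[x] - rpl + (1 if x in uni else 0)

    e2 = sum(dlt(a) * dlt(b) for cl in part.classes().values() for a, b in cl)

    # ENM3: expanded closed form
    cross_deg_sum = nH * 2 * eg + nG * 2 * eh  # sum over cross pairs of dG(u)+dH(v)
    e3 = (
        2 * (zagreb_m1(G) + zagreb_m1(H))
        + (4 * nH - 2 * rpl) * eg
        + (4 * nG - 2 * rpl) * eh
        + 2 * (len(part.E12) + len(part.E22))
        + len(part.E13) + len(part.E23)
        + 2 * cross_deg_sum
        + (2 * (nG + nH) - 2 * rpl) * nG * nH
        + len(part.E32) + len(part.E33) + 2 * len(part.E34)
    )
    return e1, e2, e3


def _pair_enm_closed(kind: ProductKind, G: nx.Graph, H: nx.Graph) -> tuple[int, int, int]:
    uG, uH = universal_vertices(G), universal_vertices(H)
    r, s = len(uG), len(uH)
    rs = r * s
    deg = _product_degrees(kind, G, H)
    P = product_graph(kind, G, H)  # adjacency only; no distances computed
    m1 = sum(d * d for d in deg.values())
    m2 = sum(deg[a] * deg[b] for a, b in P.edges())
    nE = P.number_of_edges()

    both_complete = (r == G.number_of_nodes() and s == H.number_of_nodes())
    if both_complete:
        # the product is complete; delta_en = d on every vertex
        return m1, m2, m1

    if rs == 0:
        if kind is ProductKind.COMPOSITION and r == 0:
            raise NoClosedFormError(
                "composition with no universal vertex in the first factor "
                "is not covered by a closed form"
            )
        # all product eccentricities are 2: delta_en = 2d
        return 4 * m1, 4 * m2, 2 * m1

    idx = _pair_index(H)
    one = {idx(u, v) for u in uG for v in uH}
    part = _pair_partition(kind, G, H)
    sum_d_one = sum(deg[x] for x in one)
    N = G.number_of_nodes() * H.number_of_nodes()

    e1 = 4 * m1 - 8 * rs * nE + 4 * sum_d_one + (1 - 2 * rs + rs * N) * rs
    e2 = (
        4 * m2
        - 2 * (
            (rs - 1) * sum(deg[a] + deg[b] for a, b in part.E1)
            + rs * sum(deg[a] + deg[b] for a, b in part.E2)
            + sum(rs * deg[a] + (rs - 1) * deg[b] for a, b in part.E3)
        )
        + (rs - 1) ** 2 * len(part.E1)
        + rs * (rs * len(part.E2) + (rs - 1) * len(part.E3))
    )
    e3 = 2 * m1 - 2 * rs * nE + 2 * len(part.E1) + len(part.E3)
    return e1, e2, e3


def product_enm_closed(
    kind: ProductKind, G: nx.Graph, H: nx.Graph
) -> tuple[int, int, int]:
    """(ENM1, ENM2, ENM3) of a product, from the closed-form expressions.

    All quantities are assembled from factor degrees, vertex counts,
    universal-vertex sets and the edge partitions; the product's distance
    structure is never computed.

    Raises
    ------
    NoClosedFormError
        For the composition when the first factor has no universal vertex
        (the one case the case analysis does not cover).
    GraphError
        For empty factors, or factors with fewer than two vertices outside
        the join.
    """
    kind = ProductKind(kind)
    _check_factors(kind, G, H)
    if kind is ProductKind.JOIN:
        return _join_enm_closed(G, H)
    if kind is ProductKind.SYMMETRIC_DIFFERENCE:
        deg = _product_degrees(kind, G, H)
        P = product_graph(kind, G, H)
        m1 = sum(d * d for d in deg.values())
        m2 = sum(deg[a] * deg[b] for a, b in P.edges())
        return 4 * m1, 4 * m2, 2 * m1
    return _pair_enm_closed(kind, G, H)
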