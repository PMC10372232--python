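"""Named graph families: generators and closed-form ENM evaluators.

Families covered (canonical 1-based labelings):

============================  =====================================================
path ``P_n``                  vertices 1..n along the path
cycle ``C_n``                 vertices 1..n around the cycle
star ``S_r``                  center 1, leaves 2..r+1  (r+1 vertices)
double star ``S_{r,s}``       centers 1,2 (adjacent); r leaves on 1, s on 2
wheel ``W_n``                 hub 1 plus an (n-1)-cycle 2..n  (n vertices total)
complete ``K_n``              vertices 1..n
complete bipartite ``K_{r,s}``  part A = 1..r, part B = r+1..r+s
banana ``B_{r,s}``            root 1, then per star copy: connector leaf,
                              center, s-2 pendant leaves  (rs+1 vertices)
============================  =====================================================

The banana tree joins one leaf ("connector") of each of r copies of an
s-vertex star to a common root.  Closed forms are exact integer polynomial
evaluations; parameters outside a formula's validity range fall back to
direct computation on the constructed graph, flagged in the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .graph_core import DeltaEnProfile, ParameterError
from . import indices as _ix

__all__ = [
    "FAMILY_KINDS",
    "SWEEP_DEFAULT",
    "FamilySpec",
    "ClosedFormResult",
    "family_graph",
    "path_delta_profile",
    "banana_delta_profile",
    "family_closed_form",
]

#: The standard validation sweep: every (kind, params) pair over which the
#: closed forms are checked against direct computation.
SWEEP_DEFAULT: list[tuple[str, tuple[int, ...]]] = (
    [("path", (n,)) for n in range(3, 31)]
    + [("cycle", (n,)) for n in range(3, 31)]
    + [("star", (r,)) for r in range(1, 21)]
    + [("double_star", (r, s)) for r in range(1, 11) for s in range(1, 11)]
    + [("wheel", (n,)) for n in range(5, 21)]
    + [("complete", (n,)) for n in range(1, 9)]
    + [("complete_bipartite", (r, s)) for r in range(1, 11) for s in range(1, 11)]
    + [("banana", (r, s)) for r in range(2, 7) for s in range(3, 9)]
)

FAMILY_KINDS = (
    "path", "cycle", "star", "double_star", "wheel",
    "complete", "complete_bipartite", "banana",
)

# kind -> (arity, [(bound, message), ...]) with bound a predicate on params
_BOUNDS = {
    "path": (1, lambda p: p[0] >= 1, "path requires n >= 1"),
    "cycle": (1, lambda p: p[0] >= 3, "cycle requires n >= 3"),
    "star": (1, lambda p: p[0] >= 1, "star requires r >= 1"),
    "double_star": (2, lambda p: p[0] >= 1 and p[1] >= 1,
                    "double star requires r, s >= 1"),
    "wheel": (1, lambda p: p[0] >= 5, "wheel requires n >= 5 vertices"),
    "complete": (1, lambda p: p[0] >= 1, "complete requires n >= 1"),
    "complete_bipartite": (2, lambda p: p[0] >= 1 and p[1] >= 1,
                           "complete bipartite requires r, s >= 1"),
    "banana": (2, lambda p: p[0] >= 2 and p[1] >= 3,
               "banana requires r >= 2 and s >= 3"),
}


@dataclass(frozen=True)
class FamilySpec:
    """A family name plus its integer parameters, validated on construction."""

    kind: str
    params: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.kind not in FAMILY_KINDS:
            raise ParameterError(f"unknown family {self.kind!r}; one of {FAMILY_KINDS}")
        arity, ok, msg = _BOUNDS[self.kind]
        if len(self.params) != arity:
            raise ParameterError(f"{self.kind} takes {arity} parameter(s)")
        if not ok(self.params):
            raise ParameterError(msg)


@dataclass(frozen=True)
class ClosedFormResult:
    """Closed-form (or flagged fallback) values of ENM1, ENM2, ENM3."""

    enm1: int
    enm2: int
    enm3: int
    #: names of indices obtained by direct computation because the closed
    #: form does not cover the parameters (e.g. ENM2 of P4)
    fallback: frozenset[str] = frozenset()


def family_graph(spec: FamilySpec) -> nx.Graph:
    """Construct the canonically labeled graph of a family."""
    kind, p = spec.kind, spec.params
    G = nx.Graph()
    if kind == "path":
        n = p[0]
        G.add_nodes_from(range(1, n + 1))
        G.add_edges_from((i, i + 1) for i in range(1, n))
    elif kind == "cycle":
        n = p[0]
        G.add_edges_from((i, i + 1) for i in range(1, n))
        G.add_edge(n, 1)
    elif kind == "star":
        r = p[0]
        G.add_node(1)
        G.add_edges_from((1, i) for i in range(2, r + 2))
    elif kind == "double_star":
        r, s = p
        G.add_edge(1, 2)
        G.add_edges_from((1, 2 + i) for i in range(1, r + 1))
        G.add_edges_from((2, 2 + r + i) for i in range(1, s + 1))
    elif kind == "wheel":
        n = p[0]
        G.add_edges_from((i, i + 1) for i in range(2, n))
        G.add_edge(n, 2)
        G.add_edges_from((1, i) for i in range(2, n + 1))
    elif kind == "complete":
        G = nx.complete_graph(range(1, p[0] + 1))
    elif kind == "complete_bipartite":
        r, s = p
        G.add_edges_from((i, r + j) for i in range(1, r + 1) for j in range(1, s + 1))
    elif kind == "banana":
        r, s = p
        G.add_node(1)
        nxt = 2
        for _ in range(r):
            connector, center = nxt, nxt + 1
            G.add_edge(1, connector)
            G.add_edge(connector, center)
            for k in range(s - 2):
                G.add_edge(center, nxt + 2 + k)
            nxt += s
    return G


def path_delta_profile(n: int) -> DeltaEnProfile:
    """delta_en profile of the path P_n, by the piecewise closed form.

    Endpoints get n-2; the one (odd n) or two (even n) central vertices get
    n+1; on the first half the value decreases as 2n-2i, mirrored on the
    second half.  Requires n >= 3 (P2's profile is not covered).
    """
    if n < 3:
        raise ParameterError("path delta profile requires n >= 3")
    half = n // 2 if n % 2 == 0 else (n + 1) // 2
    prof: dict[int, int] = {}
    for i in range(1, n + 1):
        if i in (1, n):
            prof[i] = n - 2
        elif (n % 2 == 0 and i in (half, half + 1)) or (n % 2 == 1 and i == half):
            prof[i] = n + 1
        elif i < half:
            prof[i] = 2 * n - 2 * i
        else:
            prof[i] = 2 * i - 2
    return DeltaEnProfile(delta_en=prof)


def banana_delta_profile(r: int, s: int) -> DeltaEnProfile:
    """delta_en profile of the banana tree B_{r,s}, by vertex role.

    Root: 4r; each star center: 6s-8; each connector leaf (adjacent to both
    its center and the root): 8; each pendant leaf: 5.
    """
    FamilySpec("banana", (r, s))
    prof = {1: 4 * r}
    nxt = 2
    for _ in range(r):
        prof[nxt] = 8            # connector
        prof[nxt + 1] = 6 * s - 8  # center
        for k in range(s - 2):
            prof[nxt + 2 + k] = 5  # pendant
        nxt += s
    return DeltaEnProfile(delta_en=prof)


def _direct(spec: FamilySpec) -> tuple[int, int, int]:
    G = family_graph(spec)
    b = _ix.index_bundle(G)
    return b.enm1, b.enm2, b.enm3


def family_closed_form(spec: FamilySpec) -> ClosedFormResult:
    """Closed-form ENM1/ENM2/ENM3 of a family member.

    Exact polynomial formulas where they are valid; parameters outside a
    formula's range (S_1, K_{1,s}, short paths for ENM2, P_1/P_2) are
    computed directly and flagged in ``fallback``.
    """
    kind, p = spec.kind, spec.params
    fb: set[str] = set()

    if kind == "path":
        n = p[0]
        if n % 2 == 0 and n >= 4:
            e1 = (7 * n**3 - 27 * n**2 + 38 * n + 6) // 3
            e3 = 3 * n**2 - 8 * n + 8
        elif n % 2 == 1 and n >= 3:
            e1 = (7 * n**3 - 27 * n**2 + 35 * n + 3) // 3
            e3 = 3 * n**2 - 8 * n + 7
        else:
            e1, _, e3 = _direct(spec)
            fb |= {"enm1", "enm3"}
        if n % 2 == 0 and n >= 6:
            e2 = (7 * n**3 - 33 * n**2 + 56 * n + 15) // 3
        elif n % 2 == 1 and n >= 5:
            e2 = (7 * n**3 - 33 * n**2 + 53 * n + 9) // 3
        else:
            _, e2, _ = _direct(spec)
            fb.add("enm2")
    elif kind == "cycle":
        # the odd formulas are exact at n=3 as well (C3 = K3)
        n = p[0]
        if n % 2 == 0:
            e1 = e2 = n**3
            e3 = 2 * n**2
        else:
            e1 = e2 = n * (n - 1) ** 2
            e3 = 2 * n * (n - 1)
    elif kind == "star":
        r = p[0]
        if r >= 2:
            e1, e2, e3 = 4 * r**2 + r, 2 * r**2, 2 * r**2 + r
        else:  # S1 = K2: both vertices have eccentricity 1, not the 1/2 split
            e1, e2, e3 = _direct(spec)
            fb |= {"enm1", "enm2", "enm3"}
    elif kind == "double_star":
        r, s = p
        e1 = 9 * (r**2 + s**2) + 16 * (r + s) + 8
        e2 = (2 + 3 * r) * (2 * r + 3 * s + 2) + 2 * s * (2 + 3 * s)
        e3 = (4 + 3 * r) * r + (3 * s + 4) * s + 3 * (r + s) + 4
    elif kind == "wheel":
        n = p[0]
        e1 = 4 * n**2 + 17 * n - 21
        e2 = 10 * n**2 + 5 * n - 15
        e3 = 2 * n**2 + 11 * n - 13
    elif kind == "complete":
        # every vertex: ecc = 1, delta_en = n-1
        n = p[0]
        e1 = n * (n - 1) ** 2
        e2 = n * (n - 1) ** 3 // 2
        e3 = n * (n - 1) ** 2
    elif kind == "complete_bipartite":
        r, s = p
        if min(r, s) >= 2:
            e1 = 4 * (r * s**2 + s * r**2)
            e2 = 4 * r**2 * s**2
            e3 = 2 * (r * s**2 + s * r**2)
        else:  # K_{1,s} is a star: one side universal, formulas above break
            e1, e2, e3 = _direct(spec)
            fb |= {"enm1", "enm2", "enm3"}
    elif kind == "banana":
        r, s = p
        e1 = 16 * r**2 + 36 * s**2 * r - 71 * s * r + 78 * r
        e2 = 32 * r**2 + 30 * s**2 * r - 52 * s * r + 16 * r
        e3 = 4 * r**2 + 6 * s**2 * r - 9 * r * s + 14 * r
    else:  # pragma: no cover - FamilySpec already validates kind
        raise ParameterError(kind)

    return ClosedFormResult(enm1=e1, enm2=e2, enm3=e3, fallback=frozenset(fb))
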