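"""Edge-list file I/O and seeded random-graph generation.

Edge-list format: UTF-8 text, one edge per line as two whitespace-separated
labels; lines starting with ``#`` are comments; an optional ``n=<count>``
header declares the vertex count (allowing isolated vertices, which make the
graph disconnected and hence unusable for the distance-based indices - the
read itself still succeeds).  Arbitrary string labels are mapped to 1-based
integers in order of first appearance; the mapping is kept in
``G.graph["labels"]``.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .graph_core import GraphError, build_graph

__all__ = ["RandomGraphSpec", "read_edgelist", "write_edgelist", "random_graph"]

_ER_RETRY_CAP = 1000


def read_edgelist(path: str | Path) -> nx.Graph:
    """Parse an edge-list file into a validated graph."""
    labels: dict[str, int] = {}

    def intern(tok: str) -> int:
        if tok not in labels:
            labels[tok] = len(labels) + 1
        return labels[tok]

    edges: list[tuple[int, int]] = []
    n = None
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("n="):
            n = int(line[2:])
            continue
        parts = line.split()
        if len(parts) != 2:
            raise GraphError(f"{path}:{lineno}: expected two labels, got {line!r}")
        u, v = intern(parts[0]), intern(parts[1])
        if u == v:
            raise GraphError(f"{path}:{lineno}: self-loop on {parts[0]!r}")
        edges.append((u, v))
    if n is not None and n < len(labels):
        raise GraphError(f"{path}: header n={n} smaller than {len(labels)} labels seen")
    G = build_graph(edges, n=n if n is not None else None)
    G.graph["labels"] = labels
    return G


def write_edgelist(G: nx.Graph, path: str | Path) -> None:
    """Write a graph back out, preserving original labels when present."""
    labels = G.graph.get("labels")
    inv = {v: k for k, v in labels.items()} if labels else {}
    lines = [f"n={G.number_of_nodes()}"]
    lines += [f"{inv.get(u, u)} {inv.get(v, v)}" for u, v in sorted(map(sorted, G.edges()))]
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class RandomGraphSpec:
    """A reproducible random-graph request.

    model "tree": uniform random labeled tree on n vertices.
    model "er": Erdos-Renyi G(n, p) conditioned on connectivity by rejection.
    """

    model: str  # "tree" | "er"
    n: int
    seed: int
    p: float | None = None


def random_graph(spec: RandomGraphSpec) -> nx.Graph:
    """Generate the connected graph described by ``spec`` (bit-reproducible)."""
    if spec.n < 1:
        raise GraphError("random graph requires n >= 1")
    if spec.model == "tree":
        T = nx.random_labeled_tree(spec.n, seed=spec.seed)
        return nx.relabel_nodes(T, {v: v + 1 for v in T.nodes})
    if spec.model != "er":
        raise GraphError(f"unknown random graph model {spec.model!r}")
    if spec.p is None or not 0 < spec.p <= 1:
        raise GraphError("ER model requires 0 < p <= 1")
    rng = random.Random(spec.seed)
    for _ in range(_ER_RETRY_CAP):
        G = nx.gnp_random_graph(spec.n, spec.p, seed=rng)
        if nx.is_connected(G):
            return nx.relabel_nodes(G, {v: v + 1 for v in G.nodes})
    raise GraphError(
        f"no connected G({spec.n}, {spec.p}) in {_ER_RETRY_CAP} tries; increase p"
    )
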