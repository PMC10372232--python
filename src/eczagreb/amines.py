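"""Bundled molecular graphs of 21 primary amines and the published
descriptor table.

The compounds are the classic primary-amine calibration set used for
boiling-point QSPR work.  Each record carries the hydrogen-suppressed
molecular graph (heavy atoms C and N as vertices, single bonds as edges;
all 21 structures are trees), the experimental boiling point in deg C, and
the five descriptor values as published (xi_c, W, ENM1, ENM2, ENM3) -
stored verbatim, typos included.  Atom identity plays no role in any of the
descriptors and is not stored.

:func:`discrepancy_report` recomputes every descriptor from the structures
and compares cell by cell against the published numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import networkx as nx
import pandas as pd

from .graph_core import GraphError, build_graph
from .indices import index_bundle

__all__ = [
    "CompoundRecord",
    "DiscrepancyCell",
    "DiscrepancyReport",
    "load_compounds",
    "computed_table1",
    "discrepancy_report",
]

DESCRIPTORS = ("xi_c", "wiener", "enm1", "enm2", "enm3")


@dataclass(frozen=True)
class CompoundRecord:
    """One primary amine: name, heavy-atom edge list, boiling point and the
    published descriptor row."""

    name: str
    heavy_atom_edges: tuple[tuple[int, int], ...]
    bp_celsius: float
    printed: dict[str, int]  # keyed by DESCRIPTORS

    def graph(self) -> nx.Graph:
        return build_graph(self.heavy_atom_edges)


@dataclass(frozen=True)
class DiscrepancyCell:
    compound: str
    descriptor: str
    printed: int
    computed: int

    @property
    def match(self) -> bool:
        return self.printed == self.computed


@dataclass(frozen=True)
class DiscrepancyReport:
    """Cell-by-cell comparison of published vs recomputed descriptors."""

    cells: tuple[DiscrepancyCell, ...]

    @property
    def mismatches(self) -> tuple[DiscrepancyCell, ...]:
        return tuple(c for c in self.cells if not c.match)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.compound, c.descriptor, c.printed, c.computed, c.match)
             for c in self.cells],
            columns=["compound", "descriptor", "printed", "computed", "match"],
        )


def _parse_blocks(text: str):
    block: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            if block:
                yield block
                block = {}
            continue
        key, _, val = line.partition(":")
        block[key.strip()] = val.strip()
    if block:
        yield block


def load_compounds() -> list[CompoundRecord]:
    """Load the 21 bundled amine records, validating each graph is a tree."""
    text = (resources.files("eczagreb") / "data" / "primary_amines.txt").read_text()
    records = []
    for block in _parse_blocks(text):
        name = block["compound"]
        edges = tuple(
            tuple(int(x) for x in token.split("-")) for token in block["edges"].split()
        )
        printed_vals = [int(x) for x in block["printed"].split()]
        rec = CompoundRecord(
            name=name,
            heavy_atom_edges=edges,
            bp_celsius=float(block["bp"]),
            printed=dict(zip(DESCRIPTORS, printed_vals)),
        )
        G = rec.graph()
        if not nx.is_tree(G):
            raise GraphError(f"fixture graph for {name} is not a tree")
        if G.number_of_edges() != G.number_of_nodes() - 1:
            raise GraphError(f"edge/vertex count mismatch for {name}")
        records.append(rec)
    if len(records) != 21:
        raise GraphError(f"expected 21 compounds, found {len(records)}")
    return records


def computed_table1(compounds: list[CompoundRecord]) -> pd.DataFrame:
    """Recompute the five descriptors for every compound, in fixture order."""
    rows = []
    for rec in compounds:
        b = index_bundle(rec.graph())
        rows.append((rec.name, b.xi_c, b.wiener, b.enm1, b.enm2, b.enm3))
    return pd.DataFrame(rows, columns=("compound",) + DESCRIPTORS).set_index("compound")


def discrepancy_report(compounds: list[CompoundRecord]) -> DiscrepancyReport:
    """Compare every published descriptor cell with the recomputed value."""
    computed = computed_table1(compounds)
    cells = []
    for rec in compounds:
        for d in DESCRIPTORS:
            cells.append(
                DiscrepancyCell(
                    compound=rec.name,
                    descriptor=d,
                    printed=rec.printed[d],
                    computed=int(computed.loc[rec.name, d]),
                )
            )
    return DiscrepancyReport(cells=tuple(cells))
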