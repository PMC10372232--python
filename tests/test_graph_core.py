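"""Graph substrate: construction, eccentricities, delta_en."""

import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from eczagreb.graph_core import (
    DisconnectedGraphError,
    GraphError,
    build_graph,
    delta_en_profile,
    eccentricities,
    universal_vertices,
)
from eczagreb.families import FamilySpec, family_graph

from conftest import naive_descriptors


def path(n):
    return family_graph(FamilySpec("path", (n,)))


class TestBuildGraph:
    def test_path_from_edges(self):
        G = build_graph([(1, 2), (2, 3), (3, 4)])
        assert sorted(d for _, d in G.degree()) == [1, 1, 2, 2]

    def test_singleton_via_n(self):
        G = build_graph([], n=1)
        assert G.number_of_nodes() == 1 and G.number_of_edges() == 0

    def test_duplicate_edges_collapsed_and_counted(self):
        G = build_graph([(1, 2), (2, 1)])
        assert G.number_of_edges() == 1
        assert G.graph["duplicates"] == 1

    @pytest.mark.parametrize("edges", [[(1, 1)], [(0, 2)], [(-1, 3)]])
    def test_invalid_edges_rejected(self, edges):
        with pytest.raises(GraphError):
            build_graph(edges)

    def test_empty_vertex_set_rejected(self):
        with pytest.raises(GraphError):
            build_graph([])

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.tuples(st.integers(1, 9), st.integers(1, 9))
                    .filter(lambda e: e[0] != e[1]), min_size=1, max_size=25))
    def test_handshake_invariant(self, edges):
        """Adjacency is symmetric and |E| equals half the degree sum."""
        G = build_graph(edges)
        assert all(G.has_edge(v, u) for u, v in G.edges())
        assert 2 * G.number_of_edges() == sum(d for _, d in G.degree())
        assert G.graph["duplicates"] == len(edges) - G.number_of_edges()


class TestEccentricities:
    def test_path_endpoints(self):
        prof = eccentricities(path(4))
        assert [prof.ecc[i] for i in range(1, 5)] == [3, 2, 2, 3]
        assert (prof.radius, prof.diameter) == (2, 3)

    def test_even_cycle_constant(self):
        prof = eccentricities(family_graph(FamilySpec("cycle", (6,))))
        assert set(prof.ecc.values()) == {3}

    def test_wheel_hub_and_rim(self):
        prof = eccentricities(family_graph(FamilySpec("wheel", (6,))))
        assert prof.ecc[1] == 1
        assert all(prof.ecc[v] == 2 for v in range(2, 7))

    def test_singleton_convention(self):
        prof = eccentricities(build_graph([], n=1))
        assert prof.ecc == {1: 0} and prof.radius == prof.diameter == 0

    def test_disconnected_rejected(self):
        G = build_graph([(1, 2)], n=3)
        with pytest.raises(DisconnectedGraphError, match="disconnected"):
            eccentricities(G)

    def test_agrees_with_floyd_warshall(self, random_connected_graphs):
        for G in random_connected_graphs:
            if G.number_of_nodes() > 8:
                continue
            assert eccentricities(G).ecc == naive_descriptors(G)["ecc"]


class TestUniversalVertices:
    def test_k2_both(self):
        assert universal_vertices(path(2)) == {1, 2}

    def test_path_none(self):
        assert universal_vertices(path(4)) == frozenset()

    def test_wheel_hub_only(self):
        assert universal_vertices(family_graph(FamilySpec("wheel", (6,)))) == {1}

    def test_singleton_empty(self):
        assert universal_vertices(build_graph([], n=1)) == frozenset()


class TestDeltaEn:
    def test_p6_profile(self):
        prof = delta_en_profile(path(6))
        assert [prof.delta_en[i] for i in range(1, 7)] == [4, 8, 7, 7, 8, 4]

    def test_banana_roles(self):
        """B_{2,3}: root 8, connectors 8, centers 10, pendants 5."""
        G = family_graph(FamilySpec("banana", (2, 3)))
        d = delta_en_profile(G).delta_en
        assert d[1] == 8
        assert sorted(d.values()) == sorted([8, 8, 8, 10, 10, 5, 5])

    def test_singleton_zero(self):
        assert delta_en_profile(build_graph([], n=1)).delta_en == {1: 0}

    def test_sum_equals_eccentric_connectivity(self, random_connected_graphs):
        from eczagreb.indices import eccentric_connectivity

        for G in random_connected_graphs:
            assert delta_en_profile(G).total() == eccentric_connectivity(G)

    def test_degree_radius_diameter_sandwich(self, random_connected_graphs):
        for G in random_connected_graphs:
            prof = eccentricities(G)
            d = delta_en_profile(G, prof).delta_en
            for v in G:
                assert G.degree(v) * prof.radius <= d[v] <= G.degree(v) * prof.diameter

    def test_self_centered_graphs_scale_degree(self):
        """Constant eccentricity c forces delta_en = c * degree."""
        for G in (family_graph(FamilySpec("cycle", (7,))),
                  family_graph(FamilySpec("complete", (5,))),
                  family_graph(FamilySpec("complete_bipartite", (3, 4,)))):
            prof = eccentricities(G)
            assert prof.radius == prof.diameter
            d = delta_en_profile(G, prof).delta_en
            assert all(d[v] == prof.radius * G.degree(v) for v in G)
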