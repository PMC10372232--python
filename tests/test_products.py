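"""Graph products: constructions, eccentricity/delta_en formulas, closed forms."""

import networkx as nx
import pytest

from eczagreb.families import FamilySpec, family_graph
from eczagreb.graph_core import (
    GraphError,
    NoClosedFormError,
    build_graph,
    delta_en_profile,
    eccentricities,
    universal_vertices,
)
from eczagreb.indices import index_bundle
from eczagreb.products import (
    ProductKind,
    join_edge_partition,
    product_delta_en,
    product_eccentricities,
    product_enm_closed,
    product_graph,
)


def fg(kind, *params):
    return family_graph(FamilySpec(kind, params))


P2, P4 = fg("path", 2), fg("path", 4)


class TestProductGraph:
    def test_join_k1_c4_is_wheel(self):
        W = product_graph(ProductKind.JOIN, build_graph([], n=1), fg("cycle", 4))
        assert nx.is_isomorphic(W, nx.wheel_graph(5))

    def test_symmetric_difference_p2_p4(self):
        P = product_graph(ProductKind.SYMMETRIC_DIFFERENCE, P2, P4)
        assert P.number_of_nodes() == 8 and P.number_of_edges() == 16
        assert set(dict(P.degree()).values()) == {4}

    def test_composition_equals_disjunction_for_k2_factor(self):
        A = product_graph(ProductKind.COMPOSITION, P2, P4)
        B = product_graph(ProductKind.DISJUNCTION, P2, P4)
        assert set(A.edges()) == set(B.edges())
        assert A.number_of_edges() == 22

    def test_empty_factor_rejected(self):
        with pytest.raises(GraphError):
            product_graph(ProductKind.JOIN, nx.Graph(), P4)

    def test_trivial_factor_rejected_outside_join(self):
        K1 = build_graph([], n=1)
        for kind in (ProductKind.DISJUNCTION, ProductKind.COMPOSITION,
                     ProductKind.SYMMETRIC_DIFFERENCE):
            with pytest.raises(GraphError):
                product_graph(kind, K1, P4)


class TestProductEccentricities:
    def test_join_sides(self):
        ecc = product_eccentricities(ProductKind.JOIN, P2, P4).ecc
        assert [ecc[i] for i in range(1, 7)] == [1, 1, 2, 2, 2, 2]

    def test_symmetric_difference_constant_two(self):
        ecc = product_eccentricities(ProductKind.SYMMETRIC_DIFFERENCE, P2, P4).ecc
        assert set(ecc.values()) == {2}

    def test_matches_bfs_oracle(self, factor_pairs):
        for G, H in factor_pairs:
            for kind in ProductKind:
                formula = product_eccentricities(kind, G, H)
                direct = eccentricities(product_graph(kind, G, H))
                assert formula.ecc == direct.ecc, (kind, sorted(G.edges()), sorted(H.edges()))


class TestProductDeltaEn:
    def test_join_p2_p4_values(self):
        d = product_delta_en(ProductKind.JOIN, P2, P4).delta_en
        assert [d[i] for i in range(1, 7)] == [9, 9, 4, 6, 6, 4]

    def test_symmetric_difference_regular(self):
        d = product_delta_en(ProductKind.SYMMETRIC_DIFFERENCE, P2, P4).delta_en
        assert set(d.values()) == {8}

    def test_disjunction_no_universal_pair_gives_twice_degree(self):
        G, H = fg("path", 4), fg("cycle", 5)  # no universal vertices anywhere
        P = product_graph(ProductKind.DISJUNCTION, G, H)
        d = product_delta_en(ProductKind.DISJUNCTION, G, H).delta_en
        assert all(d[v] == 2 * P.degree(v) for v in P)

    def test_matches_direct_oracle(self, factor_pairs):
        for G, H in factor_pairs:
            for kind in ProductKind:
                formula = product_delta_en(kind, G, H)
                direct = delta_en_profile(product_graph(kind, G, H))
                assert formula.delta_en == direct.delta_en, (
                    kind, sorted(G.edges()), sorted(H.edges()))


class TestJoinEdgePartition:
    def test_p2_p4_classes(self):
        part = join_edge_partition(P2, P4)
        sizes = {k: len(v) for k, v in part.classes().items()}
        assert sizes == {"E11": 0, "E12": 1, "E13": 0, "E21": 3, "E22": 0,
                         "E23": 0, "E31": 0, "E32": 0, "E33": 8, "E34": 0}

    def test_no_universal_vertices_collapses_to_three_classes(self):
        part = join_edge_partition(P4, fg("cycle", 5))
        sizes = {k: len(v) for k, v in part.classes().items()}
        assert sizes["E11"] == 3 and sizes["E21"] == 5 and sizes["E31"] == 20
        assert all(v == 0 for k, v in sizes.items() if k not in ("E11", "E21", "E31"))

    def test_partitions_the_join_edge_set(self, factor_pairs):
        for G, H in factor_pairs[:40]:
            part = join_edge_partition(G, H)
            classes = part.classes()
            all_edges = [frozenset(e) for cl in classes.values() for e in cl]
            assert len(all_edges) == len(set(all_edges))  # pairwise disjoint
            J = product_graph(ProductKind.JOIN, G, H)
            assert set(all_edges) == {frozenset(e) for e in J.edges()}
            cross = sum(len(classes[k]) for k in ("E31", "E32", "E33", "E34"))
            assert cross == G.number_of_nodes() * H.number_of_nodes()


class TestClosedForms:
    @pytest.mark.parametrize("kind,expected", [
        (ProductKind.JOIN, (266, 525, 162)),
        (ProductKind.COMPOSITION, (976, 2704, 488)),
        (ProductKind.SYMMETRIC_DIFFERENCE, (512, 1024, 256)),
    ])
    def test_p2_p4_worked_examples(self, kind, expected):
        assert product_enm_closed(kind, P2, P4) == expected
        b = index_bundle(product_graph(kind, P2, P4))
        assert (b.enm1, b.enm2, b.enm3) == expected

    def test_complete_bipartite_via_join_of_edgeless(self):
        E2, E3 = build_graph([], n=2), build_graph([], n=3)
        closed = product_enm_closed(ProductKind.JOIN, E2, E3)
        assert closed == (120, 144, 60)  # 4(rs^2+sr^2), 4r^2s^2, 2(rs^2+sr^2)
        b = index_bundle(product_graph(ProductKind.JOIN, E2, E3))
        assert (b.enm1, b.enm2, b.enm3) == closed

    def test_complete_factors_give_complete_product(self):
        K3, K4 = fg("complete", 3), fg("complete", 4)
        for kind in (ProductKind.DISJUNCTION, ProductKind.COMPOSITION):
            b = index_bundle(fg("complete", 12))
            assert product_enm_closed(kind, K3, K4) == (b.enm1, b.enm2, b.enm3)

    def test_composition_without_universal_left_factor_has_no_closed_form(self):
        with pytest.raises(NoClosedFormError):
            product_enm_closed(ProductKind.COMPOSITION, P4, fg("star", 2))

    def test_matches_direct_computation(self, factor_pairs):
        """Closed-form product indices equal direct computation for all four operations."""
        checked = {k: 0 for k in ProductKind}
        for G, H in factor_pairs:
            for kind in ProductKind:
                try:
                    closed = product_enm_closed(kind, G, H)
                except NoClosedFormError:
                    assert kind is ProductKind.COMPOSITION
                    assert not universal_vertices(G)
                    continue
                b = index_bundle(product_graph(kind, G, H))
                assert closed == (b.enm1, b.enm2, b.enm3), (
                    kind, sorted(G.edges()), sorted(H.edges()))
                checked[kind] += 1
        assert all(c >= 100 for k, c in checked.items()
                   if k is not ProductKind.COMPOSITION)
        assert checked[ProductKind.COMPOSITION] >= 50

    def test_commutative_kinds_are_order_invariant(self, factor_pairs):
        for G, H in factor_pairs[:30]:
            for kind in (ProductKind.DISJUNCTION, ProductKind.SYMMETRIC_DIFFERENCE):
                assert product_enm_closed(kind, G, H) == product_enm_closed(kind, H, G)
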