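"""Domain types: typed graphs, hierarchy classification, ordered partitions."""

import itertools

import pytest

from hnauty import (
    HierarchicalMoleculeGraph,
    OrderedPartition,
    assign_attributes,
    build_graph,
    classify_hierarchy,
    is_refinement,
    partition_shape,
)

from .conftest import relabeled_copy


class TestBuildGraph:
    def test_lck_species_fixture_shape(self, lck):
        g = lck.underlying
        assert g.n == 7
        assert sum(1 for *_, e in g.edges if e == 0) == 6
        assert sum(1 for *_, e in g.edges if e == 1) == 1
        assert g.attributes["Y505"] == "P"

    def test_edgeless_graph_is_valid(self):
        g = build_graph([("a", "x"), ("b", "x"), ("c", "x")], [], ["undirected"])
        assert g.n == 3 and not g.edges

    @pytest.mark.parametrize(
        "edges",
        [
            [("a", "b", 0), ("a", "b", 0)],  # same directed pair twice
            [("a", "b", 1), ("b", "a", 1)],  # same undirected pair, reversed
        ],
    )
    def test_duplicate_same_type_edge_rejected(self, edges):
        with pytest.raises(ValueError, match="duplicate"):
            build_graph([("a", "x"), ("b", "x")], edges, ["directed", "undirected"])

    def test_unknown_endpoint_rejected(self):
        with pytest.raises(ValueError, match="undeclared"):
            build_graph([("a", "x")], [("a", "zzz", 0)], ["directed"])

    def test_out_of_range_edge_type_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            build_graph([("a", "x"), ("b", "x")], [("a", "b", 3)], ["directed"])

    def test_attribute_must_be_in_possible_list(self):
        with pytest.raises(ValueError, match="not in its possible list"):
            build_graph([("a", "Y", ("U", "P"), "Q")], [], ["directed"])

    def test_undirected_edges_normalized(self):
        g1 = build_graph([("a", "x"), ("b", "x")], [("a", "b", 0)], ["undirected"])
        g2 = build_graph([("a", "x"), ("b", "x")], [("b", "a", 0)], ["undirected"])
        assert g1.edges == g2.edges


class TestClassifyHierarchy:
    def test_lck_is_strict(self, lck):
        assert classify_hierarchy(lck) == "strict_hierarchy"

    def test_tcr_is_pseudo(self, tcr):
        # Y188 sits under both the PRS and the ITAM of CD3-epsilon
        assert classify_hierarchy(tcr) == "pseudo_hierarchy"

    def test_two_cycle_is_invalid(self):
        g = build_graph(
            [("a", "x"), ("b", "x")],
            [("a", "b", 0), ("b", "a", 0)],
            ["directed", "undirected"],
        )
        assert classify_hierarchy(g) == "invalid"

    def test_invariant_under_renaming(self, tcr):
        for seed in range(5):
            assert classify_hierarchy(relabeled_copy(tcr.underlying, seed)) == "pseudo_hierarchy"

    def test_invalid_hierarchy_rejected_by_molecule_wrapper(self):
        g = build_graph(
            [("a", "x"), ("b", "x")],
            [("a", "b", 0), ("b", "a", 0)],
            ["directed", "undirected"],
        )
        with pytest.raises(ValueError, match="cycle"):
            HierarchicalMoleculeGraph(g)


class TestAssignAttributes:
    def test_lck_assignment_gives_species(self, lck_entity_graph):
        sp = assign_attributes(
            lck_entity_graph, {"Y192": "U", "Y394": "U", "Y505": "P"}
        )
        assert sp.flavor == "species"
        assert sp.underlying.attributes["Y505"] == "P"
        # labels never change; only attributes do
        assert sp.underlying.labels == lck_entity_graph.underlying.labels

    def test_no_attributed_vertices_empty_assignment(self):
        g = build_graph(
            [("a", "x"), ("b", "x")], [("a", "b", 0)], ["directed", "undirected"]
        )
        entity = HierarchicalMoleculeGraph(g, flavor="entity")
        sp = assign_attributes(entity, {})
        assert sp.flavor == "species" and sp.underlying == g

    def test_out_of_list_value_rejected(self, lck_entity_graph):
        with pytest.raises(ValueError, match="possible list"):
            assign_attributes(
                lck_entity_graph, {"Y192": "U", "Y394": "U", "Y505": "Q"}
            )

    def test_incomplete_assignment_rejected(self, lck_entity_graph):
        with pytest.raises(ValueError, match="exactly the attributed"):
            assign_attributes(lck_entity_graph, {"Y192": "U"})

    def test_species_flavor_rejected_as_input(self, lck):
        with pytest.raises(ValueError, match="entity"):
            assign_attributes(lck, {"Y192": "U", "Y394": "U", "Y505": "P"})


class TestPartitionShape:
    @pytest.mark.parametrize(
        "cells, expected",
        [
            ([{"0", "1"}, {"6"}, {"5"}, {"2", "3", "4", "7"}], (2, 1, 0, 1)),
            ([{"a"}, {"b"}, {"c"}, {"d"}, {"e"}], (5,)),
            ([{"a", "b", "c", "d"}], (0, 0, 0, 1)),
        ],
    )
    def test_reference_and_degenerate_shapes(self, cells, expected):
        assert partition_shape(OrderedPartition(cells)) == expected

    def test_invariant_under_cell_reordering_and_renaming(self):
        p = OrderedPartition([{"a", "b"}, {"c"}, {"d", "e"}])
        q = OrderedPartition([{"d", "e"}, {"a", "b"}, {"c"}])
        r = OrderedPartition([{"x", "y"}, {"z"}, {"u", "w"}])
        assert partition_shape(p) == partition_shape(q) == partition_shape(r)


def _ordered_partitions(elements):
    """All ordered partitions of a set (set partitions x cell orderings)."""

    def set_partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for part in set_partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [part[i] | {first}] + part[i + 1 :]
            yield part + [{first}]

    for part in set_partitions(list(elements)):
        for perm in itertools.permutations(part):
            yield OrderedPartition(perm)


class TestIsRefinement:
    def test_reference_example(self):
        p = OrderedPartition([{"1", "5"}, {"2", "3"}, {"4"}])
        q = OrderedPartition([{"1", "5"}, {"2", "3", "4"}])
        assert is_refinement(p, q)

    def test_reflexive(self):
        p = OrderedPartition([{"a", "b"}, {"c"}])
        assert is_refinement(p, p)

    def test_first_cell_condition_violated(self):
        p = OrderedPartition([{"2", "3"}, {"1", "5"}, {"4"}])
        q = OrderedPartition([{"1", "5"}, {"2", "3", "4"}])
        assert not is_refinement(p, q)

    def test_different_ground_sets_rejected(self):
        with pytest.raises(ValueError, match="different vertex sets"):
            is_refinement(
                OrderedPartition([{"a"}]), OrderedPartition([{"b"}])
            )

    def test_partial_order_on_four_elements(self):
        """Reflexivity, antisymmetry and transitivity, exhaustively."""
        parts = list(_ordered_partitions({"a", "b", "c", "d"}))
        assert len(parts) == 75  # ordered Bell number for n=4
        rel = {
            (i, j)
            for i, p in enumerate(parts)
            for j, q in enumerate(parts)
            if is_refinement(p, q)
        }
        for i in range(len(parts)):
            assert (i, i) in rel
        for i, j in rel:
            if (j, i) in rel:
                assert i == j
        for i, j in rel:
            for k in range(len(parts)):
                if (j, k) in rel:
                    assert (i, k) in rel


class TestOrderedPartitionInvariants:
    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            OrderedPartition([{"a"}, set()])

    def test_overlapping_cells_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            OrderedPartition([{"a", "b"}, {"b", "c"}])

    def test_discrete_and_trivial_flags(self):
        assert OrderedPartition([{"a"}, {"b"}]).is_discrete
        assert OrderedPartition([{"a", "b"}]).is_trivial
        assert not OrderedPartition([{"a", "b"}]).is_discrete
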