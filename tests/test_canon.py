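"""The individualization-refinement search: leaves, automorphisms, labels."""

import itertools
import random

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hnauty import (
    OrderedPartition,
    SearchStats,
    TypedGraph,
    are_isomorphic,
    automorphism_count,
    brute_automorphisms,
    brute_canonical,
    discover_automorphism,
    enumerate_leaves,
    hnauty_canonical,
    initial_partition,
    is_automorphism,
)

from .conftest import (
    all_single_type_graphs,
    random_two_type_graph,
    relabeled_copy,
    single_type_graph,
)


class TestInitialPartition:
    def test_uniform_labels_give_trivial_partition(self):
        g = single_type_graph(4, [(1, 2)])
        assert initial_partition(g).is_trivial

    def test_distinct_labels_give_discrete_partition(self, lck):
        assert initial_partition(lck.underlying).is_discrete

    def test_state_cells_ordered_by_color_rule(self):
        g = TypedGraph(
            ["a", "b"],
            {"a": "Y", "b": "Y"},
            [],
            (False,),
            {"a": ("U", "P"), "b": ("U", "P")},
            {"a": "U", "b": "P"},
        )
        # reverse-lexicographic on (label, possible, assigned): U before P
        assert initial_partition(g) == OrderedPartition([{"a"}, {"b"}])

    def test_invariant_to_input_vertex_order(self):
        g = TypedGraph(["a", "b", "c"], {"a": "x", "b": "y", "c": "x"}, [], (False,))
        h = TypedGraph(["c", "b", "a"], {"a": "x", "b": "y", "c": "x"}, [], (False,))
        assert initial_partition(g) == initial_partition(h)


class TestEnumerateLeaves:
    def test_g2_produces_exactly_the_two_reference_leaves(self, g2):
        leaves = enumerate_leaves(g2, pruning="none")
        assert leaves == [
            OrderedPartition([{"v1"}, {"v3"}, {"v2"}, {"v4"}, {"v5"}]),
            OrderedPartition([{"v3"}, {"v1"}, {"v2"}, {"v5"}, {"v4"}]),
        ]

    def test_edgeless_graph_generates_all_orderings(self):
        g = single_type_graph(3, [])
        leaves = enumerate_leaves(g, pruning="none")
        assert len(leaves) == 6
        assert len(set(l.ordering() for l in leaves)) == 6

    def test_g1_produces_twelve_leaves(self, g1):
        # every ordering placing v2 and v4 before v1, v3, v5
        assert len(enumerate_leaves(g1, pruning="none")) == 12

    def test_automorphism_pruning_visits_fewer_nodes(self, g1):
        full, pruned = SearchStats(), SearchStats()
        enumerate_leaves(g1, pruning="none", stats=full)
        enumerate_leaves(g1, pruning="automorphism", stats=pruned)
        assert pruned.nodes_visited < full.nodes_visited
        assert pruned.automorphisms_found >= 1


class TestDiscoverAutomorphism:
    def test_g2_leaf_pair_yields_the_swap(self, g2):
        l1, l2 = enumerate_leaves(g2, pruning="none")
        gamma = discover_automorphism(g2, l1, l2)
        assert gamma == {"v1": "v3", "v3": "v1", "v2": "v2", "v4": "v5", "v5": "v4"}
        assert is_automorphism(g2, gamma)

    def test_identical_leaves_yield_identity(self, g2):
        l1, _ = enumerate_leaves(g2, pruning="none")
        gamma = discover_automorphism(g2, l1, l1)
        assert gamma == {v: v for v in g2.vertices}

    def test_rigid_graph_leaves_yield_nothing(self):
        # spider with legs of lengths 1, 2, 3: certified rigid by brute force
        edges = [(1, 2), (1, 3), (3, 4), (1, 5), (5, 6), (6, 7)]
        g = single_type_graph(7, edges)
        assert len(brute_automorphisms(g)) == 1
        orderings = [
            OrderedPartition([{v} for v in g.vertices]),
            OrderedPartition([{v} for v in reversed(g.vertices)]),
        ]
        assert discover_automorphism(g, orderings[0], orderings[1]) is None


class TestCanonicalLabel:
    def test_isomorphic_triple_shares_one_label(self, triple):
        labels = {hnauty_canonical(g).label for g in triple}
        assert len(labels) == 1

    def test_single_vertex_label(self):
        g = single_type_graph(1, [])
        form = hnauty_canonical(g)
        assert form.label == "0" and form.ordering == ("v1",)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_label_invariant_under_relabeling(self, seed):
        rng = random.Random(seed)
        g = random_two_type_graph(rng, rng.randint(1, 9))
        h = relabeled_copy(g, seed + 1)
        assert hnauty_canonical(g).label == hnauty_canonical(h).label

    def test_fixture_labels_invariant_under_relabeling(self, lck, tcr_expanded, g1, g2):
        for g in (lck.underlying, tcr_expanded.underlying, g1, g2):
            base = hnauty_canonical(g).label
            for seed in range(3):
                assert hnauty_canonical(relabeled_copy(g, seed)).label == base

    def test_labels_define_the_same_equivalence_as_brute_force(self):
        """Two graphs get equal labels exactly when the brute-force oracle
        deems them isomorphic — on every single-type 4-vertex graph and on
        random two-type pairs."""
        graphs = list(all_single_type_graphs(4))
        ours = [hnauty_canonical(g).key() for g in graphs]
        brute = [brute_canonical(g) for g in graphs]
        for i in range(len(graphs)):
            for j in range(i + 1, len(graphs)):
                assert (ours[i] == ours[j]) == (brute[i] == brute[j])

    def test_two_type_label_equivalence_matches_brute(self):
        rng = random.Random(13)
        pairs_checked = same = 0
        for _ in range(150):
            g = random_two_type_graph(rng, 5)
            h = relabeled_copy(g, rng.randrange(1000)) if rng.random() < 0.5 else random_two_type_graph(rng, 5)
            ok_ours = hnauty_canonical(g).key() == hnauty_canonical(h).key()
            ok_brute = brute_canonical(g) == brute_canonical(h)
            assert ok_ours == ok_brute
            pairs_checked += 1
            same += ok_ours
        assert same > 0  # the suite exercises both verdicts
        assert same < pairs_checked

    def test_agrees_with_networkx_vf2(self):
        """Independent cross-check of the isomorphism verdict against the
        VF2 matcher on the multigraph export."""

        def nx_iso(a, b):
            em = nx.algorithms.isomorphism.categorical_multiedge_match(
                "edge_type", None
            )
            nm = nx.algorithms.isomorphism.categorical_node_match(
                ["label", "possible_attributes", "attribute"], [None, None, None]
            )
            return nx.is_isomorphic(
                a.to_networkx(), b.to_networkx(), node_match=nm, edge_match=em
            )

        rng = random.Random(29)
        for _ in range(40):
            g = random_two_type_graph(rng, 6)
            h = (
                relabeled_copy(g, rng.randrange(1000))
                if rng.random() < 0.5
                else random_two_type_graph(rng, 6)
            )
            assert are_isomorphic(g, h) == nx_iso(g, h)

    def test_pruning_modes_agree_and_prune(self):
        rng = random.Random(41)
        for _ in range(40):
            g = random_two_type_graph(rng, rng.randint(2, 8))
            forms = {
                mode: hnauty_canonical(g, pruning=mode)
                for mode in ("none", "automorphism", "automorphism+indicator")
            }
            labels = {f.label for f in forms.values()}
            assert len(labels) == 1
            assert (
                forms["automorphism+indicator"].stats.nodes_visited
                <= forms["automorphism"].stats.nodes_visited
                <= forms["none"].stats.nodes_visited
            )

    def test_unknown_pruning_mode_rejected(self, g2):
        with pytest.raises(ValueError, match="pruning"):
            hnauty_canonical(g2, pruning="bogus")


class TestAreIsomorphic:
    def test_triple_members_isomorphic(self, triple):
        assert are_isomorphic(triple[0], triple[1])
        assert are_isomorphic(triple[0], triple[2])

    def test_g1_g2_not_isomorphic(self, g1, g2):
        assert not are_isomorphic(g1, g2)
        assert hnauty_canonical(g1).label != hnauty_canonical(g2).label

    def test_self_isomorphic(self, lck):
        assert are_isomorphic(lck.underlying, lck.underlying)

    def test_incompatible_edge_type_tables_rejected(self, g1, lck):
        with pytest.raises(ValueError, match="incompatible"):
            are_isomorphic(g1, lck.underlying)

    def test_color_differences_separate_graphs(self):
        a = TypedGraph(["x", "y"], {"x": "A", "y": "A"}, [("x", "y", 0)], (False,))
        b = TypedGraph(["x", "y"], {"x": "A", "y": "B"}, [("x", "y", 0)], (False,))
        assert not are_isomorphic(a, b)


class TestAutomorphismCount:
    def test_g2_has_two(self, g2):
        assert automorphism_count(g2) == 2

    def test_g1_has_twelve(self, g1):
        # |Aut| of the complete bipartite graph on 2 + 3 vertices: 2! * 3!
        assert automorphism_count(g1) == 12

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_complete_graph_has_full_group(self, n):
        g = single_type_graph(n, itertools.combinations(range(1, n + 1), 2))
        assert automorphism_count(g) == __import__("math").factorial(n)

    def test_matches_brute_force_on_random_graphs(self):
        rng = random.Random(55)
        for _ in range(25):
            g = random_two_type_graph(rng, rng.randint(2, 6))
            assert automorphism_count(g) == len(brute_automorphisms(g))

    def test_size_guard(self):
        g = single_type_graph(11, [])
        with pytest.raises(ValueError, match="limited"):
            automorphism_count(g)
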