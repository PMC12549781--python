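"""Core model: parsing, validation, blobs, classification, circular orders,
isomorphism."""

import pytest
from hypothesis import given, settings, strategies as st

from qdnet.displayed import displayed_trees
from qdnet.generate import (
    build_level1_cycle_bloblet,
    build_level2_bloblet,
    random_network,
)
from qdnet.network import (
    CircularOrder,
    ParseError,
    ValidationError,
    are_isomorphic,
    parse_edgelist,
    parse_enewick,
    parse_network,
    write_edgelist,
    write_enewick,
)


class TestParsing:
    def test_enewick_simple_hybrid(self):
        net = parse_enewick("((a,(b)h#H1),(h#H1,c));")
        assert net.taxa == frozenset("abc")
        hybrids = net.hybrid_nodes()
        assert len(hybrids) == 1
        # the hybrid's child leaf is b
        (h,) = hybrids
        children = [
            net.leaves.get(net.other_end(e, h))
            for e in net.incident(h)
            if net.edge(e)[2] != h
        ]
        assert children == ["b"]

    def test_edgelist_tree(self):
        text = """
        # a quartet tree
        leaf A x
        leaf B y
        leaf C z
        leaf D w
        u -- A
        u -- B
        v -- C
        v -- D
        u -- v
        """
        net = parse_network(text, dialect="edgelist")
        assert net.classify().level == 0
        assert not net.hybrid_nodes()

    def test_hybrid_with_three_incoming_rejected(self):
        text = """
        leaf A x
        leaf B y
        p -> h
        q -> h
        r -> h
        h -- A
        p -- q
        q -- r
        r -- p
        p -- B
        """
        with pytest.raises(ValidationError):
            parse_edgelist(text)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValidationError):
            parse_edgelist("leaf A x\nleaf B x\nA -- B\n")

    def test_malformed_line(self):
        with pytest.raises(ParseError):
            parse_edgelist("A ~~ B\n")

    def test_no_rooted_partner_rejected(self):
        # a 4-cycle carrying all four hybrid edges leaves one of u, v
        # parentless under every root placement
        text = """
        leaf A x
        leaf B y
        leaf C z
        leaf D w
        u -> h1
        v -> h1
        u -> h2
        v -> h2
        u -- A
        v -- B
        h1 -- C
        h2 -- D
        """
        with pytest.raises(ValidationError):
            parse_edgelist(text)

    def test_edgelist_round_trip(self, fx):
        for name, net in fx.items():
            back = parse_edgelist(write_edgelist(net))
            assert are_isomorphic(net, back, mode="labeled"), name

    def test_enewick_round_trip(self, fx):
        for name in ("fig4_col3", "fig8_N4", "fig9_N5", "fig2b"):
            back = parse_enewick(write_enewick(fx[name]))
            assert are_isomorphic(fx[name], back, mode="labeled"), name


class TestClassify:
    def test_binary_tree_report(self):
        net = parse_enewick("((a,b),(c,d));")
        rep = net.classify()
        assert rep.level == 0
        assert rep.galled and rep.outer_labeled_planar
        assert not rep.bloblet
        assert rep.cycle_lengths == frozenset()

    def test_level2_bloblet_report(self, fx):
        rep = fx["fig5_general"].classify()
        assert rep.level == 2
        assert rep.strictly_level == 2
        assert rep.galled and rep.outer_labeled_planar and rep.bloblet

    def test_multiblob_level2_network(self, fx):
        rep = fx["fig2b"].classify()
        assert rep.level == 2 and rep.galled and rep.outer_labeled_planar
        assert not rep.bloblet

    def test_classify_invariant_under_renaming(self, fx):
        net = fx["fig9_N7"]
        assert net.relabeled_copy().classify() == net.classify()


class TestBlobs:
    def test_level1_bloblet_blob_structure(self):
        net = build_level1_cycle_bloblet(list("abcdef"), 2)
        blobs = net.blobs()
        big = [b for b in blobs if len(b.nodes) > 1]
        assert len(big) == 1
        assert len(big[0].nodes) == 6
        assert len(big[0].articulation_nodes) == 6
        assert big[0].level == 1
        assert sum(1 for b in blobs if b.is_trivial) == 6  # the leaves

    def test_tree_every_node_is_own_blob(self):
        net = parse_enewick("((a,b),(c,(d,e)));")
        assert all(len(b.nodes) == 1 for b in net.blobs())

    def test_mu_equals_two_to_r(self, fx):
        for name, net in fx.items():
            r = len(net.hybrid_nodes())
            assert displayed_trees(net).total == 2 ** r, name


class TestTreeOfBlobs:
    def test_tree_maps_to_itself(self):
        net = parse_enewick("((a,b),(c,(d,e)));")
        tob = net.tree_of_blobs()
        assert tob.topology_key() == displayed_trees(net).trees[0].topology_key()

    def test_bloblet_contracts_to_star(self):
        net = build_level1_cycle_bloblet(list("abcde"), 0)
        tob = net.tree_of_blobs()
        assert tob.taxa == frozenset("abcde")
        assert all(s.is_trivial() for s in tob.splits())

    def test_no_degree_two_nodes_and_same_taxa(self, fx):
        for net in fx.values():
            tob = net.tree_of_blobs()
            assert tob.taxa == net.taxa
            assert all(
                tob.degree(v) != 2 for v in tob.nodes if v not in tob.leaves
            )


class TestCircularOrders:
    def test_five_cycle_unique_order(self):
        net = build_level1_cycle_bloblet(list("abcde"), 1)
        assert net.induced_circular_orders() == {CircularOrder("abcde")}

    def test_bloblet_order_is_unique(self, cat6):
        for net in cat6:
            assert len(net.induced_circular_orders()) == 1

    def test_multiblob_orders_contain_planar_order(self, fx):
        orders = fx["fig2b"].induced_circular_orders()
        assert CircularOrder([f"x{i}" for i in range(1, 11)]) in orders

    def test_circular_order_canonicalization(self):
        assert CircularOrder("abcde") == CircularOrder("cdeab")
        assert CircularOrder("abcde") == CircularOrder("edcba")
        assert CircularOrder("abcde") != CircularOrder("abced")


class TestIsomorphism:
    def test_reflexive_with_identity_witness(self, fx):
        net = fx["fig9_N4"]
        ok, mapping = are_isomorphic(net, net, mode="labeled", witness=True)
        assert ok and mapping is not None
        assert all(net.leaves.get(k) == net.leaves.get(v) for k, v in mapping.items())

    def test_label_swap_breaks_labeled_isomorphism(self):
        n1 = build_level1_cycle_bloblet(list("abcde"), 0)
        n2 = build_level1_cycle_bloblet(["b", "a", "c", "d", "e"], 0)
        assert not are_isomorphic(n1, n2, mode="labeled")
        assert are_isomorphic(n1, n2, mode="up_to_relabeling")

    def test_catalogue_members_pairwise_distinct(self, cat6):
        import itertools

        for a, b in itertools.combinations(cat6, 2):
            assert not are_isomorphic(a, b, mode="up_to_relabeling")

    def test_equivalence_relation_spot_checks(self, fx):
        a = fx["fig9_N7"]
        b = a.relabeled_copy("m")
        c = b.relabeled_copy("k")
        assert are_isomorphic(a, a, mode="labeled")
        assert are_isomorphic(a, b, mode="labeled") == are_isomorphic(
            b, a, mode="labeled"
        )
        assert are_isomorphic(a, b, mode="labeled") and are_isomorphic(
            b, c, mode="labeled"
        ) and are_isomorphic(a, c, mode="labeled")

    def test_hybrid_position_matters(self):
        n1 = build_level1_cycle_bloblet(list("abcdef"), 0)
        n2 = build_level1_cycle_bloblet(list("abcdef"), 1)
        assert not are_isomorphic(n1, n2, mode="labeled")


class TestRandomNetworks:
    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6), st.integers(5, 9))
    def test_seeded_generator_is_deterministic_and_valid(self, seed, n):
        n1 = random_network(n, level=2, seed=seed)
        n2 = random_network(n, level=2, seed=seed)
        assert write_edgelist(n1) == write_edgelist(n2)
        rep = n1.classify()
        assert rep.level <= 2 and rep.galled and rep.outer_labeled_planar

    def test_round_trip_random(self):
        for seed in range(5):
            net = random_network(8, level=2, seed=seed)
            back = parse_edgelist(write_edgelist(net))
            assert are_isomorphic(net, back, mode="labeled")
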