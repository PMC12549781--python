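"""Canonical partition, dts detectors, canonical form and distinguishability."""

import itertools

import pytest

from qdnet.canonical import (
    canonical_form,
    canonical_partition,
    detect_dts_4cycles,
    detect_dts_edges,
    detect_split_symmetric_5blob,
    distinguishable,
    is_own_canonical_form,
)
from qdnet.displayed import displayed_splits
from qdnet.generate import (
    build_level1_cycle_bloblet,
    build_level2_bloblet,
    graft_subtree,
)
from qdnet.network import ClassMembershipError, are_isomorphic


def the_blob(net):
    return [b for b in net.blobs() if len(b.nodes) > 1][0]


class TestCanonicalPartition:
    def test_template_inversion(self):
        net = build_level2_bloblet(["p"], ["q"], ["r"], ["s"], "c1", "c2")
        cp = canonical_partition(net)
        blocks = {frozenset(b) for b in
                  (cp.A1, cp.A2, cp.B1, cp.B2, cp.C1, cp.C2)}
        assert blocks == {frozenset(x) for x in
                          ({"p"}, {"q"}, {"r"}, {"s"}, {"c1"}, {"c2"})}
        # A-blocks of both galls lie on the same side of the shared edge
        assert ({cp.A1, cp.A2} == {frozenset("p"), frozenset("q")}
                or {cp.A1, cp.A2} == {frozenset("r"), frozenset("s")})

    def test_quarnet_partition(self, fx):
        cp = canonical_partition(fx["fig4_col3"])
        assert {cp.C1, cp.C2} == {frozenset("y"), frozenset("w")}
        assert {cp.A1 | cp.B1, cp.A2 | cp.B2} == {frozenset("x"), frozenset("z")}

    def test_level1_rejected(self):
        with pytest.raises(ClassMembershipError):
            canonical_partition(build_level1_cycle_bloblet(list("abcde"), 0))

    def test_equivalence_up_to_interchange(self):
        net = build_level2_bloblet(["p"], ["q"], ["r"], ["s"], "c1", "c2")
        cp = canonical_partition(net)
        swapped = type(cp)(cp.B1, cp.B2, cp.A1, cp.A2, cp.C1, cp.C2)
        assert cp.equivalent(swapped)
        rotated = type(cp)(cp.A2, cp.A1, cp.B2, cp.B1, cp.C2, cp.C1)
        assert cp.equivalent(rotated)
        assert not cp.equivalent(type(cp)(cp.A2, cp.A1, cp.B1, cp.B2,
                                          cp.C1, cp.C2))


class TestDetectors:
    def test_split_symmetric_detector(self, fx):
        assert detect_split_symmetric_5blob(fx["fig8_N4"], the_blob(fx["fig8_N4"]))
        assert not detect_split_symmetric_5blob(fx["fig8_N2"], the_blob(fx["fig8_N2"]))
        five = build_level1_cycle_bloblet(list("abcde"), 0)
        assert not detect_split_symmetric_5blob(five, the_blob(five))

    def test_split_symmetry_of_displayed_splits(self, fx):
        # the defining property: the displayed split set is invariant under
        # cyclically permuting the leaves along the circular order
        net = fx["fig8_N4"]
        (order,) = net.induced_circular_orders()
        seq = list(order)
        rot = {seq[i]: seq[(i + 1) % 5] for i in range(5)}
        def rotate(split):
            a, b = split.blocks
            from qdnet.splits import Split
            return Split({rot[x] for x in a}, {rot[x] for x in b})
        s = displayed_splits(net)
        assert {rotate(sp) for sp in s} == s

    def test_dts_4cycle_detector(self, fx):
        assert len(detect_dts_4cycles(fx["fig8_N2"], the_blob(fx["fig8_N2"]))) == 1
        assert len(detect_dts_4cycles(fx["fig9_N3"], the_blob(fx["fig9_N3"]))) == 1
        six = fx["fig9_N1"]
        assert detect_dts_4cycles(six, the_blob(six)) == []
        assert detect_dts_4cycles(fx["fig9_N4"], the_blob(fx["fig9_N4"])) == []

    def test_dts_4cycle_labeling(self, fx):
        net = fx["fig9_N2"]
        ((p_u, u, p_other, w),) = detect_dts_4cycles(net, the_blob(net))
        blob = the_blob(net)
        assert u in blob.hybrids
        assert p_u in blob.articulation_nodes
        v = next(h for h in blob.hybrids if h != u)
        from qdnet.canonical import _hybrid_parents

        assert p_other in _hybrid_parents(net, v) or w in _hybrid_parents(net, v)

    def test_dts_edge_detector(self, fx):
        assert [k for _, k in detect_dts_edges(fx["fig9_N7"], the_blob(fx["fig9_N7"]))] == [1]
        assert [k for _, k in detect_dts_edges(fx["fig9_N8"], the_blob(fx["fig9_N8"]))] == [1]
        assert [k for _, k in detect_dts_edges(fx["fig9_N9"], the_blob(fx["fig9_N9"]))] == [2]
        assert detect_dts_edges(fx["fig9_N5"], the_blob(fx["fig9_N5"])) == []
        assert detect_dts_edges(fx["fig9_N6"], the_blob(fx["fig9_N6"])) == []


class TestCanonicalForm:
    def test_dts_4cycle_networks_reduce_to_cycle(self, fx):
        for name in ("fig8_N2", "fig8_N3"):
            assert are_isomorphic(canonical_form(fx[name]), fx["fig8_N1"],
                                  mode="labeled"), name
        for name in ("fig9_N2", "fig9_N3"):
            assert are_isomorphic(canonical_form(fx[name]), fx["fig9_N1"],
                                  mode="labeled"), name

    def test_split_symmetric_becomes_undirected_5cycle(self, fx):
        g = canonical_form(fx["fig8_N4"])
        assert not g.hybrid_edges()
        assert len([v for v in g.nodes if v not in g.leaves]) == 5

    def test_class_e_shares_nonbinary_form(self, fx):
        g7 = canonical_form(fx["fig9_N7"])
        g9 = canonical_form(fx["fig9_N9"])
        assert are_isomorphic(g7, g9, mode="labeled")
        assert any(g9.degree(v) > 3 for v in g9.nodes)
        assert g9.hybrid_edges()  # the larger gall keeps its direction

    def test_cycle_is_own_canonical_form(self, fx):
        assert is_own_canonical_form(fx["fig9_N1"])
        assert is_own_canonical_form(fx["fig9_N5"])
        assert not is_own_canonical_form(fx["fig8_N3"])

    def test_hybrids_separated_by_one_leaf_not_canonical(self):
        # hybrid-to-hybrid edge distance 3 is exactly the dts-edge situation
        net = build_level2_bloblet(["p", "q"], ["r"], ["s"], [], "c1", "c2")
        assert not is_own_canonical_form(net)

    def test_blob_order_invariance(self, fx):
        net = fx["fig2b"]
        forms = [canonical_form(net, blob_order_seed=s) for s in range(4)]
        assert all(are_isomorphic(forms[0], f, mode="labeled") for f in forms)

    def test_multiblob_canonical_form(self, fx):
        # grafting subtrees on a reducible bloblet: the blob still reduces
        net = build_level2_bloblet(["P", "c", "b"], ["d"], [], [], "a", "e")
        graft_subtree(net, "P", ("p1", "p2"))
        net.validate()
        g = canonical_form(net)
        ref = build_level1_cycle_bloblet(["a", "b", "c", "P", "d", "e"], 0)
        # compare displayed splits instead of direct isomorphism: the
        # grafted cherry hangs where the contracted leaves sat
        from qdnet.network import SemiDirectedNetwork

        assert {s for s in displayed_splits(SemiDirectedNetwork.adopt(g))
                if not s.is_trivial()} >= {
            s for s in displayed_splits(net) if not s.is_trivial()
        }

    def test_preserves_displayed_splits(self, fx):
        # operations (v)/(vi) leave the displayed split set unchanged
        from qdnet.network import SemiDirectedNetwork

        for name in ("fig8_N2", "fig9_N2", "fig9_N3"):
            g = canonical_form(fx[name])
            net2 = SemiDirectedNetwork.adopt(g)
            assert displayed_splits(net2) == displayed_splits(fx[name]), name


class TestDistinguishable:
    def test_same_canonical_class_indistinguishable(self, fx):
        for by in ("canonical", "quartets", "splits", "nanuq"):
            assert not distinguishable(fx["fig9_N7"], fx["fig9_N8"], by=by)

    def test_different_classes_distinguishable(self, fx):
        for by in ("canonical", "quartets", "splits", "nanuq"):
            assert distinguishable(fx["fig9_N1"], fx["fig9_N4"], by=by)

    def test_self_comparison(self, fx):
        net = fx["fig9_N6"]
        assert not distinguishable(net, net, by="canonical")

    def test_leaf_set_mismatch(self, fx):
        with pytest.raises(ValueError):
            distinguishable(fx["fig9_N1"], fx["fig8_N1"])

    def test_nanuq_requires_bloblets(self, fx):
        with pytest.raises(ClassMembershipError):
            distinguishable(fx["fig2b"], fx["fig2b"], by="nanuq")

    def test_same_canonical_form_iff_same_displayed_splits(self, cat6):
        # same canonical form <=> same displayed splits, exhaustively
        forms = [canonical_form(n) for n in cat6]
        splits = [displayed_splits(n) for n in cat6]
        for i, j in itertools.combinations(range(len(cat6)), 2):
            same_form = are_isomorphic(forms[i], forms[j], mode="labeled")
            assert same_form == (splits[i] == splits[j]), (i, j)
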