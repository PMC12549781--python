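"""Displayed trees, quarnets, induced subnetworks and split sets."""

import itertools
from fractions import Fraction

import networkx as nx
import pytest

from conftest import tree_from_newick
from qdnet.canonical import _contract_cycle
from qdnet.displayed import (
    displayed_quartets,
    displayed_splits,
    displayed_trees,
    induced_splits,
    induced_subnetwork,
    quarnet,
    tree_splits,
)
from qdnet.generate import (
    build_level1_cycle_bloblet,
    build_level2_bloblet,
    random_network,
)
from qdnet.metrics import rho_quartet_tree
from qdnet.network import are_isomorphic
from qdnet.splits import Split


def brute_force_updown_union(net, x1, x2):
    """Oracle: enumerate all simple edge paths and filter on the up-down
    pattern (all against-direction hybrid edges before all with-direction)."""
    g = net.to_multigraph()
    keep = set()
    for path in nx.all_simple_edge_paths(g, x1, x2):
        descending = False
        ok = True
        for u, v, key in path:
            _, _, head = net.edge(key)
            if head is None:
                continue
            if head == u:  # traversed against the direction: an "up" move
                if descending:
                    ok = False
                    break
            else:
                descending = True
        if ok:
            keep.update(k for _, _, k in path)
    return keep


class TestInducedSubnetwork:
    def test_full_taxon_set_is_identity(self, fx):
        for name in ("fig9_N5", "fig5_general", "fig2b"):
            net = fx[name]
            sub = induced_subnetwork(net, net.taxa)
            assert are_isomorphic(sub, net, mode="labeled"), name

    def test_matches_brute_force_path_union(self, fx):
        for name in ("fig9_N7", "fig8_N4", "fig2b"):
            net = fx[name]
            taxa = sorted(net.taxa)
            for a, b in itertools.combinations(taxa[:4], 2):
                from qdnet.displayed import _up_down_edge_union

                va, vb = net.leaf_of(a), net.leaf_of(b)
                assert _up_down_edge_union(net, va, vb) == brute_force_updown_union(
                    net, va, vb
                ), (name, a, b)

    def test_six_cycle_quarnet_missing_hybrid_becomes_tree(self):
        # leaves chosen so the up-down paths avoid one hybrid edge entirely
        net = build_level1_cycle_bloblet(list("abcdef"), 0)
        q = quarnet(net, {"b", "c", "d", "e"})
        assert not q.hybrid_nodes()
        assert len(displayed_trees(q)) == 1

    def test_requires_at_least_two_taxa(self, fx):
        with pytest.raises(ValueError):
            induced_subnetwork(fx["fig9_N1"], {"a"})

    def test_subnetwork_functoriality_for_quartets(self, fx):
        net = fx["fig2b"]
        sub = induced_subnetwork(net, {"x1", "x2", "x5", "x6", "x7"})
        q_net = displayed_quartets(net)
        q_sub = displayed_quartets(sub)
        for four in q_sub:
            assert q_sub[four] == q_net[four]


class TestQuarnets:
    def test_tree_input_gives_quartet_tree(self):
        net = tree_from_newick("((a,b),((c,d),e));")
        from qdnet.network import SemiDirectedNetwork

        net = SemiDirectedNetwork.adopt(net)
        q = quarnet(net, {"a", "b", "c", "e"})
        assert not q.hybrid_nodes()
        (t,) = displayed_trees(q).trees
        assert t.quartet_topology(frozenset("abce")) == Split("ab", "ce")

    def test_strictly_level2_quarnet_from_template(self, fx):
        q = quarnet(fx["fig5_general"], {"c1", "c2", "a1", "b2"})
        rep = q.classify()
        assert rep.level == 2

    def test_quarnet_on_one_cycle_is_level_one_or_tree(self, fx):
        # all four taxa on cycle 1 of the general template
        q = quarnet(fx["fig5_general"], {"c1", "a1", "b1", "a2"})
        assert q.classify().level <= 1


class TestDisplayedTrees:
    def test_tree_displays_itself_once(self):
        net = tree_from_newick("((a,b),((c,d),e));")
        from qdnet.network import SemiDirectedNetwork

        dt = displayed_trees(SemiDirectedNetwork.adopt(net))
        assert dt.total == 1 and len(dt) == 1

    def test_strictly_level2_total_is_four(self, fx):
        assert displayed_trees(fx["fig5_general"]).total == 4

    def test_fig4_col3_multiplicities(self, fx):
        dt = displayed_trees(fx["fig4_col3"])
        by_top = {
            t.quartet_topology(frozenset("xyzw")): m for t, m in dt.items()
        }
        assert by_top == {Split("xy", "zw"): 3, Split("xz", "yw"): 1}

    def test_level1_four_cycle_two_topologies(self, fx):
        dt = displayed_trees(fx["fig4_col2"])
        assert dt.total == 2 and len(dt) == 2
        assert all(m == 1 for _, m in dt.items())

    def test_quarnet_rho_equals_restricted_tree_average(self):
        # rho~ on the quarnet equals the mu-weighted average over the
        # network's displayed trees restricted to the four taxa
        for seed in range(6):
            net = random_network(7, level=2, seed=seed)
            trees = displayed_trees(net)
            taxa = sorted(net.taxa)
            for four in itertools.combinations(taxa, 4):
                q = quarnet(net, four)
                qt = displayed_trees(q)
                from qdnet.metrics import rho_tilde

                for x, y in itertools.combinations(four, 2):
                    direct = rho_tilde(q, x, y)
                    acc = Fraction(0)
                    for t, m in trees.items():
                        acc += m * rho_quartet_tree(
                            t.restrict(four), x, y
                        )
                    assert direct == acc / trees.total

    def test_contracting_3cycle_gall_preserves_topologies(self):
        # a 3-cycle displays exactly the same trees as a single node
        from qdnet.canonical import _blob_cycles

        net2 = build_level2_bloblet([], ["p", "q"], [], [], "c1", "c2")
        before = displayed_trees(net2).topology_keys()
        g = net2.copy()
        blob = [b for b in g.blobs() if len(b.nodes) > 1][0]
        (cyc,) = _blob_cycles(g, blob, 3)
        _contract_cycle(g, set(cyc))
        g.refresh_hybrid_status()
        after = displayed_trees(g).topology_keys()
        assert before == after


class TestSplits:
    def test_quartet_tree_splits(self):
        t = tree_from_newick("((x,y),(z,w));")
        s = tree_splits(t)
        assert len(s) == 5
        assert Split("xy", "zw") in s
        assert sum(1 for sp in s if sp.is_trivial()) == 4

    def test_caterpillar_splits(self):
        t = tree_from_newick("((((a,b),c),d),(e,f));")
        s = tree_splits(t)
        assert len(s) == len(t.edge_ids) == 9
        assert Split("ab", "cdef") in s

    def test_star_tree_only_trivial_splits(self):
        net = build_level1_cycle_bloblet(list("abcde"), 0)
        star = net.tree_of_blobs()
        assert all(sp.is_trivial() for sp in tree_splits(star))

    def test_induced_subset_of_displayed(self, fx):
        for name in ("fig2b", "fig9_N5"):
            net = fx[name]
            assert induced_splits(net) <= displayed_splits(net)

    def test_same_canonical_class_same_displayed_splits(self, fx):
        assert displayed_splits(fx["fig9_N7"]) == displayed_splits(fx["fig9_N8"])
        assert displayed_splits(fx["fig9_N1"]) == displayed_splits(fx["fig9_N2"])

    def test_displayed_quartets_match_quarnet_route(self, fx):
        net = fx["fig9_N6"]
        via_trees = displayed_quartets(net)
        for four, tops in via_trees.items():
            q = quarnet(net, four)
            got = set()
            for t in displayed_trees(q).trees:
                got.add(t.quartet_topology(four))
            assert got == set(tops)
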