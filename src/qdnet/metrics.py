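"""Inter-taxon quartet distances for trees and semi-directed networks.

For a quartet tree the cherry indicator ``rho_xy`` is 0 when x, y form a
cherry and 1 otherwise.  Summing it over all quartets containing a pair
gives Rhodes' quartet metric of a tree

    d_T(x, y) = sum_{ {z,w} subset X\\{x,y} } 2 rho_xy(T|xyzw) + 2n - 4,

which coincides with the path distance under the *quartet metrization*
(internal edge with blocks X1..X4: w = |X1||X2| + |X3||X4|; pendant edge
with tripartition ({x}, X1, X2): w = |X1||X2|).

Two network generalizations replace ``rho`` on each quarnet N|xyzw by an
average over the quartet trees the quarnet displays: weighted by
multiplicity (``rho_tilde``, giving the displayed quartet metric) or
unweighted over distinct topologies (``rho_bar``, giving the NANUQ metric).
Everything is computed in exact rational arithmetic.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

from .network import ClassMembershipError, MixedGraph, SemiDirectedNetwork
from .displayed import PhyloTree, displayed_trees, quarnet
from .splits import DistanceTable, Split

__all__ = [
    "rho_quartet_tree",
    "rho_tilde",
    "rho_bar",
    "quartet_metric",
    "quartet_metrization",
    "tree_path_distances",
    "displayed_quartet_metric",
    "nanuq_metric",
    "epsilon_terms",
]


# ---------------------------------------------------------------------------
# pair scores on quartet trees and quarnets
# ---------------------------------------------------------------------------


def rho_quartet_tree(tree: PhyloTree, x: str, y: str) -> Fraction:
    """0 iff x and y form a cherry of the 4-leaf tree, else 1."""
    taxa = tree.taxa
    if len(taxa) != 4:
        raise ValueError("rho is defined on quartet trees")
    if x not in taxa or y not in taxa:
        raise ValueError("taxa not in the tree")
    s = tree.quartet_topology(frozenset(taxa))
    return Fraction(1) if s.separates(x, y) else Fraction(0)


def _quarnet_topologies(q: SemiDirectedNetwork):
    """Displayed quartet topologies of a quarnet with multiplicities.

    Returns ``(list of (Split, multiplicity), mu)``.
    """
    taxa = frozenset(q.taxa)
    if len(taxa) != 4:
        raise ValueError("not a quarnet")
    trees = displayed_trees(q)
    tally: dict[Split, int] = {}
    for t, mult in trees.items():
        s = t.quartet_topology(taxa)
        tally[s] = tally.get(s, 0) + mult
    return list(tally.items()), trees.total


def rho_tilde(q: SemiDirectedNetwork, x: str, y: str) -> Fraction:
    """Multiplicity-weighted average cherry indicator over the quartet trees
    displayed by the quarnet."""
    tops, mu = _quarnet_topologies(q)
    acc = sum(m for s, m in tops if s.separates(x, y))
    return Fraction(acc, mu)


def rho_bar(q: SemiDirectedNetwork, x: str, y: str) -> Fraction:
    """Unweighted average over the *distinct* displayed quartet topologies."""
    tops, _ = _quarnet_topologies(q)
    acc = sum(1 for s, _ in tops if s.separates(x, y))
    return Fraction(acc, len(tops))


# ---------------------------------------------------------------------------
# quartet metric of a tree
# ---------------------------------------------------------------------------


def _components_off_path(tree: PhyloTree, x: str, y: str) -> list[int]:
    """Sizes of the leaf sets hanging off the internal nodes of the x-y path.

    A pair {z, w} forms the quartet xy|zw exactly when z and w fall in the
    same hanging component (the z-w path then avoids the x-y path).
    """
    # find the unique path between the leaf nodes of x and y
    vx, vy = tree.leaf_of(x), tree.leaf_of(y)
    prev: dict[str, tuple[str, int]] = {vx: (vx, -1)}
    stack = [vx]
    while stack:
        v = stack.pop()
        if v == vy:
            break
        for eid in tree.incident(v):
            w = tree.other_end(eid, v)
            if w not in prev:
                prev[w] = (v, eid)
                stack.append(w)
    path_nodes = []
    v = vy
    while v != vx:
        path_nodes.append(v)
        v = prev[v][0]
    path_nodes.append(vx)
    on_path = set(path_nodes)
    sizes = []
    for v in path_nodes:
        if v in (vx, vy):
            continue
        for eid in tree.incident(v):
            w = tree.other_end(eid, v)
            if w in on_path:
                continue
            # count leaves in the component behind w
            seen = {v, w}
            stack2 = [w]
            cnt = 0
            while stack2:
                u = stack2.pop()
                if u in tree.leaves:
                    cnt += 1
                for e2 in tree.incident(u):
                    t2 = tree.other_end(e2, u)
                    if t2 not in seen:
                        seen.add(t2)
                        stack2.append(t2)
            sizes.append(cnt)
    return sizes


def quartet_metric(tree: PhyloTree) -> DistanceTable:
    """Rhodes' quartet metric d_T, computed from the quartet sum."""
    taxa = sorted(tree.taxa)
    n = len(taxa)
    if n < 4:
        raise ValueError("quartet metric needs at least four leaves")
    table = DistanceTable(taxa)
    total_pairs = (n - 2) * (n - 3) // 2
    for x, y in table.pairs():
        comp = _components_off_path(tree, x, y)
        cherries = sum(c * (c - 1) // 2 for c in comp)
        rho_sum = total_pairs - cherries  # quartets where {x,y} is not a cherry
        table.set(x, y, 2 * rho_sum + 2 * n - 4)
    return table


def quartet_metrization(tree: PhyloTree) -> dict[int, Fraction]:
    """Edge weights: block-size products (internal: |X1||X2| + |X3||X4|;
    pendant: |X1||X2|)."""
    taxa = tree.taxa
    n = len(taxa)
    if n < 4:
        raise ValueError("quartet metrization needs at least four leaves")
    weights: dict[int, Fraction] = {}
    for eid in tree.edge_ids:
        u, v, _ = tree.edge(eid)
        if u in tree.leaves or v in tree.leaves:
            inner = v if u in tree.leaves else u
            # tripartition ({x}, X1, X2) given by the two other edges at inner
            blocks = []
            for e2 in tree.incident(inner):
                if e2 == eid:
                    continue
                blocks.append(tree._side_leaves(e2, tree.other_end(e2, inner)))
            if len(blocks) != 2:
                raise ValueError("metrization requires a binary tree")
            weights[eid] = Fraction(len(blocks[0]) * len(blocks[1]))
        else:
            bu = [
                tree._side_leaves(e2, tree.other_end(e2, u))
                for e2 in tree.incident(u)
                if e2 != eid
            ]
            bv = [
                tree._side_leaves(e2, tree.other_end(e2, v))
                for e2 in tree.incident(v)
                if e2 != eid
            ]
            if len(bu) != 2 or len(bv) != 2:
                raise ValueError("metrization requires a binary tree")
            weights[eid] = Fraction(
                len(bu[0]) * len(bu[1]) + len(bv[0]) * len(bv[1])
            )
    return weights


def tree_path_distances(tree: PhyloTree, weights: dict[int, Fraction]) -> DistanceTable:
    """Leaf-to-leaf path distances under an edge weighting."""
    taxa = sorted(tree.taxa)
    table = DistanceTable(taxa)
    for x, y in table.pairs():
        vx, vy = tree.leaf_of(x), tree.leaf_of(y)
        prev: dict[str, tuple[str, int]] = {vx: (vx, -1)}
        stack = [vx]
        while stack:
            v = stack.pop()
            for eid in tree.incident(v):
                w = tree.other_end(eid, v)
                if w not in prev:
                    prev[w] = (v, eid)
                    stack.append(w)
        dist = Fraction(0)
        v = vy
        while v != vx:
            v, eid = prev[v]
            dist += weights[eid]
        table.set(x, y, dist)
    return table


# ---------------------------------------------------------------------------
# network metrics
# ---------------------------------------------------------------------------


def _pairwise_quarnet_scores(net: SemiDirectedNetwork, kind: str) -> DistanceTable:
    taxa = sorted(net.taxa)
    n = len(taxa)
    if n < 4:
        raise ValueError("need at least four leaves")
    sums: dict[frozenset[str], Fraction] = {
        frozenset(p): Fraction(0) for p in itertools.combinations(taxa, 2)
    }
    for four in itertools.combinations(taxa, 4):
        q = quarnet(net, four)
        tops, mu = _quarnet_topologies(q)
        k = len(tops)
        for x, y in itertools.combinations(four, 2):
            if kind == "tilde":
                val = Fraction(sum(m for s, m in tops if s.separates(x, y)), mu)
            else:
                val = Fraction(sum(1 for s, _ in tops if s.separates(x, y)), k)
            sums[frozenset((x, y))] += val
    table = DistanceTable(taxa)
    for x, y in table.pairs():
        table.set(x, y, 2 * sums[frozenset((x, y))] + 2 * n - 4)
    return table


def displayed_quartet_metric(
    net: SemiDirectedNetwork, check: bool = True
) -> DistanceTable:
    """The displayed quartet metric computed from rho_tilde on all quarnets.

    With ``check=True`` the result is also recomputed as the
    multiplicity-weighted average of the quartet metrics of the displayed
    trees (the two routes are provably identical) and the equality asserted.
    """
    table = _pairwise_quarnet_scores(net, "tilde")
    if check:
        via_trees = _weighted_tree_metric(net)
        if table != via_trees:
            raise AssertionError(
                "quarnet route and displayed-tree route disagree"
            )
    return table


def _weighted_tree_metric(net: SemiDirectedNetwork) -> DistanceTable:
    trees = displayed_trees(net)
    taxa = sorted(net.taxa)
    acc = {frozenset(p): Fraction(0) for p in itertools.combinations(taxa, 2)}
    for t, mult in trees.items():
        dt = quartet_metric(t)
        for x, y in dt.pairs():
            acc[frozenset((x, y))] += mult * dt.get(x, y)
    table = DistanceTable(taxa)
    for x, y in table.pairs():
        table.set(x, y, acc[frozenset((x, y))] / trees.total)
    return table


def nanuq_metric(net: SemiDirectedNetwork) -> DistanceTable:
    """The NANUQ metric: rho_bar (multiplicities ignored) on all quarnets."""
    return _pairwise_quarnet_scores(net, "bar")


# ---------------------------------------------------------------------------
# error term for strictly level-2 bloblets
# ---------------------------------------------------------------------------


def epsilon_terms(net: SemiDirectedNetwork, check: bool = True) -> DistanceTable:
    """The error term eps = d_N - d~_N for a strictly level-2 bloblet.

    Computed directly as ``2 sum_{z,w} (rho_bar - rho_tilde)`` per pair and,
    with ``check=True``, also by the canonical-partition closed form; the
    two must agree exactly.  eps(x, x) = 0.
    """
    from .canonical import canonical_partition

    direct = nanuq_metric(net) - displayed_quartet_metric(net, check=False)
    if check:
        cp = canonical_partition(net)
        closed = closed_form_epsilon(net, cp)
        if direct != closed:
            raise AssertionError("direct and closed-form error terms disagree")
    return direct


def closed_form_epsilon(net: SemiDirectedNetwork, partition) -> DistanceTable:
    """Closed form of the error term from the canonical partition
    {A1, A2, B1, B2, C1, C2} of a strictly level-2 bloblet."""
    a = [partition.A1, partition.A2]
    b = [partition.B1, partition.B2]
    c = [partition.C1, partition.C2]
    taxa = sorted(net.taxa)
    table = DistanceTable(taxa)

    def block(x):
        for i in range(2):
            if x in a[i]:
                return ("A", i)
            if x in b[i]:
                return ("B", i)
            if x in c[i]:
                return ("C", i)
        raise ClassMembershipError(f"taxon {x} missing from the partition")

    sizes = {("A", 0): len(a[0]), ("A", 1): len(a[1]),
             ("B", 0): len(b[0]), ("B", 1): len(b[1])}
    for x, y in table.pairs():
        kx, i = block(x)
        ky, j = block(y)
        val = Fraction(0)
        if kx == "C" and ky == "C":
            val = -(sizes[("A", 0)] * sizes[("A", 1)]
                    + sizes[("B", 0)] * sizes[("B", 1)])
        elif "C" in (kx, ky):
            if ky == "C":  # put the hybrid first
                kx, ky, i, j = ky, kx, j, i
            # now kx == "C", hybrid on cycle i+1; other leaf in block (ky, j)
            if i == j:
                val = sizes[("A", 1 - i)] + sizes[("B", 1 - i)]
            elif ky == "A":
                val = -sizes[("B", i)]
            else:
                val = -sizes[("A", i)]
        elif kx == ky and i != j:
            val = -1
        table.set(x, y, Fraction(val, 2))
    return table
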