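"""Displayed trees, induced subnetworks, quarnets and displayed quartets.

A tree *T* is displayed by a semi-directed network *N* when it can be
obtained by deleting exactly one hybrid edge per hybrid node, pruning
unlabeled leaves and suppressing degree-2 nodes.  With *r* hybrid nodes
there are ``2^r`` deletion choices; the multiplicity ``mu(T, N)`` counts the
choices yielding *T* and ``mu(N) = sum mu(T, N) = 2^r``.

Induced subnetworks follow the up-down-path semantics: ``N|_Y`` is the
union of all paths between leaves of *Y* whose first stretch of edges is
directed back toward the start leaf and whose remainder is directed toward
the end leaf (undirected edges count as bidirected), followed by exhaustive
degree-2 suppression.  ``N|_Y`` on a 4-set is a *quarnet*.
"""

from __future__ import annotations

import itertools

from .network import (
    MixedGraph,
    SemiDirectedNetwork,
    ValidationError,
)
from .splits import Split

__all__ = [
    "PhyloTree",
    "DisplayedTreeMultiset",
    "displayed_trees",
    "induced_subnetwork",
    "quarnet",
    "displayed_quartets",
    "tree_splits",
    "displayed_splits",
    "induced_splits",
]


class PhyloTree(MixedGraph):
    """Unrooted leaf-labeled tree (binary unless produced by contraction)."""

    def validate_tree(self) -> None:
        if not self.is_connected():
            raise ValidationError("tree is not connected")
        if len(self._edges) != len(self._adj) - 1:
            raise ValidationError("graph has cycles")
        if self.hybrid_edges():
            raise ValidationError("tree has hybrid edges")

    # -- splits and topology ----------------------------------------------

    def edge_split(self, eid: int) -> Split:
        u, v, _ = self.edge(eid)
        side = self._side_leaves(eid, u)
        other = self.taxa - side
        return Split(side, other)

    def _side_leaves(self, eid: int, start: str) -> frozenset[str]:
        """Leaf labels reachable from ``start`` without crossing ``eid``."""
        seen = {start}
        stack = [start]
        labels = set()
        while stack:
            v = stack.pop()
            if v in self.leaves:
                labels.add(self.leaves[v])
            for e2 in self.incident(v):
                if e2 == eid:
                    continue
                w = self.other_end(e2, v)
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return frozenset(labels)

    def splits(self) -> set[Split]:
        """One split per edge, trivial splits included."""
        return {self.edge_split(eid) for eid in self.edge_ids}

    def topology_key(self) -> frozenset[Split]:
        """Canonical key: the split set determines the unrooted topology."""
        return frozenset(self.splits())

    # -- quartets ----------------------------------------------------------

    def quartet_topology(self, four: frozenset[str]) -> Split:
        """The 2|2 split of ``four`` induced by the tree (binary trees)."""
        if len(four) != 4:
            raise ValueError("need exactly four taxa")
        for s in self.splits():
            r = s.restrict(four)
            if r is not None and not r.is_trivial():
                return r
        raise ValidationError("no resolving split: tree is not binary on the 4-set")

    def restrict(self, taxa) -> "PhyloTree":
        """The induced subtree on a label subset, degree-2 suppressed."""
        keep_labels = set(taxa)
        t = self.copy()
        t.leaves = {v: lab for v, lab in t.leaves.items() if lab in keep_labels}
        t.prune_dead_leaves()
        t.suppress_degree2()
        return t

    # -- serialization ------------------------------------------------------

    def newick(self) -> str:
        nodes = sorted(self.nodes)
        if len(nodes) == 1:
            return self.leaves[nodes[0]] + ";"
        start = next(v for v in nodes if v not in self.leaves) if len(
            self.leaves
        ) < len(nodes) else nodes[0]

        def emit(v: str, came: int | None) -> str:
            kids = [
                (self.other_end(e, v), e) for e in self.incident(v) if e != came
            ]
            if v in self.leaves and not kids:
                return self.leaves[v]
            parts = [emit(w, e) for w, e in kids]
            if v in self.leaves:
                parts.append(self.leaves[v])
            return "(" + ",".join(parts) + ")"

        return emit(start, None) + ";"


class DisplayedTreeMultiset:
    """The displayed trees of a network with multiplicities."""

    def __init__(self) -> None:
        self._by_key: dict[frozenset[Split], tuple[PhyloTree, int]] = {}

    def add(self, tree: PhyloTree, count: int = 1) -> None:
        key = tree.topology_key()
        if key in self._by_key:
            t, c = self._by_key[key]
            self._by_key[key] = (t, c + count)
        else:
            self._by_key[key] = (tree, count)

    def items(self):
        """Iterate over ``(tree, multiplicity)``."""
        return list(self._by_key.values())

    @property
    def trees(self) -> list[PhyloTree]:
        return [t for t, _ in self._by_key.values()]

    def multiplicity(self, tree: PhyloTree) -> int:
        entry = self._by_key.get(tree.topology_key())
        return entry[1] if entry else 0

    @property
    def total(self) -> int:
        """mu(N), the number of hybrid-edge deletion choices."""
        return sum(c for _, c in self._by_key.values())

    def __len__(self) -> int:
        return len(self._by_key)

    def topology_keys(self) -> set[frozenset[Split]]:
        return set(self._by_key)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<DisplayedTreeMultiset {len(self)} topologies, mu={self.total}>"


def displayed_trees(net: MixedGraph) -> DisplayedTreeMultiset:
    """Enumerate all ``2^r`` hybrid-edge deletion choices."""
    hybrids = net.hybrid_nodes()
    choices = [net.in_edges(h) for h in hybrids]
    out = DisplayedTreeMultiset()
    for combo in itertools.product(*choices):
        g = net.copy()
        for eid in combo:
            g.remove_edge(eid)
        g.prune_dead_leaves()
        g.refresh_hybrid_status()
        if g.hybrid_edges():
            raise ValidationError("hybrid edges remain after deletion")
        g.suppress_degree2()
        if set(g.leaves.values()) != set(net.leaves.values()):
            raise ValidationError(
                "hybrid-edge deletion disconnected a labeled leaf"
            )
        t = PhyloTree.adopt(g)
        t.validate_tree()
        out.add(t)
    return out


# ---------------------------------------------------------------------------
# induced subnetworks
# ---------------------------------------------------------------------------


def _up_down_edge_union(net: MixedGraph, x1: str, x2: str) -> set[int]:
    """Edge ids lying on some up-down simple path from leaf x1 to leaf x2.

    A path is up-down if all hybrid edges traversed against their direction
    (toward x1) precede all hybrid edges traversed with it (toward x2); a
    DFS with an up/down phase flag enumerates exactly these paths.
    """
    result: set[int] = set()
    path: list[int] = []
    visited = {x1}

    def dfs(v: str, down: bool) -> None:
        if v == x2:
            result.update(path)
            return
        for eid in net.incident(v):
            u, w, head = net.edge(eid)
            other = w if v == u else u
            if other in visited:
                continue
            if head is None:
                nxt = down
            elif head == v:
                if down:
                    continue  # upward edge after the descent began
                nxt = False
            else:
                nxt = True
            visited.add(other)
            path.append(eid)
            dfs(other, nxt)
            path.pop()
            visited.discard(other)

    dfs(x1, False)
    return result


def induced_subnetwork(net: SemiDirectedNetwork, taxa) -> SemiDirectedNetwork:
    """The subnetwork ``N|_Y``: union of all up-down paths between leaves of
    Y, with hybrid status recomputed and degree-2 nodes suppressed."""
    labels = set(taxa)
    if len(labels) < 2:
        raise ValueError("need at least two taxa")
    if not labels <= set(net.taxa):
        raise ValueError("taxa not in the network")
    leaf_nodes = {lab: net.leaf_of(lab) for lab in labels}
    keep: set[int] = set()
    for a, b in itertools.combinations(sorted(labels), 2):
        keep |= _up_down_edge_union(net, leaf_nodes[a], leaf_nodes[b])
    sub = SemiDirectedNetwork()
    for eid in keep:
        u, v, head = net.edge(eid)
        sub.add_edge(u, v, head)
    for lab, v in leaf_nodes.items():
        sub.add_leaf(v, lab)
    sub.refresh_hybrid_status()
    sub.prune_dead_leaves()
    sub.suppress_degree2()
    return sub


def quarnet(net: SemiDirectedNetwork, four) -> SemiDirectedNetwork:
    four = set(four)
    if len(four) != 4:
        raise ValueError("a quarnet needs exactly four taxa")
    return induced_subnetwork(net, four)


def displayed_quartets(net: SemiDirectedNetwork) -> dict[frozenset[str], frozenset[Split]]:
    """Q(N): for each 4-subset of X, the quartet topologies displayed by its
    quarnet (equivalently, by the displayed trees of N)."""
    taxa = sorted(net.taxa)
    if len(taxa) < 4:
        raise ValueError("need at least four taxa")
    trees = displayed_trees(net)
    out: dict[frozenset[str], frozenset[Split]] = {}
    splitsets = [t.splits() for t in trees.trees]
    for four in itertools.combinations(taxa, 4):
        fs = frozenset(four)
        tops = set()
        for ss in splitsets:
            for s in ss:
                r = s.restrict(fs)
                if r is not None and not r.is_trivial():
                    tops.add(r)
                    break
        out[fs] = frozenset(tops)
    return out


# ---------------------------------------------------------------------------
# splits of trees and networks
# ---------------------------------------------------------------------------


def tree_splits(tree: PhyloTree) -> set[Split]:
    """One split per edge of the tree (trivial splits included)."""
    return tree.splits()


def induced_splits(net: MixedGraph) -> set[Split]:
    """Split(N): splits induced by the cut edges of the network."""
    out = set()
    taxa = net.taxa
    for eid in net.bridges():
        u, _, _ = net.edge(eid)
        side = _reachable_labels(net, eid, u)
        other = taxa - side
        if side and other:
            out.add(Split(side, other))
    return out


def _reachable_labels(net: MixedGraph, barrier_eid: int, start: str) -> frozenset[str]:
    seen = {start}
    stack = [start]
    labels = set()
    while stack:
        v = stack.pop()
        if v in net.leaves:
            labels.add(net.leaves[v])
        for e2 in net.incident(v):
            if e2 == barrier_eid:
                continue
            w = net.other_end(e2, v)
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return frozenset(labels)


def displayed_splits(net: SemiDirectedNetwork) -> set[Split]:
    """Split(T(N)): the union of the split sets of the displayed trees."""
    out: set[Split] = set()
    for t in displayed_trees(net).trees:
        out |= t.splits()
    return out
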