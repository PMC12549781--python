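"""Canonical form of level-2 galled outer-labeled planar networks.

Two networks in this class display the same set of quartet trees exactly
when they share a canonical form: the mixed graph obtained by applying, in
order, (i) contraction of 2-blobs, (ii) contraction of 3-blobs,
(iii) replacement of 4-blobs and (iv) split-symmetric 5-blobs by undirected
representative cycles, (v) contraction of 3-cycles in blobs with >= 5
articulation nodes, (vi) suppression of dts-undetectable 4-cycles,
(vii) contraction of dts-undetectable frontier edges (>= 6 articulation
nodes; may create degree-4 nodes that are *not* suppressed) and
(viii) undirecting the remaining 4-cycles.  "dts" is short for
displayed-tree-split: the suppressed features are invisible to the splits
of the displayed trees.

The canonical form is the most refined structure identifiable from
displayed quartets alone; :func:`distinguishable` exposes the resulting
equivalences between canonical forms, displayed quartet sets, displayed
splits, and (for bloblets) the NANUQ metric.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx

from .network import (
    Blob,
    ClassMembershipError,
    MixedGraph,
    SemiDirectedNetwork,
    are_isomorphic,
)
from .displayed import displayed_quartets, displayed_splits

__all__ = [
    "CanonicalPartition",
    "canonical_partition",
    "detect_split_symmetric_5blob",
    "detect_dts_4cycles",
    "detect_dts_edges",
    "canonical_form",
    "is_own_canonical_form",
    "distinguishable",
    "require_class_N2",
    "is_B2_bloblet",
]


# ---------------------------------------------------------------------------
# class membership helpers
# ---------------------------------------------------------------------------


def require_class_N2(net: SemiDirectedNetwork) -> None:
    rep = net.classify()
    if rep.level > 2 or not rep.galled or not rep.outer_labeled_planar:
        raise ClassMembershipError(
            "network is not outer-labeled planar, galled and level-2"
        )


def is_B2_bloblet(net: SemiDirectedNetwork) -> bool:
    rep = net.classify()
    return (
        rep.bloblet
        and rep.level <= 2
        and rep.galled
        and rep.outer_labeled_planar
    )


# ---------------------------------------------------------------------------
# canonical partition of strictly level-2 bloblets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CanonicalPartition:
    """Leaf partition {A1, A2, B1, B2, C1, C2} of a strictly level-2 bloblet.

    ``C_i`` is the pendant leaf of hybrid ``h_i``; ``A_i``/``B_i`` hold the
    leaves on the two arcs of gall *i*, with the A blocks of both galls
    attached on the same side of the shared edge.  Unique up to the
    interchanges A <-> B and 1 <-> 2.
    """

    A1: frozenset[str]
    A2: frozenset[str]
    B1: frozenset[str]
    B2: frozenset[str]
    C1: frozenset[str]
    C2: frozenset[str]

    def blocks(self):
        return {
            "A1": self.A1, "A2": self.A2,
            "B1": self.B1, "B2": self.B2,
            "C1": self.C1, "C2": self.C2,
        }

    def equivalent(self, other: "CanonicalPartition") -> bool:
        """Equality up to the allowed interchanges."""
        mine = (self.A1, self.A2, self.B1, self.B2, self.C1, self.C2)
        a1, a2, b1, b2, c1, c2 = (
            other.A1, other.A2, other.B1, other.B2, other.C1, other.C2,
        )
        variants = [
            (a1, a2, b1, b2, c1, c2),
            (b1, b2, a1, a2, c1, c2),          # A <-> B
            (a2, a1, b2, b1, c2, c1),          # 1 <-> 2
            (b2, b1, a2, a1, c2, c1),          # both
        ]
        return mine in variants


def _the_blob(net: SemiDirectedNetwork) -> Blob:
    nonleaf = [b for b in net.blobs() if len(b.nodes) > 1]
    if len(nonleaf) != 1:
        raise ClassMembershipError("network is not a bloblet")
    return nonleaf[0]


def _gall_of(net: MixedGraph, blob: Blob, hybrid: str) -> list[str]:
    """The cycle through both hybrid edges of ``hybrid`` containing no other
    hybrid edge, as the node sequence from one parent to the other."""
    e1, e2 = net.in_edges(hybrid)
    p1 = net.other_end(e1, hybrid)
    p2 = net.other_end(e2, hybrid)
    g = nx.Graph()
    g.add_nodes_from(blob.nodes)
    for eid in blob.edge_ids:
        u, v, head = net.edge(eid)
        if head is not None:
            continue
        g.add_edge(u, v)
    g.remove_node(hybrid)
    paths = list(nx.all_simple_paths(g, p1, p2))
    if len(paths) != 1:
        raise ClassMembershipError(
            "gall is not unique; network is outside the supported class"
        )
    return paths[0]


def canonical_partition(net: SemiDirectedNetwork) -> CanonicalPartition:
    """Canonical partition of a strictly level-2 galled planar bloblet."""
    rep = net.classify()
    if not (rep.bloblet and rep.level == 2 and rep.galled
            and rep.outer_labeled_planar):
        raise ClassMembershipError(
            "canonical partition requires a strictly level-2 galled "
            "outer-labeled planar bloblet"
        )
    if len(net.taxa) < 4:
        raise ClassMembershipError("need at least four leaves")
    blob = _the_blob(net)
    hybrids = sorted(blob.hybrids)
    if len(hybrids) != 2:
        raise ClassMembershipError("expected exactly two hybrid nodes")
    # the two shared-edge endpoints are the only non-articulation blob nodes
    inner = sorted(blob.nodes - blob.articulation_nodes)
    if len(inner) != 2:
        raise ClassMembershipError("unexpected blob shape (shared edge)")
    s, t = inner
    if t not in net.neighbors(s):
        raise ClassMembershipError("shared structure is not a single edge")

    def pendant_label(v: str) -> str | None:
        for eid in net.incident(v):
            w = net.other_end(eid, v)
            if w in net.leaves:
                return net.leaves[w]
        return None

    A: list[frozenset[str]] = []
    B: list[frozenset[str]] = []
    C: list[frozenset[str]] = []
    for h in hybrids:
        gall_path = _gall_of(net, blob, h)  # parent ... s ... t ... parent
        # walk from s away from t toward h: the A side
        if gall_path.index(s) > gall_path.index(t):
            gall_path = list(reversed(gall_path))
        # gall_path runs parent1 .. s, t .. parent2; arc nodes between h's
        # parents and s/t inclusive of parents
        si, ti = gall_path.index(s), gall_path.index(t)
        a_side = list(reversed(gall_path[:si]))  # from s toward h
        b_side = gall_path[ti + 1 :]  # from t toward h
        A.append(frozenset(pendant_label(v) for v in a_side))
        B.append(frozenset(pendant_label(v) for v in b_side))
        C.append(frozenset([pendant_label(h)]))
        if None in A[-1] or None in B[-1] or None in C[-1]:
            raise ClassMembershipError("blob node without a pendant leaf")
    return CanonicalPartition(A[0], A[1], B[0], B[1], C[0], C[1])


# ---------------------------------------------------------------------------
# detectors
# ---------------------------------------------------------------------------


def _blob_as_bloblet(net: MixedGraph, blob: Blob) -> MixedGraph:
    """The blob subgraph with one generic pendant leaf per articulation node
    (used for up-to-relabeling comparisons of blob structure)."""
    g = blob.subgraph()
    for i, v in enumerate(sorted(blob.articulation_nodes)):
        leaf = f"__l{i}"
        g.add_leaf(leaf, f"t{i}")
        g.add_edge(v, leaf)
    return g


_SPLIT_SYMMETRIC_TEMPLATE: MixedGraph | None = None


def _split_symmetric_template() -> MixedGraph:
    """Blob of the split-symmetric 5-blob: galls of lengths 5 and 4 sharing
    one edge, with one non-hybrid leaf on each of the three outer arcs
    (template sizes |A1|=|A2|=|B1|=1, |B2|=0)."""
    global _SPLIT_SYMMETRIC_TEMPLATE
    if _SPLIT_SYMMETRIC_TEMPLATE is None:
        from .generate import build_level2_bloblet

        net = build_level2_bloblet(["p"], ["q"], ["r"], [], "c1", "c2")
        blob = _the_blob(net)
        _SPLIT_SYMMETRIC_TEMPLATE = _blob_as_bloblet(net, blob)
    return _SPLIT_SYMMETRIC_TEMPLATE


def detect_split_symmetric_5blob(net: MixedGraph, blob: Blob) -> bool:
    """True iff the blob matches the split-symmetric 5-blob template (the
    displayed splits of such a blob are invariant under cyclically
    permuting its leaves)."""
    if len(blob.articulation_nodes) != 5 or len(blob.hybrids) != 2:
        return False
    return are_isomorphic(
        _blob_as_bloblet(net, blob),
        _split_symmetric_template(),
        mode="up_to_relabeling",
    )


def _blob_cycles(net: MixedGraph, blob: Blob, length: int | None = None):
    g = nx.MultiGraph()
    g.add_nodes_from(blob.nodes)
    for eid in blob.edge_ids:
        u, v, _ = net.edge(eid)
        g.add_edge(u, v)
    for cyc in nx.simple_cycles(g):
        if length is None or len(cyc) == length:
            yield cyc


def _hybrid_parents(net: MixedGraph, h: str) -> set[str]:
    return {net.other_end(eid, h) for eid in net.in_edges(h)}


def detect_dts_4cycles(net: MixedGraph, blob: Blob):
    """All 4-cycles through one hybrid *u* (with both its hybrid edges) and
    a parent of the other hybrid *v*, labeled ``(p_u, u, p'_u, w)`` with
    ``p_u, u`` articulation nodes and one of ``{p'_u, w}`` a parent of v."""
    if len(blob.hybrids) != 2:
        return []
    out = []
    for cyc in _blob_cycles(net, blob, 4):
        cset = set(cyc)
        hybs_on = [h for h in blob.hybrids if h in cset]
        if len(hybs_on) != 1:
            continue
        u = hybs_on[0]
        parents = _hybrid_parents(net, u)
        if not parents <= cset:
            continue  # the cycle does not carry both hybrid edges of u
        v = next(h for h in blob.hybrids if h != u)
        pv = _hybrid_parents(net, v)
        others = cset - {u} - parents
        if len(others) != 1:
            continue
        (w,) = others
        for p_u in parents:
            p_other = next(p for p in parents if p != p_u)
            if (
                p_u in blob.articulation_nodes
                and u in blob.articulation_nodes
                and (p_other in pv or w in pv)
            ):
                out.append((p_u, u, p_other, w))
                break
    return out


def detect_dts_edges(net: MixedGraph, blob: Blob):
    """Frontier edges invisible to displayed-tree splits.

    Type 1: both endpoints are hybrid parents; type 2: one endpoint is a
    hybrid parent and the other lies on a 4-cycle that the edge itself is
    not part of.  A blob admits at most one such edge (asserted).
    """
    parents: set[str] = set()
    for h in blob.hybrids:
        parents |= _hybrid_parents(net, h)
    on_4cycle: set[str] = set()
    cycles4 = [set(c) for c in _blob_cycles(net, blob, 4)]
    for c in cycles4:
        on_4cycle |= c
    found = []
    for eid in blob.edge_ids:
        u, v, head = net.edge(eid)
        if head is not None:
            continue
        if u not in blob.articulation_nodes and v not in blob.articulation_nodes:
            continue  # not a frontier edge
        if u in parents and v in parents:
            found.append((eid, 1))
        else:
            on_cycle_with_both = any({u, v} <= c for c in cycles4)
            if not on_cycle_with_both and (
                (u in parents and v in on_4cycle)
                or (v in parents and u in on_4cycle)
            ):
                found.append((eid, 2))
    if len(found) > 1:
        raise AssertionError("blob has more than one dts-undetectable edge")
    return found


# ---------------------------------------------------------------------------
# canonical form
# ---------------------------------------------------------------------------


_counter = itertools.count()


def _contract_blob(g: MixedGraph, blob: Blob) -> None:
    new = g.add_node(f"__c{next(_counter)}")
    for v in blob.nodes:
        for eid in list(g.incident(v)):
            if eid in blob.edge_ids:
                continue
            u, w, head = g.edge(eid)
            other = w if v == u else u
            if head is not None and head == v:
                raise ClassMembershipError("hybrid cut edge enters a blob")
            g.remove_edge(eid)
            g.add_edge(new, other, head if head == other else None)
    for v in blob.nodes:
        g.remove_node(v)
    g.suppress_degree2()


def _replace_blob_by_cycle(g: MixedGraph, blob: Blob) -> None:
    cut = []
    for v in sorted(blob.nodes):
        for eid in g.incident(v):
            if eid not in blob.edge_ids:
                cut.append(eid)
    order = SemiDirectedNetwork._blob_attachment_order(g, blob, cut)
    ring = [g.add_node(f"__r{next(_counter)}") for _ in order]
    for i, eid in enumerate(order):
        u, w, head = g.edge(eid)
        inside = u if u in blob.nodes else w
        other = w if inside == u else u
        g.remove_edge(eid)
        g.add_edge(ring[i], other, head if head == other else None)
    for v in blob.nodes:
        g.remove_node(v)
    k = len(ring)
    for i in range(k):
        g.add_edge(ring[i], ring[(i + 1) % k])


def _contract_cycle(g: MixedGraph, nodes: set[str]) -> None:
    new = g.add_node(f"__c{next(_counter)}")
    for v in nodes:
        for eid in list(g.incident(v)):
            u, w, head = g.edge(eid)
            other = w if v == u else u
            if other in nodes:
                g.remove_edge(eid)
                continue
            g.remove_edge(eid)
            g.add_edge(new, other, head if head == other else None)
    for v in nodes:
        if v in g.nodes:
            g.remove_node(v)


def _suppress_dts_4cycle(g: MixedGraph, labeled_cycle) -> None:
    p_u, u, p_other, _w = labeled_cycle
    for eid in list(g.in_edges(u)):
        tail = g.other_end(eid, u)
        if tail == p_u:
            g.remove_edge(eid)
        elif tail == p_other:
            g.undirect_edge(eid)
    g.suppress_degree2()


def _contract_edge(g: MixedGraph, eid: int) -> None:
    u, v, head = g.edge(eid)
    if head is not None:
        raise ValueError("cannot contract a hybrid edge")
    new = g.add_node(f"__m{next(_counter)}")
    for x in (u, v):
        for e2 in list(g.incident(x)):
            if e2 == eid:
                continue
            a, b, h = g.edge(e2)
            other = b if x == a else a
            g.remove_edge(e2)
            if other in (u, v):
                other = new  # edge between the merged pair becomes parallel
            g.add_edge(new, other, h if h == other else (new if h == x else None))
    g.remove_edge(eid)
    g.remove_node(u)
    g.remove_node(v)


def canonical_form(net: SemiDirectedNetwork, blob_order_seed: int | None = None) -> MixedGraph:
    """Apply operations (i)-(viii) of the canonical-form rewriting.

    ``blob_order_seed`` shuffles the order in which blobs are visited; the
    result is independent of that order (the operations act on blobs in
    isolation), which the tests exercise.
    """
    require_class_N2(net)
    g: MixedGraph = MixedGraph.adopt(net)

    def nonleaf_blobs():
        out = [b for b in g.blobs() if len(b.nodes) > 1]
        if blob_order_seed is not None:
            import random

            random.Random(blob_order_seed).shuffle(out)
        return out

    # (i) contract 2-blobs
    for b in nonleaf_blobs():
        if len(b.nodes) == 2 and len(b.edge_ids) >= 2:
            _contract_blob(g, b)
    # (ii) contract 3-blobs
    for b in nonleaf_blobs():
        if len(b.articulation_nodes) == 3:
            _contract_blob(g, b)
    # (iii) 4-blobs -> representative cycles
    for b in nonleaf_blobs():
        if len(b.articulation_nodes) == 4:
            _replace_blob_by_cycle(g, b)
    # (iv) split-symmetric 5-blobs -> representative cycles
    for b in nonleaf_blobs():
        if detect_split_symmetric_5blob(g, b):
            _replace_blob_by_cycle(g, b)
    # (v) contract 3-cycles in k-blobs, k >= 5
    changed = True
    while changed:
        changed = False
        for b in nonleaf_blobs():
            if len(b.articulation_nodes) < 5:
                continue
            for cyc in _blob_cycles(g, b, 3):
                _contract_cycle(g, set(cyc))
                changed = True
                break
            if changed:
                break
    # (vi) suppress dts-undetectable 4-cycles in k-blobs, k >= 5
    changed = True
    while changed:
        changed = False
        for b in nonleaf_blobs():
            if len(b.articulation_nodes) < 5 or len(b.hybrids) != 2:
                continue
            cycles = detect_dts_4cycles(g, b)
            if cycles:
                _suppress_dts_4cycle(g, cycles[0])
                changed = True
                break
    # (vii) contract dts-undetectable edges in k-blobs, k >= 6
    for b in nonleaf_blobs():
        if len(b.articulation_nodes) < 6:
            continue
        if detect_split_symmetric_5blob(g, b) or detect_dts_4cycles(g, b):
            continue
        for eid, _kind in detect_dts_edges(g, b):
            _contract_edge(g, eid)
    # (viii) undirect remaining 4-cycles in k-blobs, k >= 6
    for b in nonleaf_blobs():
        if len(b.articulation_nodes) < 6:
            continue
        for cyc in _blob_cycles(g, b, 4):
            cset = set(cyc)
            for eid in list(b.edge_ids):
                if eid not in g.edge_ids:
                    continue
                u, v, head = g.edge(eid)
                if head is not None and u in cset and v in cset:
                    g.undirect_edge(eid)
    g.refresh_hybrid_status()
    return g


def is_own_canonical_form(net: SemiDirectedNetwork) -> bool:
    return are_isomorphic(canonical_form(net), net, mode="labeled")


# ---------------------------------------------------------------------------
# distinguishability
# ---------------------------------------------------------------------------


def distinguishable(
    n1: SemiDirectedNetwork,
    n2: SemiDirectedNetwork,
    by: str = "canonical",
) -> bool:
    """Whether two networks can be told apart by the chosen criterion.

    ``canonical``: different canonical forms; ``quartets``: different
    displayed quartet sets; ``splits``: different displayed split sets;
    ``nanuq``: different NANUQ metrics (bloblets on >= 4 leaves only).
    The four criteria agree wherever they are all defined.
    """
    if n1.taxa != n2.taxa:
        raise ValueError("networks must share a leaf set")
    if by == "canonical":
        return not are_isomorphic(canonical_form(n1), canonical_form(n2),
                                  mode="labeled")
    if by == "quartets":
        return displayed_quartets(n1) != displayed_quartets(n2)
    if by == "splits":
        return displayed_splits(n1) != displayed_splits(n2)
    if by == "nanuq":
        from .metrics import nanuq_metric

        if not (is_B2_bloblet(n1) and is_B2_bloblet(n2)):
            raise ClassMembershipError("nanuq criterion needs B2 bloblets")
        if len(n1.taxa) < 4:
            raise ClassMembershipError("nanuq criterion needs >= 4 leaves")
        return nanuq_metric(n1) != nanuq_metric(n2)
    raise ValueError(f"unknown criterion {by!r}")
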