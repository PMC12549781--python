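"""Constructors for level-1/level-2 bloblets, exhaustive small enumerations,
figure fixtures, and a seeded random generator.

Every strictly level-2 galled outer-labeled planar bloblet has the shape of
two undirected cycles (the *galls*) sharing a single edge ``{s, t}``, with
hybrid ``h_i`` on gall *i* carrying a pendant hybrid leaf ``c_i`` and every
other cycle node carrying one pendant leaf; the leaves on the two arcs of
gall *i* form the blocks ``A_i`` (on the *s* side) and ``B_i`` (on the *t*
side).  The block sizes ``(|A1|, |A2|, |B1|, |B2|)`` determine the network
up to relabeling, which makes exhaustive enumeration of small bloblets a
walk over integer compositions.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass

from .network import (
    CircularOrder,
    MixedGraph,
    SemiDirectedNetwork,
    ValidationError,
    are_isomorphic,
)

__all__ = [
    "Level2Template",
    "build_level1_cycle_bloblet",
    "build_level2_bloblet",
    "build_from_template",
    "enumerate_small_bloblets",
    "random_network",
    "random_bloblet",
    "figure_fixtures",
    "graft_subtree",
]


@dataclass(frozen=True)
class Level2Template:
    """Labels for the blocks of a strictly level-2 bloblet (two-gall shape)."""

    a1: tuple[str, ...]
    a2: tuple[str, ...]
    b1: tuple[str, ...]
    b2: tuple[str, ...]
    c1: str
    c2: str

    @property
    def sizes(self) -> tuple[int, int, int, int]:
        return (len(self.a1), len(self.a2), len(self.b1), len(self.b2))

    @property
    def labels(self) -> tuple[str, ...]:
        return self.a1 + self.a2 + self.b1 + self.b2 + (self.c1, self.c2)


def build_level1_cycle_bloblet(labels, hybrid_index: int = 0) -> SemiDirectedNetwork:
    """An n-cycle blob with one pendant leaf per cycle node; the cycle node
    above ``labels[hybrid_index]`` is the hybrid (both its cycle edges are
    hybrid edges)."""
    labels = list(labels)
    n = len(labels)
    if n < 4:
        raise ValueError("cycle bloblet needs at least four leaves")
    net = SemiDirectedNetwork()
    ring = [f"v{i}" for i in range(n)]
    h = ring[hybrid_index % n]
    for i, lab in enumerate(labels):
        net.add_leaf(f"L{i}", lab)
        net.add_edge(ring[i], f"L{i}")
    for i in range(n):
        u, v = ring[i], ring[(i + 1) % n]
        head = h if h in (u, v) else None
        net.add_edge(u, v, head)
    net.validate()
    return net


def build_level2_bloblet(a1, a2, b1, b2, c1: str, c2: str) -> SemiDirectedNetwork:
    """A strictly level-2 bloblet with the given block labels.

    Gall *i* runs ``s, A_i nodes, h_i, B_i nodes, t`` plus the shared edge
    ``{s, t}``; the two cycle edges at ``h_i`` are its hybrid edges and the
    hybrid leaf ``c_i`` hangs below ``h_i``.
    """
    blocks = [list(a1), list(a2)], [list(b1), list(b2)]
    net = SemiDirectedNetwork()
    s = net.add_node("s")
    t = net.add_node("t")
    net.add_edge(s, t)  # the shared edge
    for i in range(2):
        ai, bi = blocks[0][i], blocks[1][i]
        h = net.add_node(f"h{i+1}")
        chain = [s]
        for k, lab in enumerate(ai):
            v = net.add_node(f"a{i+1}_{k}")
            net.add_leaf(f"La{i+1}_{k}", lab)
            net.add_edge(v, f"La{i+1}_{k}")
            chain.append(v)
        chain.append(h)
        for k, lab in enumerate(bi):
            v = net.add_node(f"b{i+1}_{k}")
            net.add_leaf(f"Lb{i+1}_{k}", lab)
            net.add_edge(v, f"Lb{i+1}_{k}")
            chain.append(v)
        chain.append(t)
        for u, v in zip(chain, chain[1:]):
            head = h if h in (u, v) else None
            net.add_edge(u, v, head)
        net.add_leaf(f"Lc{i+1}", [c1, c2][i])
        net.add_edge(h, f"Lc{i+1}")
    net.validate()
    return net


def build_from_template(tmpl: Level2Template) -> SemiDirectedNetwork:
    return build_level2_bloblet(tmpl.a1, tmpl.a2, tmpl.b1, tmpl.b2,
                                tmpl.c1, tmpl.c2)


# ---------------------------------------------------------------------------
# enumeration of small bloblets
# ---------------------------------------------------------------------------


def _compositions(total: int, parts: int):
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, parts - 1):
            yield (first,) + rest


def _size_orbit(sizes: tuple[int, int, int, int]):
    a1, a2, b1, b2 = sizes
    return {
        (a1, a2, b1, b2),
        (b1, b2, a1, a2),  # A <-> B
        (a2, a1, b2, b1),  # 1 <-> 2
        (b2, b1, a2, a1),
    }


def enumerate_small_bloblets(n: int, three_cycle_free: bool = True):
    """All galled outer-labeled planar level-<=2 bloblets on ``x1..xn``, up
    to relabeling, in deterministic order.

    Generated from the level-1 cycle (one representative; hybrid position
    is a relabeling) and all block-size compositions of the two-gall shape,
    deduplicated by up-to-relabeling isomorphism and validated.
    """
    if not 4 <= n <= 7:
        raise ValueError("enumeration supports 4 <= n <= 7")
    labels = [f"x{i+1}" for i in range(n)]
    reps: list[SemiDirectedNetwork] = []
    reps.append(build_level1_cycle_bloblet(labels, 0))
    seen_orbits: set[frozenset] = set()
    for sizes in sorted(_compositions(n - 2, 4), reverse=True):
        a1, a2, b1, b2 = sizes
        lo = 1 if three_cycle_free else 0
        if a1 + b1 < lo or a2 + b2 < lo:
            continue
        orbit = frozenset(_size_orbit(sizes))
        if orbit in seen_orbits:
            continue
        seen_orbits.add(orbit)
        # leaves in the induced circular order (c1, A1, A2, c2, B2, B1)
        it = iter(labels)
        c1 = next(it)
        la1 = [next(it) for _ in range(a1)]
        la2 = [next(it) for _ in range(a2)]
        c2 = next(it)
        lb2 = list(reversed([next(it) for _ in range(b2)]))
        lb1 = list(reversed([next(it) for _ in range(b1)]))
        reps.append(build_level2_bloblet(la1, la2, lb1, lb2, c1, c2))
    # paranoia: the size-orbit dedup must agree with graph isomorphism
    for g1, g2 in itertools.combinations(reps, 2):
        if are_isomorphic(g1, g2, mode="up_to_relabeling"):
            raise AssertionError("enumeration produced isomorphic duplicates")
    return reps


# ---------------------------------------------------------------------------
# random networks
# ---------------------------------------------------------------------------


def _random_binary_tree(labels, rng: random.Random) -> MixedGraph:
    g = MixedGraph()
    labels = list(labels)
    rng.shuffle(labels)
    a, b, c = labels[:3]
    center = g.add_node("i0")
    for j, lab in enumerate((a, b, c)):
        g.add_leaf(f"L{j}", lab)
        g.add_edge(center, f"L{j}")
    counter = 1
    for j, lab in enumerate(labels[3:], start=3):
        eid = rng.choice(sorted(g.edge_ids))
        u, v, _ = g.edge(eid)
        mid = g.add_node(f"i{counter}")
        counter += 1
        g.remove_edge(eid)
        g.add_edge(u, mid)
        g.add_edge(mid, v)
        g.add_leaf(f"L{j}", lab)
        g.add_edge(mid, f"L{j}")
    return g


def random_network(n: int, level: int = 2, seed: int = 0,
                   n_blobs: int | None = None) -> SemiDirectedNetwork:
    """A seeded random member of the galled outer-labeled planar level-k
    class: a random binary tree with random internal regions expanded into
    cycle blobs (level 1) or two-gall blobs (level 2)."""
    if n < 4:
        raise ValueError("need at least four leaves")
    if level not in (0, 1, 2):
        raise ValueError("level must be 0, 1 or 2")
    rng = random.Random(seed)
    labels = [f"x{i+1}" for i in range(n)]
    tag_counter = itertools.count()
    for attempt in range(50):
        g = _random_binary_tree(labels, rng)
        if level == 0:
            net = _as_network(g)
            return net
        internals = sorted(v for v in g.nodes if v not in g.leaves)
        want = n_blobs if n_blobs is not None else rng.randint(1, max(1, len(internals) // 3))
        blobs_made = 0
        used: set[str] = set()
        strict_level2 = False
        for _ in range(want):
            free = [v for v in internals if v not in used and v in g.nodes]
            if not free:
                break
            seedv = rng.choice(free)
            group = {seedv}
            while rng.random() < 0.45:
                frontier = [
                    w
                    for v in group
                    for w in g.neighbors(v)
                    if w not in g.leaves and w not in used and w not in group
                    and w in internals
                ]
                if not frontier:
                    break
                group.add(rng.choice(frontier))
            used |= group
            blob_level = level if level == 1 else rng.choice([1, 2])
            if _expand_to_blob(g, group, blob_level, rng, next(tag_counter)):
                blobs_made += 1
                if blob_level == 2:
                    strict_level2 = True
        if blobs_made == 0:
            continue
        if level == 2 and not strict_level2:
            # keep drawing until at least one two-gall blob is present so
            # the requested class is exercised, not just its level-1 part
            if attempt < 40:
                continue
        try:
            net = _as_network(g)
        except ValidationError:
            continue  # rare unrootable draw; try a fresh tree
        rep = net.classify()
        if rep.level <= level and rep.galled and rep.outer_labeled_planar:
            return net
    raise ValidationError("random generator failed to produce a valid network")


def _as_network(g: MixedGraph) -> SemiDirectedNetwork:
    net = SemiDirectedNetwork.adopt(g)
    net.validate()
    return net


def _expand_to_blob(g: MixedGraph, group: set[str], blob_level: int,
                    rng: random.Random, tag: int) -> bool:
    """Replace a connected set of internal tree nodes by a blob whose
    attachments are the edges leaving the set, in a random rotation."""
    attach = []
    for v in sorted(group):
        for eid in g.incident(v):
            if g.other_end(eid, v) not in group:
                attach.append(eid)
    d = len(attach)
    if blob_level == 2 and d < 4:
        return False
    if blob_level == 1 and d < 3:
        return False
    rng.shuffle(attach)

    def reattach(eid, node):
        u, v, head = g.edge(eid)
        inside = u if u in group else v
        outside = v if inside == u else u
        g.remove_edge(eid)
        g.add_edge(node, outside, head if head == outside else None)

    if blob_level == 1:
        ring = [g.add_node(f"q{tag}_{i}") for i in range(d)]
        for i, eid in enumerate(attach):
            reattach(eid, ring[i])
        hpos = rng.randrange(d)
        h = ring[hpos]
        for i in range(d):
            u, v = ring[i], ring[(i + 1) % d]
            g.add_edge(u, v, h if h in (u, v) else None)
    else:
        sizes = None
        while sizes is None:
            cand = rng.choice(list(_compositions(d - 2, 4)))
            sizes = cand
        a1, a2, b1, b2 = sizes
        s = g.add_node(f"q{tag}_s")
        t = g.add_node(f"q{tag}_t")
        g.add_edge(s, t)
        idx = 0
        # attachment order around the blob: c1, A1, A2, c2, B2, B1
        order = attach
        pos = {}
        pos["c1"] = order[0]
        pos["a1"] = order[1 : 1 + a1]
        pos["a2"] = order[1 + a1 : 1 + a1 + a2]
        pos["c2"] = order[1 + a1 + a2]
        rest = order[2 + a1 + a2 :]
        pos["b2"] = list(reversed(rest[:b2]))
        pos["b1"] = list(reversed(rest[b2:]))
        for i in range(2):
            h = g.add_node(f"q{tag}_h{i+1}")
            chain = [s]
            for k, eid in enumerate(pos[f"a{i+1}"]):
                v = g.add_node(f"q{tag}_a{i+1}_{k}")
                reattach(eid, v)
                chain.append(v)
            chain.append(h)
            for k, eid in enumerate(pos[f"b{i+1}"]):
                v = g.add_node(f"q{tag}_b{i+1}_{k}")
                reattach(eid, v)
                chain.append(v)
            chain.append(t)
            for u, v in zip(chain, chain[1:]):
                g.add_edge(u, v, h if h in (u, v) else None)
            reattach(pos[f"c{i+1}"], h)
    for v in group:
        g.remove_node(v)
    return True


def random_bloblet(n: int, seed: int = 0, level: int | None = None) -> SemiDirectedNetwork:
    """A seeded random galled outer-labeled planar bloblet on n leaves
    (level 1 or 2; a random block-size composition for level 2)."""
    rng = random.Random(seed)
    labels = [f"x{i+1}" for i in range(n)]
    rng.shuffle(labels)
    lvl = level if level is not None else rng.choice([1, 2])
    if lvl == 1:
        return build_level1_cycle_bloblet(labels, rng.randrange(n))
    sizes = rng.choice(list(_compositions(n - 2, 4)))
    a1, a2, b1, b2 = sizes
    it = iter(labels)
    la1 = [next(it) for _ in range(a1)]
    la2 = [next(it) for _ in range(a2)]
    lb1 = [next(it) for _ in range(b1)]
    lb2 = [next(it) for _ in range(b2)]
    return build_level2_bloblet(la1, la2, lb1, lb2, next(it), next(it))


# ---------------------------------------------------------------------------
# figure fixtures
# ---------------------------------------------------------------------------


def graft_subtree(net: SemiDirectedNetwork, leaf_label: str, spec) -> None:
    """Replace the leaf with a binary subtree given as nested label tuples."""
    v = net.leaf_of(leaf_label)
    del net.leaves[v]
    counter = itertools.count()

    def build(parent: str, sub) -> None:
        if isinstance(sub, str):
            node = f"{v}_g{next(counter)}"
            net.add_leaf(node, sub)
            net.add_edge(parent, node)
            return
        left, right = sub
        node = net.add_node(f"{v}_g{next(counter)}")
        net.add_edge(parent, node)
        build(node, left)
        build(node, right)

    left, right = spec
    build(v, left)
    build(v, right)


def figure_fixtures() -> dict[str, SemiDirectedNetwork]:
    """Named small networks used throughout the tests.

    The 4-, 5- and 6-leaf bloblets realize the published example quarnets
    and the complete 3-cycle-free 5- and 6-leaf catalogues; ``fig9_*``
    labelings reproduce the published table of pairwise NANUQ distances.
    ``fig2b`` is a synthetic 10-leaf multi-blob example (see its entry).
    """
    fx: dict[str, SemiDirectedNetwork] = {}
    # level-1 4-cycle quarnet; one leaf (here x) below the hybrid
    fx["fig4_col2"] = build_level1_cycle_bloblet(["x", "y", "z", "w"], 0)
    # two 4-cycle galls sharing an edge; hybrids above y and w
    fx["fig4_col3"] = build_level2_bloblet(["x"], ["z"], [], [], "y", "w")

    # -- 5-leaf catalogue (labels a..e in circular order) ------------------
    fx["fig8_N1"] = build_level1_cycle_bloblet(["a", "b", "c", "d", "e"], 0)
    fx["fig8_N2"] = build_level2_bloblet(["c", "b"], ["d"], [], [], "a", "e")
    fx["fig8_N3"] = build_level2_bloblet(["c", "b"], [], [], ["e"], "a", "d")
    fx["fig8_N4"] = build_level2_bloblet(["b"], ["c"], ["e"], [], "a", "d")

    # -- 6-leaf catalogue (labelings pinned by the published distances) ----
    for name, args in _FIG9_SPECS.items():
        fx[name] = build_level2_bloblet(*args) if len(args) == 6 else args[0]()
    # -- multi-blob examples -----------------------------------------------
    fx["fig5_general"] = build_level2_bloblet(
        ["a1"], ["a2"], ["b1"], ["b2"], "c1", "c2"
    )
    fx["fig2b"] = _fig2b_standin()
    return fx


def _fig9_N1() -> SemiDirectedNetwork:
    return build_level1_cycle_bloblet(["a", "b", "c", "d", "e", "f"], 0)


# Block labels (A1, A2, B1, B2, c1, c2) for the strictly level-2 members of
# the 6-leaf catalogue, transcribed so that their pairwise NANUQ distances
# reproduce the published table for the five canonical classes: (a) N1-N3,
# (b) N4, (c) N5, (d) N6, (e) N7-N9.
_FIG9_SPECS: dict[str, tuple] = {
    "fig9_N1": (_fig9_N1,),
    "fig9_N2": (["d", "c", "b"], ["e"], [], [], "a", "f"),
    "fig9_N3": (["d", "c", "b"], [], [], ["f"], "a", "e"),
    "fig9_N4": (["c"], ["d"], ["a"], ["f"], "b", "e"),
    "fig9_N5": (["a", "b"], ["f", "e"], [], [], "c", "d"),
    "fig9_N6": ([], ["f", "e"], ["b", "c"], [], "a", "d"),
    "fig9_N7": (["c", "b"], ["d"], ["f"], [], "a", "e"),
    "fig9_N8": (["c", "b"], ["d"], [], ["f"], "a", "e"),
    "fig9_N9": (["c", "b"], [], ["f"], ["e"], "a", "d"),
}


def _fig2b_standin() -> SemiDirectedNetwork:
    """Synthetic 10-leaf strictly level-2 network with tree parts.

    The published 10-leaf example cannot be transcribed from text alone;
    this stand-in reproduces its stated properties: strictly level-2,
    galled, outer-labeled planar, not a bloblet, and inducing the circular
    order (x1, ..., x10).
    """
    net = build_level2_bloblet(["x2"], ["A2"], ["B1"], ["x6"], "x1", "x5")
    graft_subtree(net, "A2", ("x3", "x4"))
    graft_subtree(net, "B1", (("x10", "x9"), ("x8", "x7")))
    net.validate()
    return net
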