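"""Semi-directed phylogenetic networks as leaf-labeled mixed multigraphs.

A semi-directed network is obtained from a rooted binary network by
suppressing the root and undirecting every non-hybrid edge; only the two
edges entering each hybrid node (reticulation) keep their direction.  The
:class:`MixedGraph` base class stores an arbitrary leaf-labeled mixed
multigraph (parallel edges and non-binary degrees allowed, as needed for
canonical forms); :class:`SemiDirectedNetwork` adds the validity contract:
binary degrees, hybrid nodes with exactly two incoming hybrid edges, and
the existence of a rooted partner whose root is the least stable ancestor
(LSA) of the taxon set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "MixedGraph",
    "SemiDirectedNetwork",
    "Blob",
    "ClassReport",
    "CircularOrder",
    "NetworkError",
    "ParseError",
    "ValidationError",
    "ClassMembershipError",
    "parse_network",
    "parse_edgelist",
    "parse_enewick",
    "write_edgelist",
    "write_enewick",
    "are_isomorphic",
]


class NetworkError(Exception):
    """Base error for network handling."""


class ParseError(NetworkError):
    """Malformed input text."""


class ValidationError(NetworkError):
    """Graph violates the semi-directed network contract."""


class ClassMembershipError(NetworkError):
    """Network is not in the class required by an operation."""


# ---------------------------------------------------------------------------
# mixed multigraph
# ---------------------------------------------------------------------------


class MixedGraph:
    """Leaf-labeled mixed multigraph with undirected and directed (hybrid) edges.

    Edges are identified by integer keys.  Each edge is a triple
    ``(u, v, head)`` where ``head`` is ``None`` for an undirected edge or one
    of ``u, v`` for a directed (hybrid) edge pointing at that endpoint.
    Node identifiers are arbitrary strings; only leaf labels carry meaning.
    """

    def __init__(self) -> None:
        self._edges: dict[int, tuple[str, str, str | None]] = {}
        self._adj: dict[str, list[int]] = {}
        self.leaves: dict[str, str] = {}  # node -> taxon label
        self._next_eid = 0

    # -- construction ------------------------------------------------------

    def add_node(self, v: str) -> str:
        self._adj.setdefault(v, [])
        return v

    def add_leaf(self, v: str, label: str) -> str:
        self.add_node(v)
        self.leaves[v] = label
        return v

    def add_edge(self, u: str, v: str, head: str | None = None) -> int:
        if head is not None and head not in (u, v):
            raise ValueError("head must be an endpoint")
        self.add_node(u)
        self.add_node(v)
        eid = self._next_eid
        self._next_eid += 1
        self._edges[eid] = (u, v, head)
        self._adj[u].append(eid)
        self._adj[v].append(eid)
        return eid

    def remove_edge(self, eid: int) -> None:
        u, v, _ = self._edges.pop(eid)
        self._adj[u].remove(eid)
        if u != v:
            self._adj[v].remove(eid)

    def remove_node(self, v: str) -> None:
        for eid in list(self._adj[v]):
            self.remove_edge(eid)
        del self._adj[v]
        self.leaves.pop(v, None)

    def copy(self) -> "MixedGraph":
        g = type(self).__new__(type(self))
        g._edges = dict(self._edges)
        g._adj = {v: list(e) for v, e in self._adj.items()}
        g.leaves = dict(self.leaves)
        g._next_eid = self._next_eid
        return g

    @classmethod
    def adopt(cls, g: "MixedGraph"):
        """Re-type a graph (shares no mutable state with the source)."""
        new = cls.__new__(cls)
        new._edges = dict(g._edges)
        new._adj = {v: list(e) for v, e in g._adj.items()}
        new.leaves = dict(g.leaves)
        new._next_eid = g._next_eid
        return new

    # -- queries -----------------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        return list(self._adj)

    @property
    def edge_ids(self) -> list[int]:
        return list(self._edges)

    def edge(self, eid: int) -> tuple[str, str, str | None]:
        return self._edges[eid]

    def edges(self):
        """Iterate over ``(eid, u, v, head)``."""
        for eid, (u, v, head) in self._edges.items():
            yield eid, u, v, head

    def degree(self, v: str) -> int:
        return len(self._adj[v])

    def incident(self, v: str) -> list[int]:
        return list(self._adj[v])

    def other_end(self, eid: int, v: str) -> str:
        u, w, _ = self._edges[eid]
        return w if v == u else u

    def neighbors(self, v: str) -> list[str]:
        return [self.other_end(eid, v) for eid in self._adj[v]]

    def in_edges(self, v: str) -> list[int]:
        """Directed edges whose head is ``v``."""
        return [eid for eid in self._adj[v] if self._edges[eid][2] == v]

    def is_hybrid(self, v: str) -> bool:
        return len(self.in_edges(v)) == 2

    def hybrid_nodes(self) -> list[str]:
        return [v for v in self._adj if self.is_hybrid(v)]

    def hybrid_edges(self) -> list[int]:
        return [eid for eid, (_, _, h) in self._edges.items() if h is not None]

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(self.leaves.values())

    def leaf_of(self, label: str) -> str:
        for v, lab in self.leaves.items():
            if lab == label:
                return v
        raise KeyError(label)

    # -- rewriting ---------------------------------------------------------

    def undirect_edge(self, eid: int) -> None:
        u, v, _ = self._edges[eid]
        self._edges[eid] = (u, v, None)

    def refresh_hybrid_status(self) -> None:
        """Undirect every directed edge whose head has in-degree below two.

        After deleting edges (subnetworks, displayed trees) a former hybrid
        node that retains fewer than two incoming hybrid edges stops being a
        hybrid; its remaining in-edge becomes an ordinary undirected edge.
        """
        changed = True
        while changed:
            changed = False
            for v in self.nodes:
                ins = self.in_edges(v)
                if len(ins) == 1:
                    self.undirect_edge(ins[0])
                    changed = True

    def prune_dead_leaves(self, keep: set[str] | None = None) -> None:
        """Recursively delete unlabeled nodes of degree <= 1."""
        keep = keep or set()
        while True:
            dead = [
                v
                for v in self.nodes
                if self.degree(v) <= 1 and v not in self.leaves and v not in keep
            ]
            if not dead:
                return
            for v in dead:
                self.remove_node(v)

    def suppress_degree2(self) -> None:
        """Exhaustively suppress unlabeled degree-2 nodes.

        Merging edges ``(u,v)`` and ``(v,w)`` yields ``(u,w)``, directed
        toward ``w`` iff ``(v,w)`` was (and symmetrically toward ``u``).
        A degree-2 node joined to a single neighbor by a parallel pair is
        removed together with both edges (the 2-cycle is contracted).
        """
        changed = True
        while changed:
            changed = False
            for v in self.nodes:
                if v in self.leaves or self.degree(v) != 2:
                    continue
                e1, e2 = self._adj[v]
                if e1 == e2:  # self-loop; drop it
                    self.remove_node(v)
                    changed = True
                    continue
                u = self.other_end(e1, v)
                w = self.other_end(e2, v)
                if u == w:
                    # parallel pair: contract the 2-cycle
                    self.remove_node(v)
                    changed = True
                    continue
                h1 = self._edges[e1][2]
                h2 = self._edges[e2][2]
                if h1 == v and h2 == v:
                    raise ValidationError(
                        "cannot suppress a node with two incoming hybrid edges"
                    )
                head: str | None = None
                if h2 == w:
                    head = w
                if h1 == u:
                    if head is not None:
                        raise ValidationError("suppression would bidirect an edge")
                    head = u
                self.remove_node(v)
                self.add_edge(u, w, head)
                changed = True

    def relabeled_copy(self, prefix: str = "n") -> "MixedGraph":
        """Copy with fresh opaque node identifiers (leaf labels preserved)."""
        g = type(self)()
        mapping = {v: f"{prefix}{i}" for i, v in enumerate(sorted(self._adj))}
        for v in self._adj:
            if v in self.leaves:
                g.add_leaf(mapping[v], self.leaves[v])
            else:
                g.add_node(mapping[v])
        for _, u, v, head in self.edges():
            g.add_edge(mapping[u], mapping[v], None if head is None else mapping[head])
        return g

    # -- conversions -------------------------------------------------------

    def to_multigraph(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        g.add_nodes_from(self._adj)
        for eid, u, v, _ in self.edges():
            g.add_edge(u, v, key=eid)
        return g

    def to_simple_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self._adj)
        g.add_edges_from((u, v) for _, u, v, _ in self.edges())
        return g

    def _iso_digraph(self, labeled: bool) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for v in self._adj:
            if v in self.leaves:
                g.add_node(v, tag=self.leaves[v] if labeled else "@leaf")
            else:
                g.add_node(v, tag="")
        for _, u, v, head in self.edges():
            if head is None:
                g.add_edge(u, v, kind="u")
                g.add_edge(v, u, kind="u")
            else:
                tail = u if head == v else v
                g.add_edge(tail, head, kind="h")
        return g

    # -- structure ---------------------------------------------------------

    def is_connected(self) -> bool:
        if not self._adj:
            return True
        return nx.is_connected(self.to_multigraph())

    def bridges(self) -> set[int]:
        """Cut edges.  Parallel edges are never bridges."""
        g = self.to_multigraph()
        out: set[int] = set()
        for eid, u, v, _ in self.edges():
            if u == v:
                continue
            g.remove_edge(u, v, key=eid)
            if not nx.has_path(g, u, v):
                out.add(eid)
            g.add_edge(u, v, key=eid)
        return out

    def blobs(self) -> list["Blob"]:
        """Maximal connected subgraphs without cut edges (2-edge-connected
        components, including trivial single-node blobs)."""
        bridges = self.bridges()
        g = nx.MultiGraph()
        g.add_nodes_from(self._adj)
        for eid, u, v, _ in self.edges():
            if eid not in bridges:
                g.add_edge(u, v, key=eid)
        blobs = []
        for comp in nx.connected_components(g):
            nodes = frozenset(comp)
            arts = frozenset(
                v
                for v in nodes
                if any(e in bridges for e in self._adj[v])
            )
            hybs = frozenset(v for v in nodes if self.is_hybrid(v))
            eids = frozenset(
                eid
                for eid, u, v, _ in self.edges()
                if u in nodes and v in nodes and eid not in bridges
            )
            blobs.append(Blob(self, nodes, arts, hybs, eids))
        return blobs

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<{type(self).__name__} |V|={len(self._adj)} |E|={len(self._edges)} "
            f"taxa={sorted(self.taxa)}>"
        )


@dataclass(frozen=True)
class Blob:
    """A 2-edge-connected component of a network.

    ``articulation_nodes`` are the blob nodes incident to a cut edge of the
    network; an *m*-blob has *m* of them.  ``level`` is the number of hybrid
    nodes inside the blob.
    """

    net: MixedGraph = field(repr=False, compare=False, hash=False)
    nodes: frozenset[str]
    articulation_nodes: frozenset[str]
    hybrids: frozenset[str]
    edge_ids: frozenset[int] = field(compare=False, hash=False)

    @property
    def level(self) -> int:
        return len(self.hybrids)

    @property
    def is_trivial(self) -> bool:
        return len(self.nodes) == 1 and not self.edge_ids

    def subgraph(self) -> MixedGraph:
        g = MixedGraph()
        for v in self.nodes:
            g.add_node(v)
        for eid in self.edge_ids:
            u, v, head = self.net.edge(eid)
            g.add_edge(u, v, head)
        return g


# ---------------------------------------------------------------------------
# circular orders
# ---------------------------------------------------------------------------


class CircularOrder:
    """A circular order of the taxa, up to rotation and reversal."""

    def __init__(self, taxa) -> None:
        seq = tuple(taxa)
        if len(set(seq)) != len(seq):
            raise ValueError("duplicate taxa in circular order")
        self._seq = self._canonical(seq)

    @staticmethod
    def _canonical(seq: tuple[str, ...]) -> tuple[str, ...]:
        n = len(seq)
        if n == 0:
            return seq
        best = None
        for s in (seq, tuple(reversed(seq))):
            for i in range(n):
                cand = s[i:] + s[:i]
                if best is None or cand < best:
                    best = cand
        return best

    @property
    def taxa(self) -> tuple[str, ...]:
        return self._seq

    def __len__(self) -> int:
        return len(self._seq)

    def __iter__(self):
        return iter(self._seq)

    def __getitem__(self, i: int) -> str:
        return self._seq[i % len(self._seq)]

    def index(self, x: str) -> int:
        return self._seq.index(x)

    def __eq__(self, other) -> bool:
        return isinstance(other, CircularOrder) and self._seq == other._seq

    def __hash__(self) -> int:
        return hash(self._seq)

    def __repr__(self) -> str:  # pragma: no cover
        return f"CircularOrder({', '.join(self._seq)})"


# ---------------------------------------------------------------------------
# semi-directed network
# ---------------------------------------------------------------------------


class SemiDirectedNetwork(MixedGraph):
    """A binary semi-directed phylogenetic network.

    Use :meth:`validate` (or the parsers, which call it) to check the
    contract; structural analyses (blobs, classification, circular orders)
    are inherited from / built on :class:`MixedGraph`.
    """

    # -- validation --------------------------------------------------------

    def validate(self, require_partner: bool = True) -> None:
        if not self._adj:
            raise ValidationError("empty network")
        if not self.is_connected():
            raise ValidationError("network is not connected")
        labels = list(self.leaves.values())
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate leaf labels")
        if len(labels) < 2:
            raise ValidationError("need at least two labeled leaves")
        for v in self.nodes:
            deg = self.degree(v)
            ins = self.in_edges(v)
            if v in self.leaves:
                if deg != 1:
                    raise ValidationError(f"leaf {v} has degree {deg}")
                if ins:
                    raise ValidationError(f"leaf {v} is the head of a hybrid edge")
            else:
                if deg != 3:
                    raise ValidationError(f"internal node {v} has degree {deg}")
                if len(ins) not in (0, 2):
                    raise ValidationError(
                        f"node {v} has {len(ins)} incoming hybrid edges"
                    )
        if require_partner and self.find_rooted_partner() is None:
            raise ValidationError("no valid rooted (LSA) partner exists")

    def find_rooted_partner(self):
        """Search for a root placement orienting the network into a valid
        rooted LSA network.

        Tries subdividing each undirected edge with a candidate root and
        propagating forced orientations; returns ``(root_eid, orientation)``
        where ``orientation`` maps each undirected edge id to its head node,
        or ``None`` if no placement works.  Brute force over root edges is
        cheap at the instance sizes this package targets.
        """
        for eid, (u, v, head) in self._edges.items():
            if head is not None:
                continue
            orient = self._try_root(eid)
            if orient is not None:
                return eid, orient
        return None

    def _try_root(self, root_eid: int):
        u0, v0, _ = self._edges[root_eid]
        # heads[eid] = head node for every edge; the root edge is split in two,
        # represented as heads pointing to both endpoints.
        heads: dict[int, str | None] = {}
        for eid, (_, _, h) in self._edges.items():
            heads[eid] = h
        heads[root_eid] = "BOTH"  # both endpoints are children of the root

        hybrids = set(self.hybrid_nodes())
        # forced: undirected edges at a hybrid node point away from it
        for h in hybrids:
            for eid in self._adj[h]:
                if eid == root_eid or heads[eid] is not None:
                    continue
                heads[eid] = self.other_end(eid, h)

        # propagate: a non-hybrid node with an in-edge sends all its other
        # undirected edges outward
        def in_count(v):
            c = 0
            for eid in self._adj[v]:
                if heads[eid] == v:
                    c += 1
                elif heads[eid] == "BOTH":
                    c += 1
            return c

        queue = [u0, v0]
        reached = set()
        while queue:
            v = queue.pop()
            if v in reached:
                continue
            reached.add(v)
            if v in hybrids:
                # children reached via already-oriented out-edges
                for eid in self._adj[v]:
                    if heads[eid] not in (v, "BOTH") and heads[eid] is not None:
                        queue.append(heads[eid])
                continue
            if in_count(v) > 1:
                return None
            for eid in self._adj[v]:
                h = heads[eid]
                if h == v or h == "BOTH":
                    continue
                w = self.other_end(eid, v)
                if h is None:
                    heads[eid] = w
                queue.append(w)

        if any(h is None for h in heads.values()):
            return None  # orientation stalled: no valid rooted partner here
        # verify degrees, acyclicity, reachability, LSA on the rooted digraph
        dg = nx.MultiDiGraph()
        dg.add_node("__root__")
        dg.add_nodes_from(self._adj)
        for eid, (a, b, _) in self._edges.items():
            h = heads[eid]
            if h == "BOTH":
                dg.add_edge("__root__", a)
                dg.add_edge("__root__", b)
            else:
                dg.add_edge(a if h == b else b, h)
        if not nx.is_directed_acyclic_graph(dg):
            return None
        for v in self._adj:
            ind, outd = dg.in_degree(v), dg.out_degree(v)
            if v in self.leaves:
                ok = ind == 1 and outd == 0
            elif v in hybrids:
                ok = ind == 2 and outd == 1
            else:
                ok = ind == 1 and outd == 2
            if not ok:
                return None
        # all nodes reachable from the root
        if len(nx.descendants(dg, "__root__")) != len(self._adj):
            return None
        # root must be the least stable ancestor of X: no other node lies on
        # every root-to-leaf path
        leaves = set(self.leaves)
        for v in self._adj:
            if v in leaves:
                continue
            dg2 = dg.copy()
            dg2.remove_node(v)
            if not any(nx.has_path(dg2, "__root__", leaf) for leaf in leaves):
                return None  # v is a stable ancestor below the root
        return {eid: h for eid, h in heads.items()}

    # -- classification ----------------------------------------------------

    def is_galled(self) -> bool:
        """Every pair of partner hybrid edges lies on a cycle containing no
        other hybrid edge of the network."""
        for h in self.hybrid_nodes():
            e1, e2 = self.in_edges(h)
            p1 = self.other_end(e1, h)
            p2 = self.other_end(e2, h)
            # path between the parents avoiding h and all other hybrid edges
            g = nx.MultiGraph()
            g.add_nodes_from(self._adj)
            for eid, u, v, head in self.edges():
                if eid in (e1, e2):
                    continue
                if head is not None:
                    continue
                g.add_edge(u, v)
            g.remove_node(h)
            if not (g.has_node(p1) and g.has_node(p2) and nx.has_path(g, p1, p2)):
                return False
        return True

    def is_outer_labeled_planar(self) -> bool:
        """Planarity of the network plus an apex vertex joined to every leaf."""
        g = self.to_simple_graph()
        apex = "__apex__"
        for v in self.leaves:
            g.add_edge(apex, v)
        ok, _ = nx.check_planarity(g)
        return ok

    def cycle_lengths(self) -> set[int]:
        g = self.to_multigraph()
        return {len(c) for c in nx.simple_cycles(g)}

    def classify(self) -> "ClassReport":
        blobs = self.blobs()
        level = max((b.level for b in blobs), default=0)
        strictly = level > 0 and any(b.level == level for b in blobs)
        nonleaf = [b for b in blobs if len(b.nodes) > 1]
        bloblet = len(nonleaf) == 1 and all(
            len(b.nodes) > 1 or next(iter(b.nodes)) in self.leaves
            for b in blobs
        )
        return ClassReport(
            level=level,
            strictly_level=level if strictly else 0,
            galled=self.is_galled(),
            outer_labeled_planar=self.is_outer_labeled_planar(),
            bloblet=bloblet,
            cycle_lengths=frozenset(self.cycle_lengths()),
            hybrid_count=len(self.hybrid_nodes()),
        )

    # -- tree of blobs -----------------------------------------------------

    def tree_of_blobs(self):
        """Contract every blob to a node; returns an unrooted tree on X."""
        from .displayed import PhyloTree

        blobs = self.blobs()
        owner = {}
        for i, b in enumerate(blobs):
            for v in b.nodes:
                owner[v] = i
        t = PhyloTree()
        for i, b in enumerate(blobs):
            node = f"B{i}"
            t.add_node(node)
            lab = [self.leaves[v] for v in b.nodes if v in self.leaves]
            if lab:
                if len(lab) > 1:
                    raise ValidationError("blob contains more than one leaf")
                t.leaves[node] = lab[0]
        bridges = self.bridges()
        for eid in bridges:
            u, v, _ = self.edge(eid)
            t.add_edge(f"B{owner[u]}", f"B{owner[v]}")
        t.suppress_degree2()
        return t

    # -- circular orders ---------------------------------------------------

    def _blob_attachment_order(self, blob: Blob, attach_edges: list[int]):
        """Cyclic order of the given cut edges around the blob in an
        outer-labeled planar embedding (unique up to reflection for blobs
        with >= 4 attachments)."""
        if len(blob.nodes) == 1:
            return list(attach_edges)
        g = nx.Graph()
        g.add_nodes_from(blob.nodes)
        for eid in blob.edge_ids:
            u, v, _ = self.edge(eid)
            g.add_edge(u, v)
        apex = ("__apex__",)
        for eid in attach_edges:
            u, v, _ = self.edge(eid)
            inside = u if u in blob.nodes else v
            stub = ("__stub__", eid)
            g.add_edge(inside, stub)
            g.add_edge(apex, stub)
        ok, emb = nx.check_planarity(g)
        if not ok:
            raise ClassMembershipError("blob is not outer-labeled planar")
        order = []
        for nbr in emb.neighbors_cw_order(apex):
            order.append(nbr[1])
        return order

    def induced_circular_orders(self) -> set[CircularOrder]:
        """All circular orders of X realizable by an outer-labeled planar
        embedding.  Exactly one for bloblets."""
        if not self.is_outer_labeled_planar():
            raise ClassMembershipError("network is not outer-labeled planar")
        labels = sorted(self.taxa)
        if len(labels) <= 3:
            return {CircularOrder(labels)}
        blobs = self.blobs()
        owner = {}
        for i, b in enumerate(blobs):
            for v in b.nodes:
                owner[v] = i
        bridges = sorted(self.bridges())
        # bridge adjacency per blob
        blob_bridges: dict[int, list[int]] = {i: [] for i in range(len(blobs))}
        for eid in bridges:
            u, v, _ = self.edge(eid)
            blob_bridges[owner[u]].append(eid)
            if owner[v] != owner[u]:
                blob_bridges[owner[v]].append(eid)

        def expand(blob_idx: int, in_eid: int) -> list[list[str]]:
            b = blobs[blob_idx]
            if len(b.nodes) == 1 and next(iter(b.nodes)) in self.leaves:
                return [[self.leaves[next(iter(b.nodes))]]]
            attach = blob_bridges[blob_idx]
            cyc = self._blob_attachment_order(b, attach)
            i = cyc.index(in_eid)
            rest_fwd = cyc[i + 1 :] + cyc[:i]
            variants = [rest_fwd, list(reversed(rest_fwd))]
            out: list[list[str]] = []
            seen = set()
            for rest in variants:
                key = tuple(rest)
                if key in seen:
                    continue
                seen.add(key)
                child_seqs = []
                for eid in rest:
                    u, v, _ = self.edge(eid)
                    nxt = owner[v] if owner[u] == blob_idx else owner[u]
                    # bridge may connect blob to itself only in degenerate cases
                    child_seqs.append(expand(nxt, eid))
                for combo in itertools.product(*child_seqs):
                    out.append([x for seq in combo for x in seq])
            return out

        x0 = self.leaf_of(labels[0])
        e0 = self._adj[x0][0]
        start = owner[self.other_end(e0, x0)]
        orders = set()
        for seq in expand(start, e0):
            orders.add(CircularOrder([labels[0]] + seq))
        return orders


@dataclass(frozen=True)
class ClassReport:
    """Structural classification of a semi-directed network."""

    level: int
    strictly_level: int
    galled: bool
    outer_labeled_planar: bool
    bloblet: bool
    cycle_lengths: frozenset[int]
    hybrid_count: int

    def k_cycle_free(self, k: int) -> bool:
        return k not in self.cycle_lengths


# ---------------------------------------------------------------------------
# isomorphism
# ---------------------------------------------------------------------------


def are_isomorphic(
    n1: MixedGraph,
    n2: MixedGraph,
    mode: str = "labeled",
    witness: bool = False,
):
    """Mixed-multigraph isomorphism.

    Respects hybrid-edge orientation, parallel-edge multiplicity and, in
    ``labeled`` mode, leaf labels.  In ``up_to_relabeling`` mode leaves only
    have to map to leaves.  Returns a bool, or ``(bool, mapping)`` when
    ``witness`` is requested.
    """
    if mode not in ("labeled", "up_to_relabeling"):
        raise ValueError(f"unknown mode {mode!r}")
    labeled = mode == "labeled"
    if labeled and n1.taxa != n2.taxa:
        return (False, None) if witness else False
    g1 = n1._iso_digraph(labeled)
    g2 = n2._iso_digraph(labeled)
    nm = nx.isomorphism.categorical_node_match("tag", "")
    em = nx.isomorphism.categorical_multiedge_match("kind", "u")
    gm = nx.isomorphism.MultiDiGraphMatcher(g1, g2, node_match=nm, edge_match=em)
    ok = gm.is_isomorphic()
    if witness:
        return ok, (dict(gm.mapping) if ok else None)
    return ok


# ---------------------------------------------------------------------------
# parsing / writing
# ---------------------------------------------------------------------------


def parse_network(text: str, dialect: str = "edgelist") -> SemiDirectedNetwork:
    """Parse a semi-directed network from text.

    ``dialect`` is ``"edgelist"`` (``u -- v`` undirected, ``u -> v`` hybrid,
    ``leaf u LABEL`` declarations, ``#`` comments) or ``"enewick"`` (the
    rooted partner in extended Newick; the root is suppressed).
    """
    if dialect == "edgelist":
        return parse_edgelist(text)
    if dialect == "enewick":
        return parse_enewick(text)
    raise ValueError(f"unknown dialect {dialect!r}")


def parse_edgelist(text: str) -> SemiDirectedNetwork:
    net = SemiDirectedNetwork()
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if parts[0] == "leaf":
            if len(parts) != 3:
                raise ParseError(f"line {lineno}: expected 'leaf NODE LABEL'")
            net.add_leaf(parts[1], parts[2])
        elif len(parts) == 3 and parts[1] == "--":
            net.add_edge(parts[0], parts[2])
        elif len(parts) == 3 and parts[1] == "->":
            net.add_edge(parts[0], parts[2], head=parts[2])
        else:
            raise ParseError(f"line {lineno}: cannot parse {raw!r}")
    net.validate()
    return net


def write_edgelist(net: MixedGraph) -> str:
    lines = []
    for v in sorted(net.leaves):
        lines.append(f"leaf {v} {net.leaves[v]}")
    for eid in sorted(net.edge_ids):
        u, v, head = net.edge(eid)
        if head is None:
            lines.append(f"{u} -- {v}")
        else:
            tail = u if head == v else v
            lines.append(f"{tail} -> {head}")
    return "\n".join(lines) + "\n"


def _tokenize_newick(text: str):
    text = text.strip()
    if text.endswith(";"):
        text = text[:-1]
    tokens = []
    i = 0
    while i < len(text):
        c = text[i]
        if c in "(),:":
            tokens.append(c)
            i += 1
        elif c.isspace():
            i += 1
        else:
            j = i
            while j < len(text) and text[j] not in "(),:" and not text[j].isspace():
                j += 1
            tokens.append(text[i:j])
            i = j
    return tokens


def parse_enewick(text: str) -> SemiDirectedNetwork:
    """Parse the rooted partner from extended Newick and unroot it.

    Hybrid nodes are written with ``#H`` tags (e.g. ``h#H1``); occurrences
    with the same tag are merged into a single node.
    """
    tokens = _tokenize_newick(text)
    if not tokens:
        raise ParseError("empty eNewick string")
    dg = nx.DiGraph()
    counter = itertools.count()
    hybrid_ids: dict[str, str] = {}
    names: dict[str, str] = {}

    def node_for(name: str) -> str:
        if "#" in name:
            base, tag = name.split("#", 1)
            if tag not in hybrid_ids:
                hybrid_ids[tag] = f"#{tag}"
                dg.add_node(hybrid_ids[tag])
            if base:
                names[hybrid_ids[tag]] = base
            return hybrid_ids[tag]
        v = f"v{next(counter)}"
        dg.add_node(v)
        if name:
            names[v] = name
        return v

    pos = 0

    def parse_clade() -> str:
        nonlocal pos
        children = []
        if pos < len(tokens) and tokens[pos] == "(":
            pos += 1
            while True:
                children.append(parse_clade())
                if pos >= len(tokens):
                    raise ParseError("unbalanced parentheses")
                if tokens[pos] == ",":
                    pos += 1
                    continue
                if tokens[pos] == ")":
                    pos += 1
                    break
                raise ParseError(f"unexpected token {tokens[pos]!r}")
        name = ""
        if pos < len(tokens) and tokens[pos] not in "(),:":
            name = tokens[pos]
            pos += 1
        if pos < len(tokens) and tokens[pos] == ":":
            pos += 2  # skip branch length
        v = node_for(name)
        for c in children:
            dg.add_edge(v, c)
        return v

    root = parse_clade()
    if pos != len(tokens):
        raise ParseError("trailing tokens in eNewick string")

    # rooted-network sanity
    if not nx.is_directed_acyclic_graph(dg):
        raise ParseError("eNewick encodes a directed cycle")
    net = SemiDirectedNetwork()
    for v in dg.nodes:
        if dg.out_degree(v) == 0:
            if v not in names:
                raise ParseError(f"unlabeled leaf node {v}")
            net.add_leaf(v, names[v])
        else:
            net.add_node(v)
    for u, v in dg.edges:
        head = v if dg.in_degree(v) == 2 else None
        net.add_edge(u, v, head=head)
    # suppress the root
    if dg.out_degree(root) != 2:
        raise ParseError("root must have out-degree 2")
    (e1, e2) = net.incident(root)
    u = net.other_end(e1, root)
    w = net.other_end(e2, root)
    h1 = net.edge(e1)[2]
    h2 = net.edge(e2)[2]
    net.remove_node(root)
    if h1 == u and h2 == w:
        raise ParseError("both root edges are hybrid edges")
    head = u if h1 == u else (w if h2 == w else None)
    net.add_edge(u, w, head=head)
    net.refresh_hybrid_status()
    net.suppress_degree2()
    net.validate()
    return net


def write_enewick(net: SemiDirectedNetwork) -> str:
    """Write some rooted partner of the network in extended Newick."""
    partner = net.find_rooted_partner()
    if partner is None:
        raise ValidationError("network has no rooted partner")
    root_eid, heads = partner
    children: dict[str, list[str]] = {v: [] for v in net.nodes}
    children["__root__"] = []
    for eid, (u, v, _) in net._edges.items():
        h = heads[eid]
        if h == "BOTH":
            children["__root__"] += [u, v]
        else:
            tail = u if h == v else v
            children[tail].append(h)
    hybrids = set(net.hybrid_nodes())
    tag = {h: f"H{i+1}" for i, h in enumerate(sorted(hybrids))}
    seen: set[str] = set()

    def emit(v: str) -> str:
        if v in hybrids:
            if v in seen:
                return f"#{tag[v]}"
            seen.add(v)
            inner = ",".join(emit(c) for c in children[v])
            return f"({inner})#{tag[v]}" if inner else f"#{tag[v]}"
        if v in net.leaves:
            return net.leaves[v]
        return "(" + ",".join(emit(c) for c in children[v]) + ")"

    return emit("__root__") + ";"
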