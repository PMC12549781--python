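"""Splits, weighted split systems, and circular (Kalmanson) decomposition.

A split ``A|B`` is an unordered bipartition of the taxon set.  A circular
order of the taxa defines the split system ``S(C)`` of all splits whose
blocks are arcs of the circle; a metric is circular decomposable exactly
when all Chepoi–Fichet split weights

    alpha_ij = d(x_i, x_j) + d(x_{i+1}, x_{j+1}) - d(x_i, x_{j+1}) - d(x_{i+1}, x_j)

are nonnegative, in which case ``d = sum alpha_ij/2 * delta_{S_ij}`` and the
support of the decomposition is ``{S_ij : alpha_ij > 0}``.  All arithmetic
here is exact (``fractions.Fraction``); there are no epsilon comparisons.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Iterable

from .network import CircularOrder

__all__ = [
    "Split",
    "DistanceTable",
    "WeightedSplitSystem",
    "split_Sij",
    "all_circular_splits",
    "split_metric_value",
    "metric_from_weighted_splits",
    "split_weights",
    "circular_decompose",
    "DecompositionFailure",
]


class Split:
    """An unordered bipartition ``A|B`` of a taxon set."""

    __slots__ = ("_blocks",)

    def __init__(self, block_a: Iterable[str], block_b: Iterable[str]):
        a = frozenset(block_a)
        b = frozenset(block_b)
        if not a or not b:
            raise ValueError("split blocks must be nonempty")
        if a & b:
            raise ValueError("split blocks must be disjoint")
        self._blocks = frozenset((a, b))

    @property
    def blocks(self) -> tuple[frozenset[str], frozenset[str]]:
        # canonical side ordering: lexicographically least block first
        a, b = sorted(self._blocks, key=lambda s: (len(s), sorted(s)))
        return a, b

    @property
    def taxa(self) -> frozenset[str]:
        a, b = self._blocks
        return a | b

    def is_trivial(self) -> bool:
        return any(len(s) == 1 for s in self._blocks)

    def separates(self, x: str, y: str) -> bool:
        """The split metric delta_S(x, y): 1 iff x and y are in different blocks."""
        a, _ = self.blocks
        return (x in a) != (y in a)

    def side_of(self, x: str) -> frozenset[str]:
        for s in self._blocks:
            if x in s:
                return s
        raise KeyError(x)

    def restrict(self, taxa: Iterable[str]) -> "Split | None":
        """Restriction to a subset; ``None`` if it becomes empty on a side."""
        t = frozenset(taxa)
        a, b = self._blocks
        a, b = a & t, b & t
        if not a or not b:
            return None
        return Split(a, b)

    def __eq__(self, other) -> bool:
        return isinstance(other, Split) and self._blocks == other._blocks

    def __hash__(self) -> int:
        return hash(self._blocks)

    def __repr__(self) -> str:
        a, b = self.blocks
        return "{%s}|{%s}" % (",".join(sorted(a)), ",".join(sorted(b)))


class DistanceTable:
    """Symmetric exact-rational distance table with zero diagonal."""

    def __init__(self, taxa: Iterable[str]):
        self.taxa = tuple(taxa)
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxa")
        self._d: dict[frozenset[str], Fraction] = {}

    def set(self, x: str, y: str, value) -> None:
        if x == y:
            if value != 0:
                raise ValueError("diagonal must be zero")
            return
        self._d[frozenset((x, y))] = Fraction(value)

    def get(self, x: str, y: str) -> Fraction:
        if x == y:
            return Fraction(0)
        return self._d[frozenset((x, y))]

    def __call__(self, x: str, y: str) -> Fraction:
        return self.get(x, y)

    def pairs(self):
        for i, x in enumerate(self.taxa):
            for y in self.taxa[i + 1 :]:
                yield x, y

    def matrix(self) -> list[list[Fraction]]:
        return [[self.get(x, y) for y in self.taxa] for x in self.taxa]

    def is_metric(self) -> bool:
        """Symmetry and zero diagonal hold by construction; checks
        nonnegativity and the triangle inequality."""
        if any(v < 0 for v in self._d.values()):
            return False
        for x in self.taxa:
            for y in self.taxa:
                for z in self.taxa:
                    if self.get(x, y) + self.get(y, z) < self.get(x, z):
                        return False
        return True

    def __eq__(self, other) -> bool:
        if not isinstance(other, DistanceTable):
            return NotImplemented
        if set(self.taxa) != set(other.taxa):
            return False
        return all(self.get(x, y) == other.get(x, y) for x, y in self.pairs())

    def __hash__(self):
        return hash((frozenset(self.taxa), frozenset(self._d.items())))

    def __sub__(self, other: "DistanceTable") -> "DistanceTable":
        out = DistanceTable(self.taxa)
        for x, y in self.pairs():
            out.set(x, y, self.get(x, y) - other.get(x, y))
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return f"<DistanceTable on {len(self.taxa)} taxa>"


class WeightedSplitSystem:
    """Map from splits to nonnegative rational weights."""

    def __init__(self, weights: dict[Split, Fraction] | None = None):
        self.weights: dict[Split, Fraction] = {}
        for s, w in (weights or {}).items():
            w = Fraction(w)
            if w < 0:
                raise ValueError("split weights must be nonnegative")
            if w > 0:
                self.weights[s] = w

    @property
    def support(self) -> frozenset[Split]:
        return frozenset(self.weights)

    def weight(self, s: Split) -> Fraction:
        return self.weights.get(s, Fraction(0))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, WeightedSplitSystem) and self.weights == other.weights
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"<WeightedSplitSystem with {len(self.weights)} splits>"


def split_Sij(order: CircularOrder, i: int, j: int) -> Split:
    """The split ``S_ij = U_ij | V_ij`` with ``U_ij = {x_{i+1}, ..., x_j}``
    (indices mod n).  ``S_ij == S_ji``."""
    n = len(order)
    if i % n == j % n:
        raise ValueError("S_ij requires i != j (mod n)")
    u = []
    k = (i + 1) % n
    while True:
        u.append(order[k])
        if k == j % n:
            break
        k = (k + 1) % n
    v = [x for x in order if x not in u]
    return Split(u, v)


def all_circular_splits(order: CircularOrder) -> set[Split]:
    """The full circular split system S(C) (trivial splits included)."""
    n = len(order)
    return {split_Sij(order, i, j) for i in range(n) for j in range(i + 1, n)}


def split_metric_value(s: Split, x: str, y: str) -> int:
    return 1 if s.separates(x, y) else 0


def metric_from_weighted_splits(ws: WeightedSplitSystem, taxa=None) -> DistanceTable:
    """d_omega(x, y) = sum_S omega(S) * delta_S(x, y)."""
    if taxa is None:
        all_taxa: set[str] = set()
        for s in ws.weights:
            all_taxa |= s.taxa
        taxa = sorted(all_taxa)
    table = DistanceTable(taxa)
    for x, y in table.pairs():
        table.set(
            x, y, sum((w for s, w in ws.weights.items() if s.separates(x, y)), Fraction(0))
        )
    return table


def split_weights(d: DistanceTable, order: CircularOrder) -> dict[tuple[int, int], Fraction]:
    """Chepoi–Fichet split weights alpha_ij for all S_ij in S(C), indexed by
    ordered ``(i, j)`` with ``i < j`` (each split once)."""
    if set(order.taxa) != set(d.taxa):
        raise ValueError("order and distance table are on different taxa")
    n = len(order)
    alpha: dict[tuple[int, int], Fraction] = {}
    for i in range(n):
        for j in range(i + 1, n):
            alpha[(i, j)] = (
                d.get(order[i], order[j])
                + d.get(order[i + 1], order[j + 1])
                - d.get(order[i], order[j + 1])
                - d.get(order[i + 1], order[j])
            )
    return alpha


class DecompositionFailure:
    """Returned when a metric is not Kalmanson for the given order."""

    def __init__(self, order: CircularOrder, violations):
        self.order = order
        self.violations = violations  # list of ((i, j), alpha_ij < 0)

    def __bool__(self) -> bool:
        return False

    def __repr__(self) -> str:  # pragma: no cover
        return f"<DecompositionFailure at {self.violations}>"


def circular_decompose(d: DistanceTable, order: CircularOrder):
    """Decompose ``d`` over the circular split system of ``order``.

    Returns a :class:`WeightedSplitSystem` with weights ``alpha_ij / 2`` if
    all split weights are nonnegative, else a :class:`DecompositionFailure`
    listing the violated splits.  By the Chepoi–Fichet identity the
    reconstruction is exact whenever it succeeds.
    """
    alpha = split_weights(d, order)
    bad = [(ij, a) for ij, a in alpha.items() if a < 0]
    if bad:
        return DecompositionFailure(order, bad)
    weights: dict[Split, Fraction] = {}
    for (i, j), a in alpha.items():
        if a > 0:
            weights[split_Sij(order, i, j)] = a / 2
    return WeightedSplitSystem(weights)
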