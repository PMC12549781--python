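"""Writers for the standard text formats: PHYLIP square matrices, TSV with
exact rationals, NEXUS splits blocks (SplitsTree-compatible), and DOT."""

from __future__ import annotations

from fractions import Fraction

from .network import CircularOrder, MixedGraph
from .splits import DistanceTable, WeightedSplitSystem

__all__ = [
    "format_rational",
    "phylip_matrix",
    "tsv_matrix",
    "nexus_splits",
    "dot_graph",
    "displayed_trees_tsv",
]


def format_rational(x: Fraction, decimal: bool = True) -> str:
    """Exact rendering: a terminating decimal when the denominator is a
    product of 2s and 5s, else ``p/q``."""
    x = Fraction(x)
    if x.denominator == 1:
        return str(x.numerator)
    if decimal:
        den = x.denominator
        while den % 2 == 0:
            den //= 2
        while den % 5 == 0:
            den //= 5
        if den == 1:
            return str(float(x)) if x.denominator <= 1 << 52 else f"{x.numerator}/{x.denominator}"
    return f"{x.numerator}/{x.denominator}"


def phylip_matrix(d: DistanceTable) -> str:
    lines = [f"{len(d.taxa)}"]
    for x in d.taxa:
        row = " ".join(format_rational(d.get(x, y)) for y in d.taxa)
        lines.append(f"{x}  {row}")
    return "\n".join(lines) + "\n"


def tsv_matrix(d: DistanceTable) -> str:
    lines = ["\t".join([""] + list(d.taxa))]
    for x in d.taxa:
        lines.append(
            "\t".join([x] + [format_rational(d.get(x, y), decimal=False)
                             for y in d.taxa])
        )
    return "\n".join(lines) + "\n"


def nexus_splits(ws: WeightedSplitSystem, order: CircularOrder) -> str:
    """NEXUS file with taxa block and a SplitsTree splits block (weights as
    decimals; the cycle records the circular order)."""
    taxa = list(order)
    idx = {t: i + 1 for i, t in enumerate(taxa)}
    lines = [
        "#NEXUS",
        "",
        "BEGIN Taxa;",
        f"DIMENSIONS ntax={len(taxa)};",
        "TAXLABELS",
    ]
    lines += [f"[{i+1}] '{t}'" for i, t in enumerate(taxa)]
    lines += [";", "END;", "", "BEGIN Splits;"]
    lines.append(
        f"DIMENSIONS ntax={len(taxa)} nsplits={len(ws.weights)};"
    )
    lines.append("FORMAT labels=no weights=yes confidences=no intervals=no;")
    lines.append("CYCLE " + " ".join(str(idx[t]) for t in taxa) + ";")
    lines.append("MATRIX")
    splits = sorted(ws.weights.items(),
                    key=lambda sw: sorted(sorted(b) for b in sw[0].blocks))
    for i, (s, w) in enumerate(splits, start=1):
        a, _ = s.blocks
        members = " ".join(str(idx[t]) for t in sorted(a, key=lambda t: idx[t]))
        lines.append(f"[{i}] {float(w)} {members},")
    lines += [";", "END;", ""]
    return "\n".join(lines)


def dot_graph(net: MixedGraph, name: str = "N") -> str:
    lines = [f"graph {name} {{"]
    for v in sorted(net.nodes):
        if v in net.leaves:
            lines.append(f'  "{v}" [label="{net.leaves[v]}", shape=none];')
        else:
            lines.append(f'  "{v}" [label="", shape=point];')
    for eid in sorted(net.edge_ids):
        u, v, head = net.edge(eid)
        if head is None:
            lines.append(f'  "{u}" -- "{v}";')
        else:
            tail = u if head == v else v
            lines.append(f'  "{tail}" -- "{head}" [dir=forward, color=red];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def displayed_trees_tsv(multiset) -> str:
    lines = ["newick\tmultiplicity"]
    rows = sorted(
        ((t.newick(), m) for t, m in multiset.items()),
        key=lambda r: r[0],
    )
    for nwk, m in rows:
        lines.append(f"{nwk}\t{m}")
    return "\n".join(lines) + "\n"
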