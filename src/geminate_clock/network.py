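"""Haplotype collapsing and minimum-spanning haplotype networks.

Sequences are collapsed to haplotypes by strict string identity (after
the ingestion normalization); ambiguity codes are *not* merged into
compatible haplotypes, unlike some network tools, so the collapse is
order-independent and reproducible. Haplotypes are labelled with Roman
numerals in order of first occurrence and connected by a minimum
spanning tree whose edge weights are mutational steps (differing
unambiguous sites).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from ._tn93 import encode
from .alignment import Alignment, GroupPartition
from .errors import AlignmentError, DistanceError

__all__ = [
    "Haplotype",
    "HaplotypeNetwork",
    "collapse_haplotypes",
    "mutational_steps",
    "build_msn",
    "write_network",
    "plot_network",
]

_ROMAN = (
    (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"), (90, "XC"),
    (50, "L"), (40, "XL"), (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
)


def roman(n: int) -> str:
    if n <= 0:
        raise ValueError("roman numerals start at 1")
    out = []
    for value, symbol in _ROMAN:
        while n >= value:
            out.append(symbol)
            n -= value
    return "".join(out)


@dataclass(frozen=True)
class Haplotype:
    """A unique sequence variant and the samples carrying it."""

    haplotype_id: str
    representative: str
    members: tuple[str, ...]

    @property
    def frequency(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class HaplotypeNetwork:
    """Haplotypes plus minimum-spanning edges weighted in mutational steps.

    ``alternative_edges`` (present only when requested) are co-minimal
    links: non-tree pairs whose step count equals the largest edge
    weight on the tree path between them, i.e. edges that could swap
    into an equally minimal spanning tree.
    """

    nodes: tuple[Haplotype, ...]
    edges: tuple[tuple[str, str, int], ...]
    annotations: Mapping[str, str] = field(default_factory=dict)
    alternative_edges: tuple[tuple[str, str, int], ...] = ()

    @property
    def total_steps(self) -> int:
        return sum(s for _, _, s in self.edges)


def collapse_haplotypes(aln: Alignment) -> list[Haplotype]:
    """Group identical sequences; label I, II, ... by first occurrence."""
    if len(aln) == 0:
        raise AlignmentError("empty alignment")
    groups: dict[str, list[str]] = {}
    for rec in aln.records:
        groups.setdefault(rec.residues, []).append(rec.sample_id)
    return [
        Haplotype(roman(i + 1), seq, tuple(members))
        for i, (seq, members) in enumerate(groups.items())
    ]


def mutational_steps(a: str, b: str) -> int:
    """Number of sites where both residues are unambiguous bases and differ."""
    if len(a) != len(b):
        raise DistanceError(f"sequence lengths differ: {len(a)} vs {len(b)}")
    ca, cb = encode(a), encode(b)
    return int(np.count_nonzero((ca < 4) & (cb < 4) & (ca != cb)))


def build_msn(
    haps: Sequence[Haplotype],
    annotations: Mapping[str, str] | None = None,
    include_alternatives: bool = False,
) -> HaplotypeNetwork:
    """Minimum spanning tree over the complete mutational-step graph.

    Kruskal on edges pre-sorted by (steps, label pair) so that ties are
    broken lexicographically and the result is deterministic.
    ``include_alternatives`` additionally reports co-minimal links
    without changing the spanning-tree edge set.
    """
    if not haps:
        raise AlignmentError("no haplotypes")
    g = nx.Graph()
    for h in haps:
        g.add_node(h.haplotype_id)
    labelled = sorted(haps, key=lambda h: h.haplotype_id)
    edges = []
    for i, hi in enumerate(labelled):
        for hj in labelled[i + 1 :]:
            steps = mutational_steps(hi.representative, hj.representative)
            edges.append((steps, hi.haplotype_id, hj.haplotype_id))
    for steps, a, b in sorted(edges):
        g.add_edge(a, b, weight=steps)
    mst = nx.minimum_spanning_tree(g, algorithm="kruskal")
    out_edges = tuple(
        sorted((min(a, b), max(a, b), int(d["weight"])) for a, b, d in mst.edges(data=True))
    )
    alternatives: tuple[tuple[str, str, int], ...] = ()
    if include_alternatives and len(haps) > 1:
        in_tree = {(a, b) for a, b, _ in out_edges}
        alts = []
        for steps, a, b in edges:
            if (min(a, b), max(a, b)) in in_tree:
                continue
            path = nx.shortest_path(mst, a, b)
            bottleneck = max(
                mst[u][v]["weight"] for u, v in zip(path[:-1], path[1:])
            )
            if steps == bottleneck:  # swapping it in gives an equal-weight tree
                alts.append((min(a, b), max(a, b), int(steps)))
        alternatives = tuple(sorted(alts))
    return HaplotypeNetwork(
        tuple(haps), out_edges, dict(annotations or {}), alternatives
    )


def annotate_by_group(haps: Sequence[Haplotype], part: GroupPartition) -> dict[str, str]:
    """Haplotype -> group label of its members (joined if mixed)."""
    ann = {}
    for h in haps:
        groups = sorted({part.group(m) for m in h.members if m in part})
        ann[h.haplotype_id] = "+".join(groups) if groups else ""
    return ann


def write_network(net: HaplotypeNetwork, node_path: str | Path, edge_path: str | Path) -> None:
    """Serialize as TSV node and edge tables."""
    with open(node_path, "w") as fh:
        fh.write("haplotype_id\tfrequency\tmembers\tgroup\n")
        for h in net.nodes:
            group = net.annotations.get(h.haplotype_id, "")
            fh.write(f"{h.haplotype_id}\t{h.frequency}\t{','.join(h.members)}\t{group}\n")
    with open(edge_path, "w") as fh:
        fh.write("from\tto\tsteps\n")
        for a, b, steps in net.edges:
            fh.write(f"{a}\t{b}\t{steps}\n")


def plot_network(net: HaplotypeNetwork, path: str | Path) -> None:
    """Cosmetic spring-layout plot; node area scales with frequency."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = nx.Graph()
    for h in net.nodes:
        g.add_node(h.haplotype_id, frequency=h.frequency)
    for a, b, steps in net.edges:
        g.add_edge(a, b, weight=steps)
    pos = nx.spring_layout(g, seed=0, weight="weight")
    groups = sorted({net.annotations.get(h.haplotype_id, "") for h in net.nodes})
    cmap = plt.get_cmap("tab10")
    color_of = {grp: cmap(i % 10) for i, grp in enumerate(groups)}
    fig, ax = plt.subplots(figsize=(6, 6))
    sizes = [120 * h.frequency for h in net.nodes]
    colors = [color_of[net.annotations.get(h.haplotype_id, "")] for h in net.nodes]
    nx.draw_networkx(
        g, pos, ax=ax, node_size=sizes, node_color=colors, with_labels=True, font_size=8
    )
    labels = {(a, b): s for a, b, s in net.edges}
    nx.draw_networkx_edge_labels(g, pos, edge_labels=labels, ax=ax, font_size=7)
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
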