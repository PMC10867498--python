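"""Tree plumbing: Newick I/O, neighbor joining, rooting.

Trees are carried as :class:`dendropy.Tree` objects throughout the
package. Neighbor joining (used only to supply a fixed topology for
the clock test) is delegated to scikit-bio; negative NJ branch lengths
are clamped to zero.
"""

from __future__ import annotations

import io
from pathlib import Path

import dendropy
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import nj as _skbio_nj

from .distances import DistanceMatrix
from .errors import TreeError

__all__ = ["parse_newick", "to_newick", "read_newick", "nj_tree", "root_tree", "leaf_labels"]


def parse_newick(newick: str) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    except Exception as exc:
        raise TreeError(f"unparseable Newick: {exc}") from exc


def read_newick(path: str | Path) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise TreeError(f"{path}: unparseable Newick: {exc}") from exc


def to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining topology with branch lengths (clamped >= 0)."""
    if len(dm) < 3:
        raise TreeError(f"neighbor joining needs >= 3 taxa, got {len(dm)}")
    sk = _SkbioDM(dm.d.copy(), ids=list(dm.ids))
    tree = _skbio_nj(sk)
    buf = io.StringIO()
    tree.write(buf, format="newick")
    out = parse_newick(buf.getvalue())
    for edge in out.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    return out


def root_tree(tree: dendropy.Tree, outgroup: str | None = None) -> dendropy.Tree:
    """Rooted copy: on the outgroup's edge if named, else at the midpoint."""
    rooted = tree.clone(depth=1)
    for edge in rooted.preorder_edge_iter():
        if edge.tail_node is not None and edge.length is None:
            edge.length = 0.0
    if outgroup is not None:
        node = rooted.find_node_with_taxon_label(outgroup)
        if node is None:
            raise TreeError(f"outgroup {outgroup!r} not found among leaves")
        length = node.edge.length or 0.0
        rooted.reroot_at_edge(node.edge, length1=length / 2.0, length2=length / 2.0)
    else:
        total = sum(
            e.length or 0.0
            for e in rooted.preorder_edge_iter()
            if e.tail_node is not None
        )
        if total > 0:
            rooted.reroot_at_midpoint()
        else:  # star of zero-length branches; any edge will do as root
            child = rooted.seed_node.child_nodes()[0]
            rooted.reroot_at_edge(child.edge, length1=0.0, length2=0.0)
    rooted.is_rooted = True
    return rooted
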