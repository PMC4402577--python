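"""Rooted-tree data model shared by guide-tree construction and Newick I/O.

Trees are lightweight node objects: leaves carry sequence ids, internal
nodes carry children. Branch lengths and UPGMA node heights are optional.
Newick parsing is delegated to :mod:`dendropy`; serialization is direct.
"""

from __future__ import annotations

import io
from typing import Iterator, Optional

import dendropy

__all__ = ["TreeNode", "GuideTree", "parse_newick", "format_newick"]


class TreeNode:
    """A node of a rooted tree.

    Parameters
    ----------
    name:
        Leaf label (``None`` for internal nodes).
    length:
        Branch length to the parent, if known.
    children:
        Child nodes, in order.
    height:
        Optional ultrametric node height (set by UPGMA).
    """

    __slots__ = ("name", "length", "children", "height")

    def __init__(
        self,
        name: Optional[str] = None,
        length: Optional[float] = None,
        children: Optional[list["TreeNode"]] = None,
        height: Optional[float] = None,
    ) -> None:
        self.name = name
        self.length = length
        self.children: list[TreeNode] = children if children is not None else []
        self.height = height

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["TreeNode"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def leaves(self) -> Iterator["TreeNode"]:
        if self.is_leaf:
            yield self
        else:
            for child in self.children:
                yield from child.leaves()

    def copy(self) -> "TreeNode":
        return TreeNode(
            self.name,
            self.length,
            [c.copy() for c in self.children],
            self.height,
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({_node_newick(self)})"


class GuideTree:
    """A rooted tree over sequence identifiers.

    Guide trees drive the order of progressive merges.  After
    binarization every internal node has exactly two children; parsers
    may produce multifurcating nodes, which :meth:`is_binary` reports.
    """

    def __init__(self, root: TreeNode) -> None:
        self.root = root

    # -- structure ----------------------------------------------------

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.root.leaves()]

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.root.leaves())

    def is_binary(self) -> bool:
        return all(
            len(node.children) == 2
            for node in self.root.postorder()
            if not node.is_leaf
        )

    def postorder(self) -> Iterator[TreeNode]:
        return self.root.postorder()

    def copy(self) -> "GuideTree":
        return GuideTree(self.root.copy())

    def validate_leaves(self, ids: list[str]) -> None:
        """Raise ``ValueError`` unless the leaf set equals ``ids`` exactly."""
        leaves = self.leaf_names()
        if len(leaves) != len(set(leaves)):
            dups = sorted({x for x in leaves if leaves.count(x) > 1})
            raise ValueError(f"duplicate leaf labels in tree: {dups}")
        missing = sorted(set(ids) - set(leaves))
        extra = sorted(set(leaves) - set(ids))
        if missing or extra:
            raise ValueError(
                f"tree leaf set does not match sequence ids: "
                f"missing={missing} extra={extra}"
            )

    # -- unrooted bipartitions ---------------------------------------

    def bipartitions(self) -> set[frozenset[frozenset[str]]]:
        """Non-trivial bipartitions of the leaf set induced by internal edges.

        The tree is treated as unrooted: the edge above each non-root
        node splits the leaves into the node's clade and its complement.
        Splits with a side of fewer than two leaves are trivial and
        omitted; the two edges incident to the root induce the same
        split and are deduplicated by the set.
        """
        all_leaves = frozenset(self.leaf_names())
        splits: set[frozenset[frozenset[str]]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])
            clade = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root:
                other = all_leaves - clade
                if len(clade) >= 2 and len(other) >= 2:
                    splits.add(frozenset([clade, other]))
            return clade

        walk(self.root)
        return splits

    # -- serialization ------------------------------------------------

    def newick(self, lengths: bool = True) -> str:
        return format_newick(self, lengths=lengths)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"GuideTree({self.newick(lengths=False)})"


# ---------------------------------------------------------------------------
# Newick serialization / parsing


def _node_newick(node: TreeNode, lengths: bool = True) -> str:
    if node.is_leaf:
        body = node.name or ""
    else:
        body = "(" + ",".join(_node_newick(c, lengths) for c in node.children) + ")"
    if lengths and node.length is not None:
        body += f":{node.length:g}"
    return body


def format_newick(tree: GuideTree, lengths: bool = True) -> str:
    """Serialize a tree to a one-line Newick string (with trailing ';')."""
    return _node_newick(tree.root, lengths=lengths) + ";"


def _convert_dendropy(dnode: dendropy.Node) -> TreeNode:
    name = dnode.taxon.label if dnode.taxon is not None else None
    node = TreeNode(name=name, length=dnode.edge.length)
    node.children = [_convert_dendropy(c) for c in dnode.child_nodes()]
    return node


def parse_newick(text: str) -> GuideTree:
    """Parse a Newick string into a :class:`GuideTree`.

    Multifurcations are accepted (binarize later with the guidetree
    module); malformed input raises ``ValueError``.
    """
    text = text.strip()
    if not text:
        raise ValueError("empty Newick input")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ValueError(f"malformed Newick: {exc}") from exc
    root = _convert_dendropy(dtree.seed_node)
    tree = GuideTree(root)
    if not any(leaf.name for leaf in root.leaves()):
        raise ValueError("Newick tree has no labeled leaves")
    return tree


def to_dendropy(tree: GuideTree) -> dendropy.Tree:
    """Convert to a dendropy tree (used for midpoint rooting and RF checks)."""
    return dendropy.Tree.get(
        data=format_newick(tree),
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
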