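"""Rooted phylogenetic trees: a light node/tree container with Newick I/O.

Branch lengths are in expected substitutions per character. Clock trees
additionally carry node ages (tips at 0, root oldest); ``support`` holds
clade credibility in percent when the tree summarizes a posterior sample.
"""

from __future__ import annotations

import io
from collections.abc import Iterator

import dendropy

__all__ = ["TreeNode", "PhyloTree"]


class TreeNode:
    __slots__ = ("children", "parent", "length", "label", "age", "support")

    def __init__(
        self,
        label: str | None = None,
        length: float = 0.0,
        age: float | None = None,
        support: float | None = None,
    ) -> None:
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None
        self.length = length
        self.label = label
        self.age = age
        self.support = support

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """A rooted tree over labelled tips."""

    def __init__(self, root: TreeNode) -> None:
        self.root = root

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> Iterator[TreeNode]:
        stack: list[tuple[TreeNode, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    @property
    def n_tips(self) -> int:
        return len(self.leaves())

    # -- clade queries ------------------------------------------------------

    def clades(self) -> list[frozenset[str]]:
        """Tip sets of every node (tips included), in postorder."""
        tipsets: dict[int, frozenset[str]] = {}
        out: list[frozenset[str]] = []
        for node in self.postorder():
            if node.is_leaf:
                s = frozenset([node.label])
            else:
                s = frozenset().union(*(tipsets[id(c)] for c in node.children))
            tipsets[id(node)] = s
            out.append(s)
        return out

    def mrca(self, labels: set[str]) -> TreeNode:
        """Smallest node whose tip set contains ``labels``."""
        want = frozenset(labels)
        tipsets: dict[int, frozenset[str]] = {}
        best: TreeNode | None = None
        for node in self.postorder():
            if node.is_leaf:
                s = frozenset([node.label])
            else:
                s = frozenset().union(*(tipsets[id(c)] for c in node.children))
            tipsets[id(node)] = s
            if best is None and want <= s:
                best = node
        if best is None:
            raise KeyError(f"labels {sorted(want)} not all present in tree")
        return best

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        depths = []
        self._tip_depths(self.root, 0.0, depths)
        return max(depths) - min(depths) <= tol if depths else True

    def _tip_depths(self, node: TreeNode, d: float, out: list[float]) -> None:
        if node.is_leaf:
            out.append(d)
        for c in node.children:
            self._tip_depths(c, d + c.length, out)

    def assign_ages_from_lengths(self) -> None:
        """Derive node ages from branch lengths (requires ultrametry)."""
        depth: dict[int, float] = {id(self.root): 0.0}
        order = list(self.postorder())
        for node in reversed(order):  # preorder
            for c in node.children:
                depth[id(c)] = depth[id(node)] + c.length
        height = max(depth[id(n)] for n in order if n.is_leaf)
        for node in order:
            node.age = height - depth[id(node)]

    def copy(self) -> "PhyloTree":
        def rec(node: TreeNode) -> TreeNode:
            clone = TreeNode(node.label, node.length, node.age, node.support)
            for c in node.children:
                clone.add_child(rec(c))
            return clone

        return PhyloTree(rec(self.root))

    # -- Newick I/O ---------------------------------------------------------

    def to_newick(self, support_as_label: bool = True) -> str:
        def rec(node: TreeNode) -> str:
            if node.is_leaf:
                core = _escape(node.label or "")
            else:
                inner = ",".join(rec(c) for c in node.children)
                tag = ""
                if support_as_label and node.support is not None:
                    tag = format(node.support, "g")
                core = f"({inner}){tag}"
            if node.parent is None:
                return core
            return f"{core}:{node.length:.10g}"

        return rec(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
        return cls._from_dendropy(dtree)

    @classmethod
    def _from_dendropy(cls, dtree: dendropy.Tree) -> "PhyloTree":
        def rec(dnode) -> TreeNode:
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            support = None
            if dnode.child_nodes() and label is not None:
                try:
                    support = float(label)
                    label = None
                except ValueError:
                    support = None
            node = TreeNode(
                label=label,
                length=dnode.edge.length or 0.0,
                support=support,
            )
            for c in dnode.child_nodes():
                node.add_child(rec(c))
            return node

        return cls(rec(dtree.seed_node))

    def to_dendropy(
        self, taxon_namespace: dendropy.TaxonNamespace | None = None
    ) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.to_newick(),
            schema="newick",
            preserve_underscores=True,
            taxon_namespace=taxon_namespace,
        )


def _escape(label: str) -> str:
    if any(ch in label for ch in " ()[]{}:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def read_newick_file(path: str) -> PhyloTree:
    with io.open(path, encoding="utf-8") as fh:
        return PhyloTree.from_newick(fh.read())
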