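"""Posterior tree summaries: clade frequencies, majority-rule consensus
trees, and consensus networks.

Clade credibilities are exact counts over the retained sample. The
majority-rule tree keeps clades whose frequency strictly exceeds the
threshold (such clades are mutually compatible for thresholds >= 0.5), with
node support in percent and branch lengths averaged over the samples
containing the clade. The consensus network keeps every unrooted split at or
above ``min_freq`` (weak inequality, so a 10% threshold keeps a split seen in
exactly 10% of trees), weighting each split by its frequency so edge length
is proportional to split probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distnet import SplitSystem
from .trees import PhyloTree, TreeNode

__all__ = [
    "CladeTable",
    "clade_frequencies",
    "majority_consensus",
    "consensus_network",
]


@dataclass(frozen=True)
class CladeTable:
    """Frequency of every observed clade (rooted tip set) in a sample."""

    frequencies: dict[frozenset[str], float]
    n_samples: int

    def frequency(self, clade: set[str]) -> float:
        return self.frequencies.get(frozenset(clade), 0.0)


def _clade_lengths(tree: PhyloTree) -> dict[frozenset[str], float]:
    out: dict[frozenset[str], float] = {}
    tipsets: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            s = frozenset([node.label])
        else:
            s = frozenset().union(*(tipsets[id(c)] for c in node.children))
        tipsets[id(node)] = s
        out[s] = node.length
    return out


def _common_tipset(trees: list[PhyloTree]) -> frozenset[str]:
    if not trees:
        raise ValueError("empty tree sample")
    tips = frozenset(trees[0].leaf_labels())
    for i, t in enumerate(trees[1:], start=2):
        other = frozenset(t.leaf_labels())
        if other != tips:
            raise ValueError(
                f"tree {i} has tip set differing from tree 1: "
                f"{sorted(other ^ tips)}"
            )
    return tips


def clade_frequencies(trees: list[PhyloTree]) -> CladeTable:
    """Exact clade counts divided by sample size."""
    _common_tipset(trees)
    counts: dict[frozenset[str], int] = {}
    for t in trees:
        for clade in set(t.clades()):
            counts[clade] = counts.get(clade, 0) + 1
    n = len(trees)
    return CladeTable(
        frequencies={c: k / n for c, k in counts.items()}, n_samples=n
    )


def majority_consensus(
    trees: list[PhyloTree], threshold: float = 0.5
) -> PhyloTree:
    """Majority-rule consensus tree of clades with frequency > threshold."""
    if threshold < 0.5:
        raise ValueError("threshold must be at least 0.5")
    tips = _common_tipset(trees)
    table = clade_frequencies(trees)
    kept = {
        c: f for c, f in table.frequencies.items()
        if f > threshold or len(c) == 1 or c == tips
    }
    # mean branch length over samples containing each kept clade
    lengths: dict[frozenset[str], list[float]] = {c: [] for c in kept}
    for t in trees:
        cl = _clade_lengths(t)
        for c in kept:
            if c in cl:
                lengths[c].append(cl[c])
    # nest clades smallest-inside-largest
    order = sorted(kept, key=len, reverse=True)
    nodes: dict[frozenset[str], TreeNode] = {}
    for c in order:
        node = TreeNode(
            label=next(iter(c)) if len(c) == 1 else None,
            length=float(np.mean(lengths[c])) if lengths[c] else 0.0,
            support=round(kept[c] * 100.0, 10),
        )
        nodes[c] = node
    root = nodes[tips]
    root.support = 100.0
    for c in order[1:]:
        parent = min(
            (p for p in order if c < p), key=len
        )
        nodes[parent].add_child(nodes[c])
    return PhyloTree(root)


def consensus_network(
    trees: list[PhyloTree], min_freq: float = 0.1
) -> SplitSystem:
    """Unrooted splits at frequency >= min_freq, weighted by frequency."""
    if not 0.0 < min_freq <= 1.0:
        raise ValueError("min_freq must lie in (0, 1]")
    tips = _common_tipset(trees)
    taxa = tuple(sorted(tips))
    counts: dict[frozenset[str], int] = {}
    for t in trees:
        splits = set()
        for clade in t.clades():
            if 0 < len(clade) < len(tips):
                side = clade if taxa[0] not in clade else tips - clade
                if side:
                    splits.add(side)
        for s in splits:
            counts[s] = counts.get(s, 0) + 1
    n = len(trees)
    kept = [(s, k / n) for s, k in counts.items() if k / n >= min_freq]
    kept.sort(key=lambda sw: (-sw[1], sorted(sw[0])))
    return SplitSystem(
        taxa=taxa,
        splits=tuple(s for s, _ in kept),
        weights=np.array([w for _, w in kept]),
    )
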