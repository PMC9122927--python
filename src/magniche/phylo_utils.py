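"""Bipartition utilities and consensus trees.

The 16S consensus procedure: several input topologies over the same leaf
set (here: different inference algorithms and alignment filters) are
reduced to the groups stable across all of them — the strict consensus,
whose bipartition set is exactly the intersection of the inputs'
bipartition sets. A majority-rule mode (> 50 % of inputs) is provided for
comparison. Branch lengths and support values are dropped.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Sequence

import dendropy

from .io_core import read_newick

__all__ = ["bipartitions", "strict_consensus", "consensus_tree",
           "tree_from_splits"]


def _leaf_labels(tree: dendropy.Tree) -> list[str]:
    return sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())


def bipartitions(tree: dendropy.Tree | str) -> set[frozenset]:
    """Non-trivial bipartitions of an (un)rooted tree.

    Each split is canonicalised as the leaf side *not* containing the
    lexicographically smallest leaf, so identical splits from differently
    rooted trees compare equal. Trees with < 4 leaves have none.
    """
    if not isinstance(tree, dendropy.Tree):
        tree = read_newick(tree)
    labels = _leaf_labels(tree)
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate leaf labels")
    anchor = labels[0]
    n = len(labels)
    splits: set[frozenset] = set()
    for node in tree.preorder_internal_node_iter(exclude_seed_node=True):
        below = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        side = frozenset(set(labels) - below) if anchor in below else below
        if 2 <= len(side) <= n - 2:
            splits.add(side)
    return splits


def tree_from_splits(splits: Iterable[frozenset],
                     leaves: Sequence[str]) -> dendropy.Tree:
    """Build the (unique) tree whose clades, rooted at the lexicographically
    smallest leaf, are exactly the given pairwise-compatible splits."""
    leaves = sorted(leaves)
    splits = sorted({frozenset(s) for s in splits}, key=len)
    for a_i, a in enumerate(splits):
        for b in splits[a_i + 1:]:
            if a & b and not a <= b:
                raise ValueError("splits are not pairwise compatible")

    def render(members: frozenset, children: list[frozenset]) -> str:
        inner = sorted(children, key=len, reverse=True)
        taken: set[str] = set()
        parts = []
        for c in inner:
            if c & taken:
                continue
            sub_children = [s for s in splits if s < c]
            # only direct children: those not nested in another child of c
            direct = [s for s in sub_children
                      if not any(s < t for t in sub_children)]
            parts.append(render(c, direct))
            taken |= c
        parts.extend(sorted(members - taken))
        return "(" + ",".join(parts) + ")"

    top = [s for s in splits if not any(s < t for t in splits)]
    newick = render(frozenset(leaves), top) + ";"
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


def consensus_tree(trees: Sequence, mode: str = "strict") -> dendropy.Tree:
    """Consensus of >= 2 trees over one leaf set.

    ``mode="strict"`` keeps splits present in every input; ``"majority"``
    keeps splits present in more than half. Conflicting regions collapse to
    polytomies; fully conflicting inputs give a star tree.
    """
    parsed = [t if isinstance(t, dendropy.Tree) else read_newick(t)
              for t in trees]
    if len(parsed) < 2:
        raise ValueError("need at least two input trees")
    leaf_sets = [set(_leaf_labels(t)) for t in parsed]
    for i, ls in enumerate(leaf_sets[1:], start=1):
        if ls != leaf_sets[0]:
            diff = sorted(ls ^ leaf_sets[0])
            raise ValueError(
                f"tree {i} has a different leaf set; symmetric difference: {diff}")
    split_sets = [bipartitions(t) for t in parsed]
    if mode == "strict":
        keep = set.intersection(*split_sets)
    elif mode == "majority":
        counts = Counter(s for ss in split_sets for s in ss)
        keep = {s for s, c in counts.items() if c > len(parsed) / 2}
    else:
        raise ValueError("mode must be 'strict' or 'majority'")
    return tree_from_splits(keep, sorted(leaf_sets[0]))


def strict_consensus(trees: Sequence) -> dendropy.Tree:
    """Strict consensus: exactly the bipartitions shared by all inputs."""
    return consensus_tree(trees, mode="strict")
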