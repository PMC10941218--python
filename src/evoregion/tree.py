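"""Phylogeny input and preprocessing.

Trees are represented as :class:`dendropy.Tree` objects throughout the
package.  The preprocessing steps mirror a common workflow for taxonomy-based
supertrees without branch-length information: assign every branch a length of
1, stretch terminal branches so the tree becomes ultrametric, and break
polytomies into binary nodes with tiny positive branches so that downstream
matrix and Markov-model machinery can assume a binary, ultrametric tree.
"""

from __future__ import annotations

import io
import warnings

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "NewickError",
    "read_newick",
    "write_newick",
    "tip_labels",
    "tip_depths",
    "set_unit_branch_lengths",
    "ultrametrize_extend",
    "resolve_polytomies",
    "patristic_distances",
]

#: branch length given to edges inserted when breaking a polytomy; small
#: enough to be negligible against unit-length branches, strictly positive.
POLYTOMY_EPSILON = 1e-6


class NewickError(ValueError):
    """Raised when a Newick string cannot be parsed or names tips twice."""


def read_newick(text: str) -> dendropy.Tree:
    """Parse a single Newick tree from a string.

    Quoted labels and ``[...]`` comments are accepted and stripped.  Missing
    branch lengths stay ``None`` (absent), they are *not* coerced to zero.

    Raises
    ------
    NewickError
        On syntax errors (message carries the parser's position) and on
        duplicate tip labels.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickError(f"Newick parse error: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    seen: set[str] = set()
    dupes = {x for x in labels if x in seen or seen.add(x)}
    if dupes:
        raise NewickError(f"duplicate tip labels: {sorted(dupes)}")
    tree.is_rooted = True
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    out = io.StringIO()
    tree.write(file=out, schema="newick", suppress_rooting=True,
               unquoted_underscores=True)
    return out.getvalue().strip() + "\n"


def tip_labels(tree: dendropy.Tree) -> list[str]:
    """Tip names in the tree's leaf-iteration order (the canonical species
    order used to align occurrence matrices)."""
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _clone(tree: dendropy.Tree) -> dendropy.Tree:
    return tree.clone(depth=1)


def tip_depths(tree: dendropy.Tree) -> dict[str, float]:
    """Root-to-tip path length per tip (missing edge lengths count as 0)."""
    depths: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        el = node.edge.length or 0.0
        node._depth = (node.parent_node._depth if node.parent_node else 0.0) + el
        if node.is_leaf():
            depths[node.taxon.label] = node._depth
    return depths


def set_unit_branch_lengths(tree: dendropy.Tree) -> dendropy.Tree:
    """Return a copy with every edge length set to 1 (root edge excluded)."""
    out = _clone(tree)
    for node in out.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = 1.0
    return out


def ultrametrize_extend(tree: dendropy.Tree) -> dendropy.Tree:
    """Make the tree ultrametric by lengthening terminal edges only.

    Each tip's terminal branch is extended by ``max_depth - depth(tip)`` so
    every tip sits at the maximum root-to-tip depth.  Internal edges are left
    untouched; an already-ultrametric tree is returned unchanged (as a copy).
    """
    out = _clone(tree)
    depths = tip_depths(out)
    max_depth = max(depths.values())
    for leaf in out.leaf_node_iter():
        gap = max_depth - depths[leaf.taxon.label]
        if gap > 0:
            leaf.edge.length = (leaf.edge.length or 0.0) + gap
    return out


def resolve_polytomies(
    tree: dendropy.Tree,
    seed: int = 0,
    epsilon: float = POLYTOMY_EPSILON,
) -> dendropy.Tree:
    """Resolve every polytomy into a randomly ordered ladder of binary nodes.

    Inserted edges get length ``epsilon``; every clade of the input tree is a
    clade of the output, and the output is deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    out = _clone(tree)
    for node in list(out.preorder_node_iter()):
        children = node.child_nodes()
        while len(children) > 2:
            idx = rng.choice(len(children), size=2, replace=False)
            a, b = children[idx[0]], children[idx[1]]
            node.remove_child(a)
            node.remove_child(b)
            joint = dendropy.Node()
            joint.add_child(a)
            joint.add_child(b)
            node.add_child(joint)
            joint.edge.length = epsilon
            children = node.child_nodes()
    return out


def patristic_distances(tree: dendropy.Tree) -> pd.DataFrame:
    """Pairwise path-length (patristic) distances between all tips.

    Returns a symmetric DataFrame indexed by tip label in canonical order,
    with a zero diagonal.  All edge lengths must be present.
    """
    labels = tip_labels(tree)
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            raise ValueError("patristic_distances requires all edge lengths")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return pd.DataFrame(d, index=labels, columns=labels)


def is_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-9) -> bool:
    depths = np.array(list(tip_depths(tree).values()))
    scale = max(depths.max(), 1.0)
    if depths.max() - depths.min() > rel_tol * scale:
        return False
    return True


def prune_to(tree: dendropy.Tree, keep: list[str]) -> dendropy.Tree:
    """Copy of the tree restricted to the given tips.

    Tips absent from ``keep`` are removed; a warning lists them.
    """
    out = _clone(tree)
    drop = [t for t in tip_labels(out) if t not in set(keep)]
    if drop:
        warnings.warn(f"pruning {len(drop)} tips absent from the data: {drop[:10]}...")
        out.retain_taxa_with_labels(list(keep))
    return out
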