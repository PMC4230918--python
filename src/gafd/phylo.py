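"""Neighbor-joining trees and the Dice-based cluster overlapping score.

An unrooted binary tree on ``n`` leaves has ``n - 3`` internal edges.  Each
internal edge defines a *cluster*: the leaf set on one side of the edge,
excluding the trivial full set and single-leaf sides.  Two trees over the
same leaves are compared by matching every cluster of each tree to its
best-overlapping cluster in the other tree under the Dice coefficient
(complement-aware, since unrooted splits have no orientation) and averaging
all those per-cluster maxima.  A tree compared against itself scores 1.

Trees are ``dendropy.Tree`` objects throughout; neighbor joining follows
Saitou-Nei with the Studier-Keppler criterion, deterministic lowest-index
tie-breaking, and negative branch lengths clamped to zero.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .spectral import DistanceMatrix

__all__ = [
    "neighbor_joining",
    "tree_clusters",
    "dice",
    "cluster_overlap_score",
    "summarize_scores",
    "read_newick",
    "write_newick",
    "random_binary_tree",
    "tree_path_distances",
]

PhyloTree = dendropy.Tree


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Build an unrooted NJ tree from a distance matrix.

    Ties in the Studier-Keppler criterion are broken toward the
    lowest-index pair; negative branch-length estimates are clamped to 0.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError(f"neighbor joining needs >= 3 taxa, got {n}")
    d0 = np.asarray(dm.d, dtype=float)
    off_diag = d0[~np.eye(n, dtype=bool)]
    if np.any(~np.isfinite(off_diag)) or np.any(off_diag < 0):
        raise ValueError("distance matrix contains NaN/inf or negative entries")

    taxa = dendropy.TaxonNamespace(dm.labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: list[dendropy.Node] = []
    for label in dm.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)

    d = d0.copy()
    active = list(range(n))
    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        sums = sub.sum(axis=1)
        q = (r - 2) * sub - sums[:, None] - sums[None, :]
        np.fill_diagonal(q, np.inf)
        # argmin scans row-major, so the first minimal entry is the
        # lowest-index pair.
        flat = int(np.argmin(q))
        ai, aj = divmod(flat, r)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        limb_i = 0.5 * dij + (sums[ai] - sums[aj]) / (2.0 * (r - 2))
        limb_j = dij - limb_i
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = max(limb_i, 0.0)
        nodes[j].edge.length = max(limb_j, 0.0)
        # reuse slot i for the new node; distances via the reduction rule
        new_d = 0.5 * (d[i, :] + d[j, :] - dij)
        d[i, :] = new_d
        d[:, i] = new_d
        d[i, i] = 0.0
        nodes[i] = parent
        active.remove(j)

    # resolve the final three nodes around a central vertex
    a, b, c = active
    center = dendropy.Node()
    for child in (nodes[a], nodes[b], nodes[c]):
        center.add_child(child)
    nodes[a].edge.length = max(0.5 * (d[a, b] + d[a, c] - d[b, c]), 0.0)
    nodes[b].edge.length = max(0.5 * (d[a, b] + d[b, c] - d[a, c]), 0.0)
    nodes[c].edge.length = max(0.5 * (d[a, c] + d[b, c] - d[a, b]), 0.0)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def _leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())


def tree_clusters(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Leaf-label sets of the internal edges of an unrooted tree.

    Each split is represented by its smaller side (ties by the side holding
    the alphabetically smallest label); sides of size < 2 or > n - 2 are
    excluded, so a star tree yields an empty set.
    """
    leaves = _leaf_labels(tree)
    n = len(leaves)
    below: dict[dendropy.Node, frozenset[str]] = {}
    clusters: set[frozenset[str]] = set()
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
        else:
            below[node] = frozenset().union(*(below[ch] for ch in node.child_nodes()))
        if node.parent_node is None:
            continue
        side = below[node]
        if not (2 <= len(side) <= n - 2):
            continue
        comp = leaves - side
        if len(comp) < len(side) or (
            len(comp) == len(side) and min(comp) < min(side)
        ):
            side = comp
        clusters.add(side)
    return clusters


def dice(c1: frozenset[str] | set[str], c2: frozenset[str] | set[str]) -> float:
    """Dice coefficient 2|c1 ∩ c2| / (|c1| + |c2|) between two leaf sets."""
    if not c1 or not c2:
        raise ValueError("Dice coefficient undefined for empty sets")
    return 2.0 * len(set(c1) & set(c2)) / (len(c1) + len(c2))


def _best_dice(
    c: frozenset[str], others: set[frozenset[str]], leaves: frozenset[str]
) -> float:
    best = 0.0
    comp_c = leaves - c
    for o in others:
        comp_o = leaves - o
        best = max(
            best, dice(c, o), dice(c, comp_o), dice(comp_c, o), dice(comp_c, comp_o)
        )
        if best == 1.0:
            break
    return best


def cluster_overlap_score(
    t1: dendropy.Tree, t2: dendropy.Tree, symmetric: bool = True
) -> float:
    """Mean best-match Dice overlap between the cluster sets of two trees.

    Every cluster of each tree is matched to its maximum-Dice counterpart
    in the other tree (complements count as the same split) and the
    per-cluster maxima are averaged.  With ``symmetric=False`` only the
    clusters of ``t1`` are matched against ``t2``.  Returns a value in
    [0, 1]; identical trees score exactly 1.
    """
    l1, l2 = _leaf_labels(t1), _leaf_labels(t2)
    if l1 != l2:
        raise ValueError(
            f"leaf sets differ; symmetric difference: {sorted(l1 ^ l2)}"
        )
    c1, c2 = tree_clusters(t1), tree_clusters(t2)
    if not c1 or not c2:
        warnings.warn(
            "a tree has no qualifying clusters (star-like); score defined as 0",
            stacklevel=2,
        )
        return 0.0
    maxima = [_best_dice(c, c2, l1) for c in c1]
    if symmetric:
        maxima += [_best_dice(c, c1, l1) for c in c2]
    return float(np.mean(maxima))


def summarize_scores(
    table: pd.DataFrame, columns: list[str] | None = None, ddof: int = 1
) -> pd.DataFrame:
    """Mean and standard deviation of the score columns of a results table.

    ``ddof=1`` (sample standard deviation) by default; pass ``ddof=0`` for
    the population convention.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 rows to summarize")
    if columns is None:
        columns = [
            c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])
        ]
    data = table[columns]
    return pd.DataFrame(
        {"mean": data.mean(), "std": data.std(ddof=ddof)}
    ).T


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read one Newick tree; requires >= 3 uniquely labelled leaves."""
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) < 3:
        raise ValueError(f"tree in {path} has {len(labels)} leaves; need >= 3")
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate leaf labels in {path}: {dupes}")
    tree.is_rooted = False
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def random_binary_tree(
    n_leaves: int,
    rng: np.random.Generator,
    min_branch: float = 0.1,
    max_branch: float = 2.0,
) -> dendropy.Tree:
    """Random unrooted binary tree with uniform random branch lengths.

    Grown by sequential random edge attachment, which samples uniformly
    over unrooted binary topologies.
    """
    if n_leaves < 3:
        raise ValueError("need >= 3 leaves")
    labels = [f"t{i}" for i in range(n_leaves)]
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)

    def blen() -> float:
        return float(rng.uniform(min_branch, max_branch))

    center = tree.seed_node
    leaves = []
    for lab in labels[:3]:
        node = dendropy.Node(taxon=taxa.get_taxon(lab))
        center.add_child(node)
        node.edge.length = blen()
        leaves.append(node)
    edges = [leaf.edge for leaf in leaves]
    for lab in labels[3:]:
        edge = edges[rng.integers(len(edges))]
        child = edge.head_node
        parent = edge.tail_node
        split = dendropy.Node()
        parent.remove_child(child)
        parent.add_child(split)
        split.edge.length = blen()
        split.add_child(child)
        child.edge.length = blen()
        new_leaf = dendropy.Node(taxon=taxa.get_taxon(lab))
        split.add_child(new_leaf)
        new_leaf.edge.length = blen()
        edges.extend([split.edge, child.edge, new_leaf.edge])
    tree.is_rooted = False
    return tree


def tree_path_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length (patristic) distances of a tree."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return DistanceMatrix(labels, d)
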