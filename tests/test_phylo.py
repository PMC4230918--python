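"""Neighbor joining, cluster extraction and the Dice overlap score."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from gafd.phylo import (
    cluster_overlap_score,
    dice,
    neighbor_joining,
    random_binary_tree,
    read_newick,
    summarize_scores,
    tree_clusters,
    tree_path_distances,
    write_newick,
)
from gafd.spectral import DistanceMatrix


def tree_from_newick(s: str) -> dendropy.Tree:
    t = dendropy.Tree.get(data=s, schema="newick", preserve_underscores=True)
    t.is_rooted = False
    return t


def test_nj_recovers_additive_four_taxon_tree():
    # generating tree ((A:1,B:2):1,(C:3,D:4)) -> hand-computed path distances
    labels = list("ABCD")
    d = np.array(
        [
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ],
        float,
    )
    tree = neighbor_joining(DistanceMatrix(labels, d))
    assert tree_clusters(tree) == {frozenset("AB")}
    recovered = tree_path_distances(tree)
    np.testing.assert_allclose(recovered.d, d, atol=1e-10)


def test_nj_three_taxa_closed_form():
    dm = DistanceMatrix(list("ABC"), np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
    tree = neighbor_joining(dm)
    limbs = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
    assert limbs == {"A": 1.0, "B": 2.0, "C": 3.0}


def test_nj_equidistant_tie_breaks_to_lowest_pair():
    d = np.full((4, 4), 2.0)
    np.fill_diagonal(d, 0)
    tree = neighbor_joining(DistanceMatrix(list("ABCD"), d))
    assert tree_clusters(tree) == {frozenset("AB")}
    # additive fit of the fully symmetric matrix: four limbs of 1, internal 0
    total = sum(e.length for e in tree.preorder_edge_iter() if e.length)
    assert total == pytest.approx(4.0)


def test_nj_input_contracts():
    with pytest.raises(ValueError, match=">= 3"):
        neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))
    d = np.array([[0, 1, 1], [1, 0, np.nan], [1, np.nan, 0]])
    with pytest.raises(ValueError):  # rejected at validation or at NJ entry
        neighbor_joining(DistanceMatrix(list("ABC"), d))


@pytest.mark.parametrize("seed", range(20))
def test_nj_consistency_on_random_additive_matrices(seed):
    """NJ recovers the generating topology and all path distances from an
    additive matrix (random binary trees, up to 12 leaves)."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 13))
    source = random_binary_tree(n, rng)
    dm = tree_path_distances(source)
    rebuilt = neighbor_joining(dm)
    assert tree_clusters(rebuilt) == tree_clusters(source)
    np.testing.assert_allclose(tree_path_distances(rebuilt).d, dm.d, atol=1e-8)


def test_nj_agrees_with_independent_implementation():
    """Same topology as scikit-bio's neighbor joining on random matrices."""
    import skbio

    for seed in range(5):
        rng = np.random.default_rng(seed)
        n = 8
        source = random_binary_tree(n, rng)
        dm = tree_path_distances(source)
        ours = tree_clusters(neighbor_joining(dm))
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(dm.d, ids=dm.labels))
        leaves = frozenset(dm.labels)
        theirs = set()
        for node in sk_tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if not 2 <= len(side) <= n - 2:
                continue
            comp = leaves - side
            if len(comp) < len(side) or (
                len(comp) == len(side) and min(comp) < min(side)
            ):
                side = comp
            theirs.add(side)
        assert ours == theirs


def test_four_leaf_tree_single_cluster():
    t = tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);")
    assert tree_clusters(t) == {frozenset("AB")}


def test_caterpillar_five_leaves_two_clusters():
    t = tree_from_newick("(((A:1,B:1):1,C:1):1,D:1,E:1);")
    # the ABC|DE split is stored by its smaller side {D, E}
    assert tree_clusters(t) == {frozenset("AB"), frozenset("DE")}


def test_star_tree_no_clusters():
    t = tree_from_newick("(A:1,B:1,C:1,D:1,E:1);")
    assert tree_clusters(t) == set()


@pytest.mark.parametrize(
    "c1, c2, expected",
    [({"A", "B"}, {"A", "B"}, 1.0), ({"A", "B"}, {"C", "D"}, 0.0),
     ({"A", "B"}, {"B", "C"}, 0.5)],
)
def test_dice_examples(c1, c2, expected):
    assert dice(c1, c2) == expected


def test_dice_empty_set_rejected():
    with pytest.raises(ValueError):
        dice(set(), {"A"})


@pytest.mark.parametrize("seed", range(10))
def test_self_comparison_scores_one(seed):
    rng = np.random.default_rng(seed)
    t = random_binary_tree(int(rng.integers(4, 20)), rng)
    assert cluster_overlap_score(t, t) == 1.0


def test_conflicting_four_leaf_splits_score_half():
    t1 = tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);")
    t2 = tree_from_newick("((A:1,C:1):1,(B:1,D:1):1);")
    assert cluster_overlap_score(t1, t2) == 0.5


def test_star_tree_scores_zero_with_warning():
    star = tree_from_newick("(A:1,B:1,C:1,D:1);")
    binary = tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);")
    with pytest.warns(UserWarning, match="star"):
        assert cluster_overlap_score(star, binary) == 0.0


def test_leaf_set_mismatch_reports_difference():
    t1 = tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);")
    t2 = tree_from_newick("((A:1,B:1):1,(C:1,E:1):1);")
    with pytest.raises(ValueError, match="D"):
        cluster_overlap_score(t1, t2)


@pytest.mark.parametrize("seed", range(10))
def test_overlap_score_symmetry_and_bounds(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 15))
    t1 = random_binary_tree(n, rng)
    t2 = random_binary_tree(n, rng)
    s12 = cluster_overlap_score(t1, t2)
    s21 = cluster_overlap_score(t2, t1)
    assert s12 == pytest.approx(s21)
    assert 0 <= s12 <= 1


def test_score_one_iff_identical_cluster_sets(rng):
    t1 = random_binary_tree(10, rng)
    t2 = random_binary_tree(10, rng)
    s = cluster_overlap_score(t1, t2)
    same = tree_clusters(t1) == tree_clusters(t2)
    assert (s == 1.0) == same


def test_summarize_scores_mean_and_std(data_dir):
    table = pd.read_csv(data_dir / "trna_scores.tsv", sep="\t")
    summary = summarize_scores(table, columns=["A", "B", "C"])
    assert summary.loc["mean", "A"] == pytest.approx(86.75, abs=0.005)
    # printed Std rows follow the population (n) convention
    pop = summarize_scores(table, columns=["A"], ddof=0)
    assert pop.loc["std", "A"] == pytest.approx(4.48, abs=0.005)


def test_summarize_identical_column_zero_std():
    table = pd.DataFrame({"A": [5.0, 5.0, 5.0]})
    assert summarize_scores(table).loc["std", "A"] == 0.0


def test_summarize_needs_two_rows():
    with pytest.raises(ValueError):
        summarize_scores(pd.DataFrame({"A": [1.0]}))


def test_newick_round_trip_preserves_tree(tmp_path, rng):
    for _ in range(20):
        n = int(rng.integers(4, 15))
        t = random_binary_tree(n, rng)
        path = tmp_path / "t.nwk"
        write_newick(t, path)
        back = read_newick(path)
        assert tree_clusters(back) == tree_clusters(t)
        np.testing.assert_allclose(
            tree_path_distances(back).d, tree_path_distances(t).d, atol=1e-9
        )


def test_newick_two_leaves_rejected(tmp_path):
    path = tmp_path / "pair.nwk"
    path.write_text("(A:1,B:1);\n")
    with pytest.raises(ValueError, match="leaves"):
        read_newick(path)
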