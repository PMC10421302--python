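import numpy as np
import pytest
import skbio

from mgbssr.diversity import (
    cut_tree_groups,
    distance,
    nj_tree,
    pcoa,
    to_binary_matrix,
    tree_to_newick,
)
from mgbssr.popgen import GenotypeTable


# --- binary matrix -------------------------------------------------------
def test_binary_matrix_presence_and_column_order():
    t = GenotypeTable(
        samples=["A", "B"],
        markers=["M"],
        cells={("A", "M"): (100, 100), ("B", "M"): (100, 120)},
    )
    bm = to_binary_matrix(t)
    assert list(bm.columns) == [("M", 100), ("M", 120)]
    assert bm.loc["A"].tolist() == [1, 0]
    assert bm.loc["B"].tolist() == [1, 1]


def test_binary_matrix_missing_cell_and_triploid_dosage(toy_table):
    bm = to_binary_matrix(toy_table)
    # c is missing at M2 -> all zeros in M2's columns
    m2_cols = [c for c in bm.columns if c[0] == "M2"]
    assert bm.loc["c", m2_cols].sum() == 0
    # triploid 100/100/120 scores presence, not dosage
    assert bm.loc["t", ("M1", 100)] == 1


# --- distances -----------------------------------------------------------
def dm_of(rows, ids=None):
    import pandas as pd

    ids = ids or [f"s{i}" for i in range(len(rows))]
    return pd.DataFrame(np.array(rows), index=ids)


def test_jaccard_dice_and_matching_values():
    m = dm_of([[1, 1, 0], [1, 0, 1]])
    assert distance(m, "jaccard")[0, 1] == pytest.approx(2 / 3)
    assert distance(m, "dice")[0, 1] == pytest.approx(0.5)
    assert distance(m, "simple_matching")[0, 1] == pytest.approx(2 / 3)


def test_identical_and_complementary_rows():
    m = dm_of([[1, 0, 1], [1, 0, 1], [0, 1, 0]])
    d = distance(m, "jaccard")
    assert d[0, 1] == 0.0
    assert d[0, 2] == 1.0


def test_all_zero_rows_are_handled():
    m = dm_of([[0, 0, 0], [0, 0, 0], [1, 0, 1]])
    d = distance(m, "jaccard")
    assert d[0, 1] == 0.0
    assert d[0, 2] == 1.0


def test_distance_requires_two_samples():
    with pytest.raises(ValueError):
        distance(dm_of([[1, 0]]), "jaccard")


# --- neighbor joining ----------------------------------------------------
def test_three_taxon_branch_lengths_from_three_point_formulas():
    dm = skbio.DistanceMatrix(
        [[0, 2, 4], [2, 0, 4], [4, 4, 0]], ids=["A", "B", "C"]
    )
    tree = nj_tree(dm)
    lengths = {t.name: t.length for t in tree.tips()}
    assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})


def random_additive_tree(rng, n):
    """Random binary tree with exponential branch lengths, plus its
    tip-to-tip path-length matrix (the oracle: NJ must reproduce it)."""
    nodes = [skbio.TreeNode(name=f"t{i}") for i in range(n)]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        parent = skbio.TreeNode()
        a.length = float(rng.exponential(1.0)) + 0.05
        b.length = float(rng.exponential(1.0)) + 0.05
        parent.extend([a, b])
        nodes = [x for k, x in enumerate(nodes) if k not in (int(i), int(j))]
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


def path_matrix(tree, ids):
    td = tree.tip_tip_distances()
    return np.array([[0.0 if a == b else td[a, b] for b in ids] for a in ids])


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_nj_reproduces_additive_distances_exactly(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 13))
    truth = random_additive_tree(rng, n)
    ids = sorted(t.name for t in truth.tips())
    d = path_matrix(truth, ids)
    est = nj_tree(skbio.DistanceMatrix(d, ids=ids))
    d2 = path_matrix(est, ids)
    assert np.max(np.abs(d2 - d)) < 1e-9


def test_nj_agrees_with_skbio_on_additive_data():
    """Independent cross-check: on additive input (no negative-branch
    corrections in play) our NJ and scikit-bio's produce the same path
    lengths."""
    rng = np.random.default_rng(77)
    truth = random_additive_tree(rng, 9)
    ids = sorted(t.name for t in truth.tips())
    dm = skbio.DistanceMatrix(path_matrix(truth, ids), ids=ids)
    ours = path_matrix(nj_tree(dm), ids)
    ref = path_matrix(skbio.tree.nj(dm), ids)
    assert np.max(np.abs(ours - ref)) < 1e-8


def test_equidistant_taxa_give_equal_terminal_branches():
    n = 5
    d = np.ones((n, n)) - np.eye(n)
    tree = nj_tree(skbio.DistanceMatrix(d, ids=list("ABCDE")))
    lengths = {t.name: t.length for t in tree.tips()}
    assert all(l == pytest.approx(0.5) for l in lengths.values())


def test_nj_rejects_fewer_than_three():
    with pytest.raises(ValueError):
        nj_tree(skbio.DistanceMatrix([[0, 1], [1, 0]], ids=["a", "b"]))


def test_newick_serialization_has_branch_lengths():
    dm = skbio.DistanceMatrix(
        [[0, 2, 4], [2, 0, 4], [4, 4, 0]], ids=["A", "B", "C"]
    )
    nwk = tree_to_newick(nj_tree(dm))
    assert nwk.endswith(";")
    back = skbio.TreeNode.read([nwk])
    assert {t.name for t in back.tips()} == {"A", "B", "C"}
    assert all(t.length is not None for t in back.tips())


def test_negative_branch_clamp_moves_deficit_to_sibling():
    """A distance matrix engineered to yield a negative NJ branch: the
    clamped pair still sums to its original joint length."""
    d = np.array(
        [
            [0.0, 5.0, 9.0, 9.0],
            [5.0, 0.0, 14.0, 14.0],
            [9.0, 14.0, 0.0, 1.0],
            [9.0, 14.0, 1.0, 0.0],
        ]
    )
    # perturb to force asymmetry strong enough for a negative estimate
    d[0, 1] = d[1, 0] = 0.5
    tree = nj_tree(skbio.DistanceMatrix(d, ids=list("abcd")))
    lengths = {t.name: t.length for t in tree.tips()}
    assert all(l >= 0 for l in lengths.values())
    assert lengths["a"] + lengths["b"] == pytest.approx(0.5)


# --- PCoA ----------------------------------------------------------------
def euclidean_dm(points, ids):
    diff = points[:, None, :] - points[None, :, :]
    return skbio.DistanceMatrix(np.sqrt((diff**2).sum(-1)), ids=ids)


def test_pcoa_round_trips_euclidean_distances():
    rng = np.random.default_rng(3)
    pts = rng.random((10, 2))
    ids = [f"s{i}" for i in range(10)]
    dm = euclidean_dm(pts, ids)
    res = pcoa(dm, k=2)
    emb = res.coordinates.to_numpy()
    diff = emb[:, None, :] - emb[None, :, :]
    d2 = np.sqrt((diff**2).sum(-1))
    assert np.max(np.abs(d2 - dm.data)) < 1e-8


def test_collinear_points_put_all_inertia_on_axis_one():
    pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.5, 0.0], [4.0, 0.0]])
    dm = euclidean_dm(pts, list("abcd"))
    res = pcoa(dm, k=1)
    pos = res.eigenvalues[res.eigenvalues > 1e-10]
    assert len(pos) == 1
    assert res.proportion_explained[0] == pytest.approx(1.0)


def test_identical_samples_get_identical_coordinates():
    pts = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [2.0, 0.0]])
    res = pcoa(euclidean_dm(pts, list("abcd")), k=2)
    c = res.coordinates
    assert np.allclose(c.loc["a"], c.loc["b"], atol=1e-10)


def test_requesting_too_many_axes_warns_and_truncates():
    pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
    with pytest.warns(UserWarning, match="axes"):
        res = pcoa(euclidean_dm(pts, list("abc")), k=3)
    assert res.n_axes < 3


def test_axis_signs_are_canonical_and_relabeling_equivariant():
    rng = np.random.default_rng(9)
    pts = rng.random((8, 3))
    ids = [f"s{i}" for i in range(8)]
    res1 = pcoa(euclidean_dm(pts, ids), k=2)
    perm = list(reversed(range(8)))
    res2 = pcoa(euclidean_dm(pts[perm], [ids[i] for i in perm]), k=2)
    for s in ids:
        assert np.allclose(
            res1.coordinates.loc[s], res2.coordinates.loc[s], atol=1e-8
        )


def test_cut_tree_groups_partitions_tips():
    dm = skbio.DistanceMatrix(
        [
            [0, 0.1, 0.9, 0.9],
            [0.1, 0, 0.9, 0.9],
            [0.9, 0.9, 0, 0.1],
            [0.9, 0.9, 0.1, 0],
        ],
        ids=list("abcd"),
    )
    groups = cut_tree_groups(tree_to_newick(nj_tree(dm)), 2)
    flat = sorted(x for g in groups for x in g)
    assert flat == list("abcd")
    assert sorted(map(sorted, groups)) == [["a", "b"], ["c", "d"]]
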