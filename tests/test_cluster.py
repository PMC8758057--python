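"""Standardisation, Ward/K-means oracles, elbow selection and PCoA."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from bladderpheno import (
    PhenotypeClustering,
    cut_tree,
    kmeans_fit,
    pcoa_bray,
    standardize,
    suggest_k,
    unit_scale,
    ward_dendrogram,
    wss_curve,
)
from bladderpheno.cluster import bray_curtis_matrix
from bladderpheno.errors import DegenerateFeatureError, ValidationError

# ---------------------------------------------------------------------------
# standardisation


def test_standardize_continuous_and_binary(default_cohort):
    cohort, _ = default_cohort
    fm = standardize(cohort)
    for col in fm.features:
        x = fm.frame[col].to_numpy()
        if fm.feature_kind[col] == "binary":
            assert set(np.unique(x)) <= {0.0, 1.0}
        else:
            assert abs(x.mean()) < 1e-12
            assert abs(x.std(ddof=0) - 1) < 1e-12
    # stored parameters re-apply bit-identically
    again = fm.apply(cohort)
    np.testing.assert_array_equal(again.to_numpy(), fm.values)


def test_standardize_zero_variance_named():
    df = pd.DataFrame({"subject_id": ["a", "b"], "icsi_1": [2, 2], "icsi_2": [1, 3]})
    with pytest.raises(DegenerateFeatureError, match="icsi_1"):
        standardize(df)


def test_standardize_log_transform():
    df = pd.DataFrame({"subject_id": list("abcd"), "icsi_1": [0, 1, 2, 5]})
    fm = standardize(df, log_columns=("icsi_1",))
    expected = np.log1p([0, 1, 2, 5])
    expected = (expected - expected.mean()) / expected.std()
    np.testing.assert_allclose(fm.frame["icsi_1"], expected)


# ---------------------------------------------------------------------------
# Ward


def brute_force_best_2partition(X):
    """Exhaustive optimal 2-partition by total within-cluster sum of squares."""
    n = len(X)
    best, best_sets = np.inf, None
    for r in range(1, n // 2 + 1):
        for combo in combinations(range(n), r):
            a = np.asarray(combo)
            b = np.setdiff1d(np.arange(n), a)
            wss = ((X[a] - X[a].mean(0)) ** 2).sum() + ((X[b] - X[b].mean(0)) ** 2).sum()
            if wss < best - 1e-12:
                best, best_sets = wss, (set(a.tolist()), set(b.tolist()))
    return best, best_sets


def test_ward_singleton_merge_height():
    tree = ward_dendrogram(np.array([[0.0], [2.0]]))
    assert len(tree.merges) == 1
    assert tree.merges[0][2] == pytest.approx(2.0)  # ||a-b||^2 / 2


def test_ward_duplicate_point_first_merge_zero():
    tree = ward_dendrogram(np.array([[1.0, 1.0], [1.0, 1.0], [5.0, 0.0]]))
    assert tree.merges[0][2] == pytest.approx(0.0)
    assert np.all(np.diff(tree.heights) >= -1e-12)


def test_ward_two_triads_cut_matches_exhaustive_optimum():
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(0, 0.1, (3, 2)), rng.normal(5, 0.1, (3, 2))])
    tree = ward_dendrogram(X)
    labels = cut_tree(tree, 2)
    got = ({i for i in range(6) if labels[i] == 1}, {i for i in range(6) if labels[i] == 2})
    _, expected = brute_force_best_2partition(X)
    assert set(map(frozenset, got)) == set(map(frozenset, expected))


def test_cut_tree_bounds_and_nesting():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(10, 3))
    tree = ward_dendrogram(X)
    assert np.all(cut_tree(tree, 1) == 1)
    assert len(set(cut_tree(tree, 10).tolist())) == 10
    with pytest.raises(ValidationError):
        cut_tree(tree, 0)
    with pytest.raises(ValidationError):
        cut_tree(tree, 11)
    # successive cuts are nested refinements
    for k in range(1, 9):
        coarse, fine = cut_tree(tree, k), cut_tree(tree, k + 1)
        for c in set(fine.tolist()):
            members = coarse[fine == c]
            assert len(set(members.tolist())) == 1


def test_ward_requires_two_subjects():
    with pytest.raises(ValidationError):
        ward_dendrogram(np.array([[1.0]]))


# ---------------------------------------------------------------------------
# K-means


def test_kmeans_k1_is_grand_mean():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(20, 4))
    model = kmeans_fit(X, k=1, seed=0)
    np.testing.assert_allclose(model.centroids[0], X.mean(0))
    assert model.wss == pytest.approx(((X - X.mean(0)) ** 2).sum())


def test_kmeans_matches_exhaustive_2partition_oracle():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(8, 2))
    model = kmeans_fit(X, k=2, seed=0, n_restarts=50)
    best_wss, best_sets = brute_force_best_2partition(X)
    got = ({i for i in range(8) if model.labels[i] == 1},
           {i for i in range(8) if model.labels[i] == 2})
    assert model.wss == pytest.approx(best_wss, rel=1e-9)
    assert set(map(frozenset, got)) == set(map(frozenset, best_sets))


def test_kmeans_invariants_and_determinism():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(30, 3))
    a = kmeans_fit(X, k=3, seed=7)
    b = kmeans_fit(X, k=3, seed=7)
    np.testing.assert_array_equal(a.labels, b.labels)
    np.testing.assert_allclose(a.centroids, b.centroids)
    # centroids are member means; wss is the recomputed objective
    for c in range(1, 4):
        np.testing.assert_allclose(a.centroids[c - 1], X[a.labels == c].mean(0))
    assert a.wss == pytest.approx(a.recompute_wss(X))
    assert sorted(set(a.labels.tolist())) == [1, 2, 3]
    with pytest.raises(ValidationError):
        kmeans_fit(X[:2], k=3, seed=0)


def test_wss_curve_monotone_and_elbow():
    rng = np.random.default_rng(5)
    X = np.vstack([rng.normal(c, 0.2, (15, 2)) for c in ((0, 0), (6, 0), (0, 6))])
    curve = wss_curve(X, k_max=6, seed=0, n_restarts=10)
    wss = [w for _, w in curve]
    assert all(wss[i] >= wss[i + 1] - 1e-9 for i in range(len(wss) - 1))
    assert suggest_k(curve) == 3
    assert wss_curve(X[:5], k_max=5, seed=0)[-1][1] == pytest.approx(0.0)


def test_elbow_suggests_three_phenotypes_across_seeds(default_cohort):
    """The default synthetic cohort has a three-cluster elbow, stably."""
    cohort, _ = default_cohort
    model = PhenotypeClustering.from_dataframe(cohort)
    picks = [model.suggest_k(k_max=8, seed=s) for s in range(10)]
    assert all(p == 3 for p in picks)


def test_label_permutation_invariance():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(20, 2))
    model = kmeans_fit(X, k=2, seed=1)
    # swapping label names leaves the objective and centroid set unchanged
    swapped = np.where(model.labels == 1, 2, 1)
    wss_swapped = sum(((X[swapped == c] - X[swapped == c].mean(0)) ** 2).sum()
                      for c in (1, 2))
    assert wss_swapped == pytest.approx(model.wss)


# ---------------------------------------------------------------------------
# PCoA / Bray-Curtis


def test_bray_curtis_reference_values():
    X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0], [0.0, 0.0], [0.0, 0.0]])
    d = bray_curtis_matrix(X)
    assert d[0, 1] == pytest.approx(1.0)      # disjoint support
    assert d[0, 2] == pytest.approx(0.0)      # identical profiles
    assert d[3, 4] == pytest.approx(0.0)      # double-zero pair defined as 0
    with pytest.raises(ValidationError):
        bray_curtis_matrix(np.array([[-1.0, 0.0]]))


def test_pcoa_reproduces_toy_dissimilarities():
    """3 subjects: the full-rank PCoA embedding must reproduce the
    hand-computed Bray-Curtis dissimilarities (independent eigen oracle)."""
    df = pd.DataFrame({"a": [1.0, 0.0, 0.5], "b": [0.0, 1.0, 0.5]},
                      index=["s1", "s2", "s3"])
    X = df.to_numpy()
    # independent oracle: classical MDS by double-centering + eigh
    d = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            num = np.abs(X[i] - X[j]).sum()
            den = (X[i] + X[j]).sum()
            d[i, j] = num / den if den else 0.0
    J = np.eye(3) - np.ones((3, 3)) / 3
    B = -0.5 * J @ (d ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    keep = vals > 1e-12
    oracle = vecs[:, keep] * np.sqrt(vals[keep])
    oracle_dist = np.linalg.norm(oracle[:, None] - oracle[None, :], axis=2)

    coords = pcoa_bray(df, n_dims=2).to_numpy()
    got_dist = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
    np.testing.assert_allclose(got_dist, oracle_dist, atol=1e-8)


def test_unit_scale_respects_item_bounds(default_cohort):
    cohort, _ = default_cohort
    scaled = unit_scale(cohort)
    assert ((scaled >= 0) & (scaled <= 1)).all().all()
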