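"""Feature fusion: class entropy, MIBIF ranking, PCA, pairwise feature MI."""

import numpy as np
import pytest

import cissacsp as cc


def feature_matrix(values, labels):
    return cc.FeatureMatrix(np.atleast_2d(values.T).T if values.ndim == 1 else values,
                            labels)


# ---------------------------------------------------------------------------
# class entropy
# ---------------------------------------------------------------------------

def test_class_entropy(balanced_labels):
    assert cc.class_entropy(balanced_labels) == pytest.approx(1.0)
    assert cc.class_entropy(np.ones(10, int)) == 0.0
    assert cc.class_entropy([1, 1, 1, 2]) == pytest.approx(0.811278, abs=1e-6)
    with pytest.raises(ValueError, match="empty"):
        cc.class_entropy([])


# ---------------------------------------------------------------------------
# MIBIF
# ---------------------------------------------------------------------------

def test_mibif_constant_feature_is_zero_bits(balanced_labels):
    F = cc.FeatureMatrix(np.zeros((280, 1)), balanced_labels)
    assert cc.mibif_scores(F).mi[0] == 0.0


def test_mibif_separating_feature_near_one_bit(balanced_labels):
    sep = np.where(balanced_labels == 1, -10.0, 10.0)
    F = cc.FeatureMatrix(sep[:, None], balanced_labels)
    # discrete plug-in oracle on the binarized feature gives exactly 1 bit
    assert cc.mibif_scores(F, bandwidth=1.0).mi[0] >= 0.99


def test_mibif_independent_feature_near_zero(balanced_labels):
    hits = 0
    for seed in range(100):
        x = np.random.default_rng(seed).standard_normal(280)
        F = cc.FeatureMatrix(x[:, None], balanced_labels)
        hits += cc.mibif_scores(F).mi[0] < 0.05
    assert hits >= 95


def test_mibif_monotone_in_class_separation(balanced_labels):
    means = []
    for delta in (0.0, 1.0, 2.0, 4.0):
        mis = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(280) + np.where(balanced_labels == 1, 0.0, delta)
            mis.append(cc.mibif_scores(cc.FeatureMatrix(x[:, None], balanced_labels)).mi[0])
        means.append(np.mean(mis))
    assert all(b > a for a, b in zip(means, means[1:]))


def test_mibif_requires_both_classes_and_minimum_n():
    F = cc.FeatureMatrix(np.random.default_rng(0).standard_normal((8, 2)), np.ones(8, int) )
    with pytest.raises(ValueError, match="both classes"):
        cc.mibif_scores(F)
    F = cc.FeatureMatrix(np.random.default_rng(0).standard_normal((5, 2)),
                         np.array([1, 1, 1, 1, 2]))
    with pytest.raises(ValueError, match="class 2"):
        cc.mibif_scores(F)


def test_mibif_select_orders_and_bounds(balanced_labels):
    rng = np.random.default_rng(1)
    sep = np.where(balanced_labels == 1, -10.0, 10.0)
    F = cc.FeatureMatrix(
        np.column_stack([rng.standard_normal(280), sep, rng.standard_normal(280)]),
        balanced_labels,
    )
    ranking = cc.mibif_scores(F, bandwidth=1.0)
    top1 = cc.mibif_select(ranking, 1, F)
    np.testing.assert_array_equal(top1.values[:, 0], sep)
    full = cc.mibif_select(ranking, 3, F)
    assert sorted(map(tuple, full.columns)) == sorted(map(tuple, F.columns))
    with pytest.raises(ValueError, match="out of range"):
        cc.mibif_select(ranking, 4, F)


def test_mibif_selection_stability(default_features):
    """Top-5 columns stay within the top-10 under 90/10 resampling."""
    rng = np.random.default_rng(0)
    full_rank = cc.mibif_scores(default_features)
    top5 = set(full_rank.order[:5])
    ok = 0
    n = default_features.n
    for _ in range(20):
        idx = rng.choice(n, size=int(0.9 * n), replace=False)
        sub = cc.FeatureMatrix(
            default_features.values[idx], default_features.labels[idx],
            columns=list(default_features.columns),
        )
        order = cc.mibif_scores(sub).order
        ok += top5 <= set(order[:10])
    assert ok >= 16


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def test_pca_recovers_dominant_axis(balanced_labels):
    rng = np.random.default_rng(2)
    X = rng.standard_normal((2000, 2)) * np.array([np.sqrt(3.0), 1.0])
    F = cc.FeatureMatrix(X, np.resize([1, 2], 2000))
    model = cc.pca_fit(F, 1)
    angle = np.degrees(np.arccos(abs(model.W[:, 0] @ [1.0, 0.0])))
    assert angle < 5.0


def test_pca_full_rotation_properties(balanced_labels):
    rng = np.random.default_rng(3)
    F = cc.FeatureMatrix(rng.standard_normal((280, 6)) @ rng.standard_normal((6, 6)),
                         balanced_labels)
    model = cc.pca_fit(F, 6)
    np.testing.assert_allclose(model.W.T @ model.W, np.eye(6), atol=1e-10)
    proj = cc.pca_transform(model, F)
    C = np.cov(proj.values, rowvar=False)
    off = C - np.diag(np.diag(C))
    assert np.abs(off).max() < 1e-8
    assert np.all(np.diff(np.diag(C)) <= 1e-9)  # non-increasing variances
    assert np.trace(C) == pytest.approx(np.trace(np.cov(F.values, rowvar=False)), rel=1e-9)
    assert np.abs(proj.values.mean(axis=0)).max() < 1e-9  # centred


def test_pca_transform_known_rotation(balanced_labels):
    theta = np.pi / 6
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    model = cc.PcaModel(mean=np.array([1.0, -2.0]), W=R, variances=np.array([2.0, 1.0]))
    F = cc.FeatureMatrix(np.array([[1.0, -2.0], [2.0, 0.0]]), np.array([1, 2]))
    proj = cc.pca_transform(model, F)
    np.testing.assert_allclose(proj.values[0], [0.0, 0.0], atol=1e-12)
    np.testing.assert_allclose(proj.values[1], (np.array([1.0, 2.0]) @ R), atol=1e-12)
    with pytest.raises(ValueError, match="d="):
        cc.pca_transform(model, cc.FeatureMatrix(np.zeros((2, 3)), np.array([1, 2])))


def test_pca_idempotent_on_projected_data(balanced_labels):
    rng = np.random.default_rng(4)
    F = cc.FeatureMatrix(rng.standard_normal((280, 8)), balanced_labels)
    proj = cc.pca_transform(cc.pca_fit(F, 4), F)
    model2 = cc.pca_fit(proj, 4)
    again = cc.pca_transform(model2, proj)
    from scipy.spatial.distance import pdist
    np.testing.assert_allclose(pdist(again.values), pdist(proj.values), atol=1e-8)


def test_pca_k_out_of_range(balanced_labels):
    F = cc.FeatureMatrix(np.random.default_rng(0).standard_normal((280, 4)), balanced_labels)
    with pytest.raises(ValueError, match="out of range"):
        cc.pca_fit(F, 5)


# ---------------------------------------------------------------------------
# pairwise feature MI
# ---------------------------------------------------------------------------

def test_pairwise_mi_duplicated_column_equals_self_mi(balanced_labels):
    rng = np.random.default_rng(5)
    x = rng.standard_normal(280)
    F = cc.FeatureMatrix(np.column_stack([x, rng.standard_normal(280), x]), balanced_labels)
    M = cc.pairwise_feature_mi(F)
    assert M[0, 2] == pytest.approx(M[0, 0], abs=1e-6)
    np.testing.assert_allclose(M, M.T, atol=1e-9)


def test_pairwise_mi_independent_columns_near_zero(balanced_labels):
    hits = 0
    for seed in range(40):
        X = np.random.default_rng(seed).standard_normal((280, 2))
        M = cc.pairwise_feature_mi(cc.FeatureMatrix(X, balanced_labels))
        hits += M[0, 1] < 0.05
    assert hits >= 38


def test_pairwise_mi_requires_two_columns(balanced_labels):
    F = cc.FeatureMatrix(np.random.default_rng(0).standard_normal((280, 3)), balanced_labels)
    with pytest.raises(ValueError, match="2 columns"):
        cc.pairwise_feature_mi(F, columns=[0])
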