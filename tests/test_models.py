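"""OPLS-DA, double cross-validation, permutation testing and clustering."""

import numpy as np
import pytest
from scipy.cluster import hierarchy
from sklearn.cross_decomposition import PLSRegression

from uromet.models import (OPLSDA, ClusterOrder, double_cv_q2,
                           hierarchical_heatmap_order, pca, permutation_test)


def two_class_data(rng, n_per_class=10, n_bins=20, delta=0.0):
    X = rng.normal(0, 1, (2 * n_per_class, n_bins))
    y = np.repeat([0, 1], n_per_class)
    X[y == 1, :3] += delta
    return X, y


class TestPCA:
    def test_rank_one_data_fully_explained_by_pc1(self):
        t = np.linspace(-1, 1, 8)
        X = np.outer(t, [1.0, 2.0, -1.0]) + 5.0
        scores, loadings, evr = pca(X, 2)
        assert evr[0] == pytest.approx(1.0)

    def test_full_reconstruction(self, rng):
        X = rng.normal(0, 1, (6, 4))
        scores, loadings, _ = pca(X, 4)
        recon = scores @ loadings.T + X.mean(axis=0)
        np.testing.assert_allclose(recon, X, atol=1e-10)

    def test_two_sample_pc1_distance(self, rng):
        X = rng.normal(0, 1, (2, 5))
        scores, _, _ = pca(X, 1)
        assert abs(scores[0, 0] - scores[1, 0]) == pytest.approx(
            np.linalg.norm(X[0] - X[1]))

    def test_components_beyond_rank_truncated_with_warning(self, rng):
        X = rng.normal(0, 1, (3, 5))
        with pytest.warns(UserWarning, match="truncated"):
            scores, _, _ = pca(X, 5)
        assert scores.shape[1] == 2


class TestOPLSDA:
    def test_zero_orthogonal_reduces_to_pls1(self, rng):
        """With no orthogonal components the predictive scores are PLS1's."""
        X, y = two_class_data(rng, delta=1.0)
        model = OPLSDA(n_orthogonal=0).fit(X, y)
        pls = PLSRegression(n_components=1, scale=False).fit(
            X, np.where(y == 1, 1.0, -1.0))
        a = model.scores_ / np.linalg.norm(model.scores_)
        b = pls.x_scores_[:, 0] / np.linalg.norm(pls.x_scores_[:, 0])
        assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_orthogonal_confound_removed_exactly(self, rng):
        """Structured y-orthogonal noise leaves predictive loadings intact."""
        n = 16
        y = np.repeat([0, 1], n // 2)
        yc = np.where(y == 1, 1.0, -1.0)
        yc = yc - yc.mean()
        t_conf = rng.normal(0, 1, n)
        t_conf -= t_conf @ yc / (yc @ yc) * yc  # orthogonal to the labels
        a = rng.normal(0, 1, 10)
        b = rng.normal(0, 1, 10)
        X_clean = np.outer(yc, a)
        X_conf = X_clean + np.outer(t_conf, b)
        clean = OPLSDA(n_orthogonal=0).fit(X_clean, y)
        conf = OPLSDA(n_orthogonal=1).fit(X_conf, y)
        sign = np.sign(clean.loadings_ @ conf.loadings_)
        np.testing.assert_allclose(conf.loadings_, sign * clean.loadings_,
                                   atol=1e-6)

    def test_perfect_separation_r2y_is_one(self):
        X = np.array([[0.0, 0.0]] * 3 + [[1.0, 1.0]] * 3)
        model = OPLSDA(n_orthogonal=0).fit(X, np.repeat([0, 1], 3))
        assert model.R2Y_ == pytest.approx(1.0)

    def test_single_class_rejected(self, rng):
        X = rng.normal(0, 1, (6, 4))
        with pytest.raises(ValueError, match="2 classes"):
            OPLSDA().fit(X, np.zeros(6))

    def test_predict_recovers_training_labels_on_strong_signal(self, rng):
        X, y = two_class_data(rng, delta=5.0)
        model = OPLSDA(n_orthogonal=1).fit(X, y)
        np.testing.assert_array_equal(model.predict(X), y)

    def test_model_fit_invariants(self, rng):
        X, y = two_class_data(rng, delta=2.0)
        model = OPLSDA(n_orthogonal=1).fit(X, y)
        assert 0.0 <= model.R2Y_ <= 1.0
        q2 = double_cv_q2(X, y, seed=0)
        assert q2 <= model.R2Y_ + 1e-9


class TestDoubleCV:
    def test_null_labels_give_nonpositive_q2(self):
        """Labels independent of X: Q2 <= 0 in at least 90% of replicates."""
        neg = 0
        for rep in range(100):
            rng = np.random.default_rng(rep)
            X, y = two_class_data(rng, n_per_class=20, n_bins=10, delta=0.0)
            if double_cv_q2(X, y, seed=rep) <= 0.0:
                neg += 1
        assert neg >= 90

    def test_strong_signal_gives_high_q2(self, rng):
        X, y = two_class_data(rng, n_per_class=20, delta=6.0)
        assert double_cv_q2(X, y, seed=0) > 0.9

    def test_same_seed_same_q2(self, rng):
        X, y = two_class_data(rng, delta=1.0)
        assert double_cv_q2(X, y, seed=7) == double_cv_q2(X, y, seed=7)

    def test_tiny_classes_collapse_to_leave_one_out(self, rng):
        X, y = two_class_data(rng, n_per_class=3, delta=4.0)
        q2 = double_cv_q2(X, y, outer_folds=10, inner_folds=10, seed=0)
        assert np.isfinite(q2)


class TestPermutationTest:
    def test_p_floor_when_observed_beats_all_permutations(self, rng):
        X, y = two_class_data(rng, n_per_class=10, delta=8.0)
        res = permutation_test(X, y, statistic="R2Y", n_perm=50, seed=0)
        assert res.p == pytest.approx(1.0 / 51.0)

    def test_single_permutation_at_or_above_observed_gives_p_one(self):
        # label-orthogonal predictor: any permutation scores at least as well
        y = np.repeat([0, 1], 4)
        x = np.array([1.0, -1, 1, -1, 1, -1, 1, -0.9])[:, None]
        res = permutation_test(x, y, statistic="R2Y", n_perm=1, seed=0)
        assert res.permuted[0] >= res.observed
        assert res.p == 1.0

    def test_null_calibration_mean_p_near_half(self):
        """Pure-noise labels: permutation p is uniform on its grid."""
        ps = []
        for rep in range(200):
            rng = np.random.default_rng(1000 + rep)
            X, y = two_class_data(rng, n_per_class=8, n_bins=10, delta=0.0)
            ps.append(permutation_test(X, y, statistic="R2Y", n_perm=19,
                                       seed=rep).p)
        assert 0.45 <= np.mean(ps) <= 0.55

    def test_seed_reproducible(self, rng):
        X, y = two_class_data(rng, delta=1.0)
        a = permutation_test(X, y, n_perm=20, seed=5).p
        b = permutation_test(X, y, n_perm=20, seed=5).p
        assert a == b


def brute_force_ward(X):
    """O(n^3) agglomeration minimizing the Ward variance increase (oracle)."""
    clusters = {i: [i] for i in range(len(X))}
    merges = []
    while len(clusters) > 1:
        best = None
        for i in sorted(clusters):
            for j in sorted(clusters):
                if j <= i:
                    continue
                a, b = X[clusters[i]], X[clusters[j]]
                na, nb = len(a), len(b)
                d = np.linalg.norm(a.mean(0) - b.mean(0)) ** 2
                delta = na * nb / (na + nb) * d
                if best is None or delta < best[0] - 1e-12:
                    best = (delta, i, j)
        _, i, j = best
        merges.append(frozenset(clusters[i]) | frozenset(clusters[j]))
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return merges


class TestHeatmapOrder:
    def test_identical_rows_merge_first(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0]])
        order = hierarchical_heatmap_order(X)
        first = order.row_linkage[0, :2].astype(int)
        assert set(first) == {0, 1}

    def test_merge_order_matches_brute_force(self, rng):
        X = rng.normal(0, 1, (8, 3))
        order = hierarchical_heatmap_order(X)
        oracle = brute_force_ward(X)
        n = len(X)
        members = {i: frozenset([i]) for i in range(n)}
        got = []
        for k, (i, j, *_rest) in enumerate(order.row_linkage):
            merged = members[int(i)] | members[int(j)]
            members[n + k] = merged
            got.append(merged)
        assert got == oracle

    def test_row_permutation_preserves_heights(self, rng):
        X = rng.normal(0, 1, (7, 4))
        perm = rng.permutation(7)
        a = hierarchical_heatmap_order(X)
        b = hierarchical_heatmap_order(X[perm])
        np.testing.assert_allclose(sorted(a.row_linkage[:, 2]),
                                   sorted(b.row_linkage[:, 2]), atol=1e-12)

    def test_single_row_trivial_order(self):
        order = hierarchical_heatmap_order(np.ones((1, 3)))
        assert order.row_order == [0]
        assert order.row_linkage is None
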