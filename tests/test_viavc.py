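"""VIAVC: resampling matrix, subset AUC, ranking, best-subset selection."""

import numpy as np
import pytest

from uromet.simulate import planted_bin_matrix
from uromet.viavc import (VIAVCSelector, best_subset,
                          random_combination_matrix, rank_variables,
                          subset_auc)


def labelled_noise(rng, n_per_class=20, n_bins=20, delta=0.0, planted=()):
    X = rng.normal(0, 1, (2 * n_per_class, n_bins))
    y = np.repeat([0, 1], n_per_class)
    for j in planted:
        X[y == 1, j] += delta
    return X, y


class TestRandomCombinationMatrix:
    def test_inclusion_frequency_concentrates(self):
        B = random_combination_matrix(500, 1000, 0.5, seed=0)
        means = B.mean(axis=0)
        assert np.mean((means >= 0.45) & (means <= 0.55)) >= 0.99

    def test_same_seed_identical(self):
        a = random_combination_matrix(30, 50, 0.3, seed=4)
        b = random_combination_matrix(30, 50, 0.3, seed=4)
        np.testing.assert_array_equal(a, b)

    def test_no_all_zero_rows(self):
        B = random_combination_matrix(3, 2000, 0.05, seed=1)
        assert B.any(axis=1).all()

    def test_zero_bins_rejected(self):
        with pytest.raises(ValueError, match="n_bins"):
            random_combination_matrix(0, 10, 0.5)


class TestSubsetAUC:
    def test_perfectly_separating_bin_gives_auc_one(self, rng):
        X, y = labelled_noise(rng, n_per_class=6, delta=50.0, planted=(0,))
        assert subset_auc(X, y, [0], folds=6, seed=0) == pytest.approx(1.0)

    def test_label_flip_invariance_of_refitted_auc(self, rng):
        """The PLS weights re-orient with the labels, so CV-AUC is invariant
        under a label flip (the 1-AUC complement applies only to fixed
        scores, which roc_curve covers)."""
        X, y = labelled_noise(rng, n_per_class=5, delta=1.0, planted=(0,))
        a = subset_auc(X, y, [0, 1], folds=100, seed=0)  # collapses to LOO
        b = subset_auc(X, 1 - y, [0, 1], folds=100, seed=0)
        assert a == pytest.approx(b, abs=1e-12)

    def test_noise_bins_stay_near_chance(self):
        """Null CV-AUC is centred on 0.5; in-dataset luck bounds its spread."""
        aucs = []
        for rep in range(200):
            rng = np.random.default_rng(rep)
            X, y = labelled_noise(rng, n_per_class=20, n_bins=5)
            aucs.append(subset_auc(X, y, [0, 1, 2], folds=10, seed=rep))
        aucs = np.asarray(aucs)
        assert 0.45 <= aucs.mean() <= 0.55
        assert np.mean((aucs >= 0.3) & (aucs <= 0.7)) >= 0.85
        assert np.mean((aucs >= 0.25) & (aucs <= 0.75)) >= 0.92

    def test_unknown_bin_rejected(self, rng):
        X, y = labelled_noise(rng, n_per_class=4, n_bins=3)
        with pytest.raises(ValueError, match="unknown bin"):
            subset_auc(X, y, [7])


class TestRankVariables:
    def test_planted_bin_ranked_first_across_seeds(self):
        """One discriminating bin among 49 noise bins tops the F-ranking."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X, y = labelled_noise(rng, n_per_class=20, n_bins=50, delta=1.5,
                                  planted=(7,))
            _, ranking, _ = rank_variables(X, y, n_rows=500, seed=seed)
            wins += ranking[0] == 7
        assert wins >= 18

    def test_shuffled_labels_flag_almost_no_bins(self):
        """Null restraint: the significant category stays rare under
        label shuffling (in-dataset luck makes a strict zero unattainable
        for any resampling-based importance test)."""
        fracs = []
        for rep in range(100):
            rng = np.random.default_rng(rep)
            X, y = labelled_noise(rng, n_per_class=10, n_bins=30)
            y = rng.permutation(y)
            _, _, cats = rank_variables(X, y, n_rows=150, folds=5, seed=rep)
            fracs.append(np.mean(cats == "significant"))
        assert np.mean(fracs) <= 0.08

    def test_planted_bin_categorized_significant(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X, y = labelled_noise(rng, n_per_class=20, n_bins=50, delta=1.5,
                                  planted=(7,))
            _, _, cats = rank_variables(X, y, n_rows=500, seed=seed)
            hits += cats[7] == "significant"
        assert hits >= 9

    def test_duplicated_informative_bins_both_rank_high(self):
        rng = np.random.default_rng(3)
        X, y = labelled_noise(rng, n_per_class=20, n_bins=20, delta=2.0,
                              planted=(0,))
        X[:, 1] = X[:, 0] + rng.normal(0, 0.05, len(y))
        _, ranking, _ = rank_variables(X, y, n_rows=500, seed=3)
        assert {0, 1} <= set(ranking[:3])

    def test_single_bin_rejected(self, rng):
        X, y = labelled_noise(rng, n_per_class=4, n_bins=1)
        with pytest.raises(ValueError, match="at least 2"):
            rank_variables(X, y)


class TestBestSubset:
    def test_single_planted_bin_gives_singleton_subset(self):
        """Parsimony tie-break: one informative bin, best subset size 1."""
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X, y = labelled_noise(rng, n_per_class=20, n_bins=10, delta=6.0,
                                  planted=(0,))
            subset, aucs, _ = best_subset(np.arange(10), X, y, max_k=5,
                                          folds=10, seed=seed)
            wins += list(subset) == [0]
        assert wins >= 9

    def test_all_noise_auc_not_significant(self):
        """Best-of-noise AUC stays within its own permutation null."""
        rng = np.random.default_rng(0)
        X, y = labelled_noise(rng, n_per_class=20, n_bins=10)
        _, ranking, _ = rank_variables(X, y, n_rows=200, seed=0)
        subset, aucs, _ = best_subset(ranking, X, y, max_k=5, folds=10, seed=0)
        observed = max(aucs)
        null = []
        for b in range(60):
            yp = rng.permutation(y)
            _, rk, _ = rank_variables(X, yp, n_rows=200, seed=b)
            _, a, _ = best_subset(rk, X, yp, max_k=5, folds=10, seed=b)
            null.append(max(a))
        p = (np.sum(np.asarray(null) >= observed) + 1) / (len(null) + 1)
        assert p > 0.05

    def test_max_k_capped_with_warning(self, rng):
        X, y = labelled_noise(rng, n_per_class=5, n_bins=3)
        with pytest.warns(UserWarning, match="capped"):
            best_subset(np.arange(3), X, y, max_k=10, folds=5, seed=0)


class TestVIAVCSelector:
    def test_run_is_pure_function_of_inputs_and_seed(self):
        X, y, _ = planted_bin_matrix(n_subjects=10, n_bins=40, seed=5)
        a = VIAVCSelector(n_rows=100, random_state=9).fit(X, y)
        b = VIAVCSelector(n_rows=100, random_state=9).fit(X, y)
        np.testing.assert_array_equal(a.ranking_, b.ranking_)
        np.testing.assert_array_equal(a.best_subset_, b.best_subset_)
        assert a.best_auc_ == b.best_auc_

    def test_ranking_is_permutation_and_subset_of_ranking(self):
        X, y, _ = planted_bin_matrix(n_subjects=10, n_bins=40, seed=6)
        sel = VIAVCSelector(n_rows=100, random_state=0).fit(X, y)
        assert sorted(sel.ranking_) == list(range(40))
        assert set(sel.best_subset_) <= set(sel.ranking_)
        assert 0.5 <= sel.best_auc_ <= 1.0

    def test_f_ranked_head_is_prefix_of_ranking(self):
        X, y, _ = planted_bin_matrix(n_subjects=10, n_bins=40, seed=7)
        sel = VIAVCSelector(n_rows=100, random_state=0).fit(X, y)
        res = sel.result()
        np.testing.assert_array_equal(res.f_ranked_head(19), sel.ranking_[:19])

    def test_adding_noise_bin_never_helps_much(self):
        """Monotone sanity of the selected panel under noise augmentation."""
        gains = []
        for seed in range(10):
            X, y, planted = planted_bin_matrix(n_subjects=15, n_bins=30,
                                               seed=seed)
            base = subset_auc(X, y, planted, folds=10, seed=seed)
            noisy = subset_auc(X, y, list(planted) + [29], folds=10, seed=seed)
            gains.append(noisy - base)
        assert np.mean(gains) <= 0.02

    def test_json_roundtrip(self, tmp_path):
        from uromet.viavc import VIAVCResult
        X, y, _ = planted_bin_matrix(n_subjects=10, n_bins=30, seed=8)
        res = VIAVCSelector(n_rows=80, random_state=2).fit(X, y).result()
        res.to_json(tmp_path / "v.json")
        back = VIAVCResult.from_json(tmp_path / "v.json")
        np.testing.assert_array_equal(back.ranking, res.ranking)
        np.testing.assert_array_equal(back.best_subset, res.best_subset)
        assert back.best_auc == res.best_auc
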