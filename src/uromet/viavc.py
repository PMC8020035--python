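"""Variable Importance Analysis based on random Variable Combination (VIAVC).

VIAVC ranks spectral bins by how much their inclusion improves the
cross-validated AUC of a classifier trained on random bin subsets:

1. draw a binary combination matrix — each row is a Bernoulli(p) mask over
   bins (all-zero rows are redrawn);
2. score every row's subset with cross-validated single-component PLS1-DA
   and record its AUC;
3. a bin's importance is the mean AUC of the rows that include it minus the
   mean AUC of the rows that exclude it; bins are sorted by descending
   importance (the F-ranking) and categorized by a one-sided Mann-Whitney
   test on the two AUC populations (Bonferroni-controlled across bins);
4. rounds iterate: after each round the bottom half of the ranking is
   eliminated and the matrix is redrawn over the survivors, concentrating
   the resampling on informative bins until a final compact round;
5. the best subset is the nested head of the final ranking (top-1, top-2,
   ...) with maximal cross-validated AUC, ties broken toward fewer bins.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from ._plscv import auc_mann_whitney, cv_plsda_scores, make_splits
from .models import _encode_labels

__all__ = [
    "VIAVCResult",
    "VIAVCSelector",
    "random_combination_matrix",
    "subset_auc",
    "rank_variables",
    "best_subset",
]


def random_combination_matrix(n_bins: int, n_rows: int, inclusion_prob: float, seed=None):
    """n_rows x n_bins Bernoulli(inclusion_prob) masks with no all-zero rows."""
    if n_bins == 0:
        raise ValueError("n_bins must be positive")
    if n_rows < 1:
        raise ValueError("n_rows must be >= 1")
    if not 0.0 < inclusion_prob < 1.0:
        raise ValueError("inclusion_prob must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    B = rng.random((n_rows, n_bins)) < inclusion_prob
    empty = ~B.any(axis=1)
    while empty.any():
        B[empty] = rng.random((int(empty.sum()), n_bins)) < inclusion_prob
        empty = ~B.any(axis=1)
    return B


def subset_auc(X, y, subset, folds: int = 10, seed: int = 0) -> float:
    """Cross-validated PLS1-DA AUC of one bin subset (raw orientation).

    The pooled held-out decision values follow the -1/+1 label encoding, so
    flipping the labels maps the AUC to 1 - AUC; no floor convention is
    applied here.
    """
    X = np.asarray(X, dtype=float)
    subset = np.asarray(subset, dtype=int)
    if subset.size == 0:
        raise ValueError("subset must be nonempty")
    if subset.max() >= X.shape[1] or subset.min() < 0:
        raise ValueError("subset references an unknown bin")
    ym, _ = _encode_labels(y)
    splits = make_splits(y, folds, np.random.default_rng(seed))
    yhat = cv_plsda_scores(X[:, subset], ym, splits)
    return auc_mann_whitney(yhat, ym)


def _round_importances(X, y, n_rows, inclusion_prob, folds, rng, alpha):
    """One resampling round on the given columns of X.

    Returns (importances, categories, p_values) per column.
    """
    n_bins = X.shape[1]
    ym, _ = _encode_labels(y)
    splits = make_splits(y, folds, rng)
    B = random_combination_matrix(n_bins, n_rows, inclusion_prob, rng)
    aucs = np.empty(n_rows)
    for r in range(n_rows):
        cols = np.flatnonzero(B[r])
        yhat = cv_plsda_scores(X[:, cols], ym, splits)
        aucs[r] = auc_mann_whitney(yhat, ym)

    importances = np.full(n_bins, np.nan)
    pvals = np.full(n_bins, np.nan)
    categories = np.array(["undefined"] * n_bins, dtype=object)
    threshold = alpha / n_bins  # family-wise control across the tested bins
    for j in range(n_bins):
        inc = aucs[B[:, j]]
        exc = aucs[~B[:, j]]
        if inc.size == 0 or exc.size == 0:
            continue
        importances[j] = inc.mean() - exc.mean()
        pvals[j] = stats.mannwhitneyu(inc, exc, alternative="greater").pvalue

    # The rank test alone detects any in-dataset quirk once n_rows is large,
    # so "significant" additionally requires the bin's importance to be an
    # outlier of the across-bin importance distribution: under a global null
    # all bins are exchangeable, which makes the robust z-score calibration
    # self-referential and keeps the family-wise null rate near alpha.
    finite = np.isfinite(importances)
    med = np.median(importances[finite]) if finite.any() else 0.0
    mad = np.median(np.abs(importances[finite] - med)) if finite.any() else 0.0
    scale = 1.4826 * mad if mad > 0 else np.inf
    for j in range(n_bins):
        if not np.isfinite(importances[j]):
            continue
        z = (importances[j] - med) / scale
        outlier = stats.norm.sf(z) < threshold
        if pvals[j] < threshold and outlier:
            categories[j] = "significant"
        elif importances[j] > 0:
            categories[j] = "positive"
        elif importances[j] < 0:
            categories[j] = "negative"
        else:
            categories[j] = "neutral"
    return importances, categories, pvals


def rank_variables(X, y, n_rows: int = 500, inclusion_prob: float = 0.5,
                   folds: int = 10, seed: int = 0, alpha: float = 0.05):
    """Single-round VIAVC ranking: (importances, ranking, categories).

    ``ranking`` is the F-ranking — bin indices sorted by descending
    importance (undefined importances last, ties by index).
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 bins to rank")
    rng = np.random.default_rng(seed)
    imps, cats, _ = _round_importances(X, y, n_rows, inclusion_prob, folds, rng, alpha)
    key = np.where(np.isnan(imps), -np.inf, imps)
    ranking = np.argsort(-key, kind="stable")
    return imps, ranking, cats


@dataclass
class VIAVCResult:
    """Outcome of a full VIAVC run."""

    importances: np.ndarray  # per bin, from the round each bin last entered
    ranking: np.ndarray  # bin indices, best first (the F-ranking)
    categories: np.ndarray
    best_subset: np.ndarray  # bin indices
    best_auc: float  # oriented (floored at 0.5 by convention)
    best_auc_raw: float
    accuracies: list  # cross-validated accuracy per nested panel size
    subset_aucs: list  # AUC per nested panel size
    n_rows: int
    seed: int
    bin_ids: list = field(default_factory=list)

    def f_ranked_head(self, k: int = 19) -> np.ndarray:
        """The top-k bins of the F-ranking (the correlation-screen input)."""
        return self.ranking[: min(k, len(self.ranking))]

    @classmethod
    def from_json(cls, path) -> "VIAVCResult":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            importances=np.asarray(d["importances"], dtype=float),
            ranking=np.asarray(d["ranking"], dtype=int),
            categories=np.asarray(d["categories"], dtype=object),
            best_subset=np.asarray(d["best_subset"], dtype=int),
            best_auc=d["best_auc"],
            best_auc_raw=d.get("best_auc_raw", d["best_auc"]),
            accuracies=list(d["accuracies"]),
            subset_aucs=list(d["subset_aucs"]),
            n_rows=d["n_rows"],
            seed=d["seed"],
            bin_ids=list(d.get("bin_ids", [])),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "ranking": self.ranking.tolist(),
                    "importances": self.importances.tolist(),
                    "categories": self.categories.tolist(),
                    "best_subset": self.best_subset.tolist(),
                    "best_auc": self.best_auc,
                    "best_auc_raw": self.best_auc_raw,
                    "accuracies": self.accuracies,
                    "subset_aucs": self.subset_aucs,
                    "n_rows": self.n_rows,
                    "seed": self.seed,
                    "bin_ids": list(self.bin_ids),
                },
                fh,
                indent=1,
            )


def best_subset(ranking, X, y, max_k: int = 10, folds: int = 10, seed: int = 0):
    """Evaluate nested heads of the ranking; maximal AUC, fewer bins on ties.

    Returns (subset indices, aucs per size, accuracies per size).
    """
    import warnings

    from .roc import panel_accuracy

    ranking = np.asarray(ranking, dtype=int)
    if ranking.size == 0:
        raise ValueError("ranking must be nonempty")
    if max_k > ranking.size:
        warnings.warn("max_k exceeds the number of ranked bins; capped", stacklevel=2)
        max_k = ranking.size
    aucs = [
        subset_auc(X, y, ranking[:k], folds=folds, seed=seed)
        for k in range(1, max_k + 1)
    ]
    best_k = int(np.argmax(np.asarray(aucs) > np.max(aucs) - 1e-12)) + 1
    accuracies = panel_accuracy(X, y, ranking[:max_k], folds=folds, seed=seed)
    return ranking[:best_k], aucs, accuracies


class VIAVCSelector(BaseEstimator):
    """AUC-driven variable selection over random bin combinations.

    Iterative halving concentrates the resampling budget: each round draws
    ``n_rows`` random combinations over the surviving bins, ranks them by
    inclusion-AUC gain, and discards the bottom half until at most
    ``min_final_bins`` survive (``n_iterations=1`` reproduces a single
    global round). The final ranking lists survivors first (by final-round
    importance), then earlier casualties by elimination round.

    The whole run is a pure function of (X, y, parameters, random_state).
    """

    def __init__(
        self,
        n_rows: int = 500,
        inclusion_prob: float = 0.5,
        folds: int = 10,
        max_k: int = 10,
        alpha: float = 0.05,
        n_iterations="auto",
        min_final_bins: int = 24,
        random_state: int = 0,
    ):
        self.n_rows = n_rows
        self.inclusion_prob = inclusion_prob
        self.folds = folds
        self.max_k = max_k
        self.alpha = alpha
        self.n_iterations = n_iterations
        self.min_final_bins = min_final_bins
        self.random_state = random_state

    def fit(self, X, y, bin_ids=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        n_bins = X.shape[1]
        if n_bins < 2:
            raise ValueError("need at least 2 bins")
        rng = np.random.default_rng(self.random_state)

        importances = np.full(n_bins, np.nan)
        categories = np.array(["undefined"] * n_bins, dtype=object)
        active = np.arange(n_bins)
        eliminated: list[np.ndarray] = []  # per round, worst-last order
        max_rounds = math.inf if self.n_iterations == "auto" else int(self.n_iterations)

        rounds = 0
        while True:
            imps, cats, _ = _round_importances(
                X[:, active], y, self.n_rows, self.inclusion_prob,
                self.folds, rng, self.alpha,
            )
            importances[active] = imps
            categories[active] = cats
            rounds += 1
            key = np.where(np.isnan(imps), -np.inf, imps)
            order = np.argsort(-key, kind="stable")
            if rounds >= max_rounds or active.size <= max(self.min_final_bins, 2):
                final_order = active[order]
                break
            keep = order[: (active.size + 1) // 2]
            drop = order[(active.size + 1) // 2 :]
            eliminated.append(active[drop])
            active = active[np.sort(keep)]

        tail = [b for grp in reversed(eliminated) for b in grp]
        self.ranking_ = np.concatenate([final_order, np.array(tail, dtype=int)]) \
            if tail else final_order
        self.importances_ = importances
        self.categories_ = categories
        self.n_rounds_ = rounds

        subset, aucs, accuracies = best_subset(
            self.ranking_, X, y, max_k=self.max_k, folds=self.folds,
            seed=int(rng.integers(2**31 - 1)),
        )
        self.best_subset_ = subset
        self.subset_aucs_ = aucs
        raw = aucs[len(subset) - 1]
        self.best_auc_raw_ = raw
        self.best_auc_ = max(raw, 1.0 - raw)  # orientation floor convention
        self.accuracies_ = accuracies
        self.bin_ids_ = list(bin_ids) if bin_ids is not None else None
        self.n_features_in_ = n_bins
        return self

    def transform(self, X):
        return np.asarray(X)[:, self.best_subset_]

    def get_support(self, indices: bool = False):
        if indices:
            return self.best_subset_
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.best_subset_] = True
        return mask

    def result(self) -> VIAVCResult:
        return VIAVCResult(
            importances=self.importances_,
            ranking=self.ranking_,
            categories=self.categories_,
            best_subset=self.best_subset_,
            best_auc=self.best_auc_,
            best_auc_raw=self.best_auc_raw_,
            accuracies=list(self.accuracies_),
            subset_aucs=list(self.subset_aucs_),
            n_rows=self.n_rows,
            seed=self.random_state,
            bin_ids=self.bin_ids_ or [],
        )
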