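"""Multivariate models for paired-cohort discrimination.

The centerpiece is OPLS-DA for a binary class vector: variation in X that is
orthogonal to the class labels is peeled off first (the "within-group"
axes), then a single predictive PLS component is fitted on what remains
(the "between-group" axis). Model quality is summarized by

* R2Y — the fraction of class-label variance explained by the training fit,
* Q2  — the cross-validation analogue, here from double (nested)
  cross-validation: an outer loop holds every sample out at least once
  while an inner loop picks the number of orthogonal components,
* permutation p-values — the observed statistic ranked against the same
  statistic recomputed under random label permutations.

PCA and Ward hierarchical clustering (the heat-map ordering) complete the
unsupervised view.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import PCA as _SkPCA
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "OPLSDA",
    "ModelFit",
    "ClusterOrder",
    "pca",
    "fit_oplsda",
    "double_cv_q2",
    "permutation_test",
    "PermutationResult",
    "hierarchical_heatmap_order",
]


def _encode_labels(y):
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"expected exactly 2 classes, got {classes.size}")
    ym = np.where(y == classes[1], 1.0, -1.0)
    return ym, classes


class OPLSDA(ClassifierMixin, BaseEstimator):
    """Orthogonal projections to latent structures discriminant analysis.

    Binary classes are encoded -1/+1 and centered. ``n_orthogonal``
    y-orthogonal components are removed from centered X, then one predictive
    PLS component is fitted; with ``n_orthogonal=0`` the model reduces
    exactly to single-component PLS1-DA.

    Fitted attributes
    -----------------
    scores_, loadings_, weights_ : predictive component (t, p, w)
    orthogonal_scores_, orthogonal_loadings_, orthogonal_weights_ : (n, k), ...
    y_loading_ : regression scalar q with y_hat = t * q
    R2Y_ : fraction of class-label variance explained on the training data
    """

    def __init__(self, n_orthogonal: int = 1):
        self.n_orthogonal = n_orthogonal

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        ym, self.classes_ = _encode_labels(y)
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = ym.mean()
        E = X - self.x_mean_
        f = ym - self.y_mean_

        t_orth, p_orth, w_orth = [], [], []
        for _ in range(int(self.n_orthogonal)):
            w = E.T @ f
            nw = np.linalg.norm(w)
            if nw == 0:
                break
            w /= nw
            t = E @ w
            p = E.T @ t / (t @ t)
            wo = p - (w @ p) * w
            nwo = np.linalg.norm(wo)
            if nwo < 1e-12:  # no y-orthogonal structure left
                break
            wo /= nwo
            to = E @ wo
            po = E.T @ to / (to @ to)
            E = E - np.outer(to, po)
            t_orth.append(to)
            p_orth.append(po)
            w_orth.append(wo)

        w = E.T @ f
        nw = np.linalg.norm(w)
        if nw == 0:
            raise ValueError("X carries no covariance with the class labels")
        w /= nw
        t = E @ w
        p = E.T @ t / (t @ t)
        q = f @ t / (t @ t)

        self.weights_ = w
        self.scores_ = t
        self.loadings_ = p
        self.y_loading_ = float(q)
        self.orthogonal_scores_ = (
            np.column_stack(t_orth) if t_orth else np.zeros((X.shape[0], 0))
        )
        self.orthogonal_loadings_ = (
            np.column_stack(p_orth) if p_orth else np.zeros((X.shape[1], 0))
        )
        self.orthogonal_weights_ = (
            np.column_stack(w_orth) if w_orth else np.zeros((X.shape[1], 0))
        )
        self.n_orthogonal_ = self.orthogonal_scores_.shape[1]
        resid = f - t * q
        self.R2Y_ = float(1.0 - (resid @ resid) / (f @ f))
        return self

    def _deflate(self, X):
        E = np.asarray(X, dtype=float) - self.x_mean_
        t_orth = np.zeros((E.shape[0], self.n_orthogonal_))
        for k in range(self.n_orthogonal_):
            to = E @ self.orthogonal_weights_[:, k]
            E = E - np.outer(to, self.orthogonal_loadings_[:, k])
            t_orth[:, k] = to
        return E, t_orth

    def transform(self, X):
        """Predictive and orthogonal scores of new samples."""
        E, t_orth = self._deflate(X)
        return E @ self.weights_, t_orth

    def decision_function(self, X):
        t, _ = self.transform(X)
        return t * self.y_loading_ + self.y_mean_

    def predict(self, X):
        return np.where(self.decision_function(X) >= 0, self.classes_[1], self.classes_[0])


@dataclass
class ModelFit:
    """Summary of a fitted OPLS-DA model plus its validation statistics."""

    model: OPLSDA
    R2Y: float
    Q2: float | None = None
    p_R2Y: float | None = None
    p_Q2: float | None = None

    @property
    def n_orthogonal(self) -> int:
        return self.model.n_orthogonal_

    def summary(self) -> dict:
        return {
            "R2Y": self.R2Y,
            "Q2": self.Q2,
            "p_R2Y": self.p_R2Y,
            "p_Q2": self.p_Q2,
            "n_orthogonal": self.n_orthogonal,
        }


def fit_oplsda(X, y, n_orthogonal: int = 1) -> ModelFit:
    model = OPLSDA(n_orthogonal=n_orthogonal).fit(X, y)
    return ModelFit(model=model, R2Y=model.R2Y_)


def pca(X, n_components: int):
    """Centered PCA: (scores, loadings, explained variance fractions)."""
    X = np.asarray(X, dtype=float)
    rank = min(X.shape[0] - 1, X.shape[1])
    if n_components > rank:
        warnings.warn(
            f"n_components={n_components} exceeds the data rank {rank}; truncated",
            stacklevel=2,
        )
        n_components = rank
    model = _SkPCA(n_components=n_components, svd_solver="full").fit(X)
    return (
        model.transform(X),
        model.components_.T,
        model.explained_variance_ratio_,
    )


def _splitter(y, n_folds, rng):
    """Stratified folds, collapsing to leave-one-out on tiny classes."""
    y = np.asarray(y)
    min_class = min(np.sum(y == c) for c in np.unique(y))
    if min_class < n_folds:
        n = len(y)
        return [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)]
    skf = StratifiedKFold(
        n_splits=n_folds, shuffle=True, random_state=int(rng.integers(2**31 - 1))
    )
    return list(skf.split(np.zeros(len(y)), y))


def _press(X, y, n_orthogonal, splits):
    """Pooled squared prediction error of OPLS-DA over the given splits."""
    ym, _ = _encode_labels(y)
    press = 0.0
    for train, test in splits:
        model = OPLSDA(n_orthogonal=n_orthogonal).fit(X[train], np.asarray(y)[train])
        yhat = model.decision_function(X[test])
        press += float(np.sum((ym[test] - yhat) ** 2))
    return press


def double_cv_q2(
    X,
    y,
    outer_folds: int = 10,
    inner_folds: int = 10,
    seed: int = 0,
    max_orthogonal: int = 3,
) -> float:
    """Q2 from double (nested) ten-fold cross-validation.

    The outer loop holds every sample out at least once (folds collapse to
    leave-one-out when a class is smaller than the fold count); the inner
    loop, run on each outer-training set, picks the number of orthogonal
    components (0..``max_orthogonal``) minimizing inner prediction error.
    Q2 = 1 - PRESS/TSS over the pooled outer held-out predictions.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    ym, classes = _encode_labels(y)
    if min((y == c).sum() for c in classes) < 2:
        raise ValueError("double cross-validation needs >= 2 samples per class")
    rng = np.random.default_rng(seed)
    press = 0.0
    for train, test in _splitter(y, outer_folds, rng):
        inner = _splitter(y[train], inner_folds, rng)
        best_k, best_press = 0, np.inf
        for k in range(max_orthogonal + 1):
            try:
                pk = _press(X[train], y[train], k, inner)
            except ValueError:
                continue
            if pk < best_press - 1e-12:
                best_k, best_press = k, pk
        model = OPLSDA(n_orthogonal=best_k).fit(X[train], y[train])
        yhat = model.decision_function(X[test])
        press += float(np.sum((ym[test] - yhat) ** 2))
    tss = float(np.sum((ym - ym.mean()) ** 2))
    return 1.0 - press / tss


@dataclass
class PermutationResult:
    statistic: str
    observed: float
    permuted: np.ndarray
    p: float


def permutation_test(
    X,
    y,
    statistic: str = "R2Y",
    n_perm: int = 2000,
    seed: int = 0,
    n_orthogonal: int = 1,
    **dcv_kwargs,
) -> PermutationResult:
    """Permutation p-value for R2Y or Q2: p = (#{perm >= obs} + 1)/(n_perm + 1)."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)

    def stat(labels, s):
        if statistic == "R2Y":
            return OPLSDA(n_orthogonal=n_orthogonal).fit(X, labels).R2Y_
        if statistic == "Q2":
            return double_cv_q2(X, labels, seed=s, **dcv_kwargs)
        raise ValueError("statistic must be 'R2Y' or 'Q2'")

    observed = stat(y, int(rng.integers(2**31 - 1)))
    permuted = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(y)
        try:
            permuted[i] = stat(perm, int(rng.integers(2**31 - 1)))
        except ValueError:  # degenerate permutation (cannot happen for 2 classes)
            permuted[i] = -np.inf
    if np.allclose(permuted, permuted[0]):
        warnings.warn("permutation statistic is constant across permutations",
                      stacklevel=2)
    p = (float(np.sum(permuted >= observed)) + 1.0) / (n_perm + 1.0)
    return PermutationResult(statistic=statistic, observed=observed,
                             permuted=permuted, p=p)


@dataclass
class ClusterOrder:
    """Ward/Euclidean agglomeration of rows and columns for heat-map display."""

    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None
    row_order: list = field(default_factory=list)
    col_order: list = field(default_factory=list)


def hierarchical_heatmap_order(X) -> ClusterOrder:
    """Deterministic Ward-linkage ordering of samples and bins.

    Euclidean distance with Ward linkage on both axes (the defaults of the
    standard metabolomics heat-map tooling); a single row or column yields
    the trivial order.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D matrix")

    def one_axis(M):
        if M.shape[0] < 2:
            return None, list(range(M.shape[0]))
        Z = hierarchy.linkage(M, method="ward")
        return Z, list(hierarchy.leaves_list(Z))

    row_linkage, row_order = one_axis(X)
    col_linkage, col_order = one_axis(X.T)
    return ClusterOrder(row_linkage, col_linkage, row_order, col_order)
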