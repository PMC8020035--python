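"""ROC evaluation of candidate biomarker panels.

AUC is computed as the normalized Mann-Whitney U statistic (ties count one
half), which equals the area under the empirical ROC step curve; the 95%
confidence interval is a stratified percentile bootstrap. Panel accuracy
evaluates the nested heads of an ordered panel (top-1, top-2, ...) by
cross-validated single-component PLS1-DA classification with the decision
threshold chosen on each training fold by the Youden index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from ._plscv import auc_mann_whitney, make_splits
from .models import _encode_labels

__all__ = ["ROCResult", "roc_curve", "bootstrap_ci", "panel_accuracy"]


@dataclass
class ROCResult:
    """Empirical ROC step curve plus AUC and its bootstrap interval."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    ci: tuple | None = None
    n_bootstrap: int = 0
    seed: int | None = None
    accuracies: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "auc": self.auc,
                    "ci": list(self.ci) if self.ci else None,
                    "n_bootstrap": self.n_bootstrap,
                    "seed": self.seed,
                    "accuracies": list(self.accuracies),
                    "fpr": self.fpr.tolist(),
                    "tpr": self.tpr.tolist(),
                },
                fh,
                indent=1,
            )


def roc_curve(scores, labels) -> ROCResult:
    """Empirical ROC curve and tie-aware AUC for real-valued scores.

    The curve starts at (0, 0) and ends at (1, 1) with both coordinates
    non-decreasing; the AUC equals exhaustive pair counting with ties
    weighted one half, and is invariant under strictly monotone transforms
    of the scores.
    """
    scores = np.asarray(scores, dtype=float)
    ym, _ = _encode_labels(labels)
    fpr, tpr, _ = _sk_roc_curve((ym > 0).astype(int), scores)
    if fpr[0] != 0.0 or tpr[0] != 0.0:
        fpr = np.concatenate([[0.0], fpr])
        tpr = np.concatenate([[0.0], tpr])
    return ROCResult(fpr=fpr, tpr=tpr, auc=auc_mann_whitney(scores, ym))


def bootstrap_ci(scores, labels, n_boot: int = 2000, level: float = 0.95,
                 seed: int = 0) -> tuple:
    """Stratified percentile bootstrap interval for the AUC.

    Samples are resampled with replacement within each class (so no
    resample loses a class); the interval is the percentile interval of the
    resampled AUCs at the requested level.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    scores = np.asarray(scores, dtype=float)
    ym, _ = _encode_labels(labels)
    pos = np.flatnonzero(ym > 0)
    neg = np.flatnonzero(ym <= 0)
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [rng.choice(pos, size=pos.size), rng.choice(neg, size=neg.size)]
        )
        aucs[b] = auc_mann_whitney(scores[idx], ym[idx])
    lo = (1.0 - level) / 2.0
    return (
        float(np.quantile(aucs, lo)),
        float(np.quantile(aucs, 1.0 - lo)),
    )


def _youden_threshold(scores, ym) -> float:
    """Midpoint threshold maximizing TPR - FPR on the given scores."""
    order = np.argsort(scores)
    s = scores[order]
    labels = ym[order] > 0
    candidates = [s[0] - 1.0]
    candidates += [(a + b) / 2.0 for a, b in zip(s[:-1], s[1:])]
    candidates.append(s[-1] + 1.0)
    n_pos = max(int(labels.sum()), 1)
    n_neg = max(int((~labels).sum()), 1)
    best_t, best_j = candidates[0], -np.inf
    for t in candidates:
        pred = scores >= t
        tpr = np.sum(pred & (ym > 0)) / n_pos
        fpr = np.sum(pred & (ym <= 0)) / n_neg
        j = tpr - fpr
        if j > best_j + 1e-12:
            best_t, best_j = t, j
    return best_t


def panel_accuracy(X, y, panel, folds: int = 10, seed: int = 0) -> list:
    """Cross-validated accuracy of each nested head of an ordered panel.

    For k = 1..len(panel), held-out samples are classified by the
    single-component PLS1-DA score on the first k panel bins, thresholded
    at the training-fold Youden point; the pooled accuracy is returned per
    k.
    """
    X = np.asarray(X, dtype=float)
    panel = np.asarray(panel, dtype=int)
    if panel.size == 0:
        raise ValueError("panel must be nonempty")
    if panel.max() >= X.shape[1] or panel.min() < 0:
        raise ValueError("panel references a bin missing from the matrix")
    ym, _ = _encode_labels(y)
    accuracies = []
    for k in range(1, panel.size + 1):
        Xk = X[:, panel[:k]]
        splits = make_splits(y, folds, np.random.default_rng(seed))
        correct = 0
        for train, test in splits:
            mean = Xk[train].mean(axis=0)
            yc = ym[train] - ym[train].mean()
            w = (Xk[train] - mean).T @ yc
            nw = np.linalg.norm(w)
            if nw == 0.0:
                pred = np.full(test.size, ym[train].mean() >= 0)
            else:
                w /= nw
                train_scores = (Xk[train] - mean) @ w
                thr = _youden_threshold(train_scores, ym[train])
                pred = (Xk[test] - mean) @ w >= thr
            correct += int(np.sum(pred == (ym[test] > 0)))
        accuracies.append(correct / len(y))
    return accuracies
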