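"""Internal single-component PLS1-DA cross-validation machinery.

Shared by the VIAVC selector and the biomarker-panel evaluator: both score
candidate bin subsets with the pooled held-out decision values of a
one-component PLS1 regression on -1/+1 encoded labels.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .models import _encode_labels, _splitter

__all__ = ["cv_plsda_scores", "auc_mann_whitney", "make_splits"]


def make_splits(y, folds: int, rng) -> list:
    """Stratified k-fold splits, collapsing to leave-one-out on tiny classes."""
    return _splitter(y, folds, rng)


def cv_plsda_scores(X, ym, splits) -> np.ndarray:
    """Pooled held-out decision values of single-component PLS1-DA.

    ``ym`` must already be -1/+1 encoded; orientation of the returned scores
    therefore follows the label encoding (an informative subset scores the
    +1 class higher), so downstream AUCs are directly comparable across
    subsets without any flipping convention.
    """
    X = np.asarray(X, dtype=float)
    yhat = np.empty(X.shape[0])
    for train, test in splits:
        Xt = X[train]
        mean = Xt.mean(axis=0)
        ybar = ym[train].mean()
        yc = ym[train] - ybar
        w = (Xt - mean).T @ yc
        nw = np.linalg.norm(w)
        if nw == 0.0:
            yhat[test] = ybar
            continue
        w /= nw
        t = (Xt - mean) @ w
        q = (yc @ t) / (t @ t)
        yhat[test] = q * ((X[test] - mean) @ w) + ybar
    return yhat


def auc_mann_whitney(scores, ym) -> float:
    """AUC as the normalized Mann-Whitney U statistic; ties count one half."""
    scores = np.asarray(scores, dtype=float)
    pos = scores[ym > 0]
    neg = scores[ym <= 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))
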