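"""Shapiro-Wilk-routed paired testing of every bin between timepoints.

For each bin the within-subject differences (T2 - T1) are tested for
normality with Shapiro-Wilk; normal-looking differences go to the paired
t-test, the rest to the Wilcoxon signed-rank test. For small cohorts the
signed-rank p-value is exact: the null distribution of W+ over all 2^n sign
assignments is built by dynamic programming over (possibly tied) midranks,
which is identical to brute-force enumeration but polynomial in n.

No multiplicity correction is applied here: the paired screen feeds the
multivariate stages with its raw significant set, and the correlation
module applies its own Bonferroni control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .preprocess import ProcessedMatrix

__all__ = [
    "BinTestResult",
    "exact_signed_rank",
    "route_and_test",
    "test_all_bins",
    "paired_differences",
]


@dataclass(frozen=True)
class BinTestResult:
    bin_id: str
    test: str  # "paired-t" | "wilcoxon-signed-rank" | "untestable"
    statistic: float
    p: float
    direction: int  # sign of the mean paired difference

    @property
    def untestable(self) -> bool:
        return self.test == "untestable"


def exact_signed_rank(differences) -> tuple[float, float]:
    """Exact two-sided Wilcoxon signed-rank test via sign-flip enumeration.

    Zeros are discarded; |d| are midranked (ties allowed). The null
    distribution of W+ = sum of ranks of positive differences over all 2^n
    equiprobable sign assignments is accumulated by dynamic programming on
    doubled midranks (integers), so it equals literal enumeration exactly.
    Returns (W+, two-sided p) with p = min(1, 2*min(P(W<=w), P(W>=w))).
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero")
    ranks = stats.rankdata(np.abs(d))
    r2 = np.rint(2 * ranks).astype(int)  # doubled midranks are integers
    w_plus2 = int(r2[d > 0].sum())
    total = int(r2.sum())

    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    counts /= counts.sum()

    cdf = counts[: w_plus2 + 1].sum()
    sf = counts[w_plus2:].sum()
    p = min(1.0, 2.0 * min(cdf, sf))
    return w_plus2 / 2.0, float(p)


def route_and_test(pairs, alpha_normality: float = 0.05, bin_id: str = "") -> BinTestResult:
    """Test one bin's per-subject (T1, T2) pairs, routing on normality.

    Shapiro-Wilk is applied to the paired differences (the quantity whose
    normality the paired t-test assumes); p > ``alpha_normality`` routes to
    the paired t-test, otherwise to the exact Wilcoxon signed-rank test
    (normal approximation beyond n = 25). Identical differences (including
    the all-zero case) make both routes degenerate and are reported
    untestable rather than forced through either test.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array of (T1, T2) values")
    if np.any(~np.isfinite(pairs)):
        raise ValueError("missing pair values")
    if pairs.shape[0] < 3:
        raise ValueError("need at least 3 complete pairs")
    d = pairs[:, 1] - pairs[:, 0]
    direction = int(np.sign(d.mean()))
    if np.allclose(d, d[0]):
        return BinTestResult(bin_id, "untestable", np.nan, np.nan, direction)

    shapiro_p = stats.shapiro(d).pvalue
    if shapiro_p > alpha_normality:
        res = stats.ttest_rel(pairs[:, 1], pairs[:, 0])
        return BinTestResult(bin_id, "paired-t", float(res.statistic), float(res.pvalue), direction)
    if d.size <= 25:
        w, p = exact_signed_rank(d)
    else:
        res = stats.wilcoxon(d, method="approx")
        w, p = float(res.statistic), float(res.pvalue)
    return BinTestResult(bin_id, "wilcoxon-signed-rank", w, p, direction)


def paired_differences(matrix: ProcessedMatrix) -> tuple[np.ndarray, list]:
    """(n_subjects, n_bins) T2 - T1 difference matrix and the subject order."""
    subjects = list(dict.fromkeys(matrix.subjects))
    tps = sorted(set(matrix.timepoints))
    if len(tps) != 2:
        raise ValueError("paired design requires exactly two timepoints")
    index = {(s, t): i for i, (s, t) in enumerate(zip(matrix.subjects, matrix.timepoints))}
    rows = []
    for s in subjects:
        if (s, tps[0]) not in index or (s, tps[1]) not in index:
            raise ValueError(f"subject {s} is missing a timepoint")
        rows.append(matrix.data[index[(s, tps[1])]] - matrix.data[index[(s, tps[0])]])
    return np.vstack(rows), subjects


def test_all_bins(matrix: ProcessedMatrix, alpha: float = 0.05,
                  alpha_normality: float = 0.05):
    """Route-and-test every bin; return (all results, significant bin ids)."""
    subjects = list(dict.fromkeys(matrix.subjects))
    tps = sorted(set(matrix.timepoints))
    if len(tps) != 2:
        raise ValueError("paired design requires exactly two timepoints")
    index = {(s, t): i for i, (s, t) in enumerate(zip(matrix.subjects, matrix.timepoints))}
    for s in subjects:
        for t in tps:
            if (s, t) not in index:
                raise ValueError(f"subject {s} is missing timepoint {t}")

    results = []
    for j, bin_id in enumerate(matrix.bin_ids):
        pairs = np.array(
            [
                (matrix.data[index[(s, tps[0])], j], matrix.data[index[(s, tps[1])], j])
                for s in subjects
            ]
        )
        results.append(route_and_test(pairs, alpha_normality=alpha_normality, bin_id=bin_id))
    significant = [r.bin_id for r in results if not r.untestable and r.p < alpha]
    return results, significant
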