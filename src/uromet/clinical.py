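"""Clinical-score analysis: SCIM %-difference and biomarker correlations.

The Spinal Cord Independence Measure (SCIM) is a 0-100 functional-
independence score assessed here at two timepoints per subject. Recovery
is summarized by the symmetric percent difference

    100 * (post - pre) / ((post + pre) / 2)

and screened against urinary metabolite levels two ways: the *initial*
normalized bin level (can the first collection predict recovery?) and the
*delta* between collections (does the change track recovery?). Each
predictor family is Pearson-correlated with the %-difference and
Bonferroni-controlled over the tested bin list (by convention the top
F-ranked bins from the VIAVC screen).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClinicalRecord",
    "CorrelationResult",
    "load_clinical",
    "load_example_cohort",
    "scim_pct_diff",
    "improvement_summary",
    "metabolite_delta",
    "correlate_biomarkers",
]

CLINICAL_COLUMNS = [
    "subject", "sci_type", "asia", "lesion", "comorbidities",
    "age", "scim_pre", "scim_post",
]


@dataclass(frozen=True)
class ClinicalRecord:
    subject: str
    sci_type: str
    asia: str
    lesion: str
    comorbidities: str
    age: float
    scim_pre: float
    scim_post: float

    def __post_init__(self) -> None:
        for v in (self.scim_pre, self.scim_post):
            if not 0.0 <= v <= 100.0:
                raise ValueError("SCIM scores must lie in [0, 100]")


def load_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table is missing columns: {missing}")
    df["comorbidities"] = df["comorbidities"].fillna("")
    return df[CLINICAL_COLUMNS]


def load_example_cohort() -> pd.DataFrame:
    """Bundled six-subject paired cohort characteristics table.

    A small example of the clinical input format: six male subjects with
    complete or incomplete spinal cord injury, their ASIA grade, lesion
    location, age, and SCIM at one month and six months post-injury.
    """
    with importlib.resources.as_file(
        importlib.resources.files("uromet.data") / "example_cohort.csv"
    ) as p:
        return load_clinical(p)


def scim_pct_diff(pre: float, post: float) -> float:
    """Symmetric percent difference of two scores: 100*(post-pre)/mean."""
    if pre + post <= 0:
        raise ValueError("pre + post must be positive")
    return 100.0 * (post - pre) / ((post + pre) / 2.0)


def improvement_summary(records) -> tuple:
    """Mean and sample SD of the raw point improvement (post - pre).

    Accepts a clinical DataFrame or a list of :class:`ClinicalRecord`;
    values are reported to one decimal, the convention for SCIM summaries.
    """
    if isinstance(records, pd.DataFrame):
        diffs = (records["scim_post"] - records["scim_pre"]).to_numpy(float)
    else:
        records = list(records)
        diffs = np.array([r.scim_post - r.scim_pre for r in records], dtype=float)
    if diffs.size < 2:
        raise ValueError("need at least 2 records")
    return round(float(diffs.mean()), 1), round(float(diffs.std(ddof=1)), 1)


def metabolite_delta(initial, post, convention: str = "initial-minus-post"):
    """Change in normalized level between collections.

    The default convention subtracts the post-injury level from the initial
    level (delta = initial - post); ``convention="post-minus-initial"``
    gives the opposite sign. Works element-wise on scalars, arrays and
    DataFrames alike.
    """
    if convention == "initial-minus-post":
        return initial - post
    if convention == "post-minus-initial":
        return post - initial
    raise ValueError(f"unknown delta convention {convention!r}")


@dataclass(frozen=True)
class CorrelationResult:
    bin_id: str
    predictor: str  # "initial" | "delta"
    r: float
    p: float
    threshold: float
    significant: bool


def _pearson(x: np.ndarray, yv: np.ndarray):
    if np.std(x) == 0.0 or np.std(yv) == 0.0:
        return np.nan, np.nan
    res = stats.pearsonr(x, yv)
    return float(res.statistic), float(res.pvalue)


def correlate_biomarkers(
    initial: pd.DataFrame,
    delta: pd.DataFrame,
    pct_diffs: pd.Series,
    tested_bins,
    alpha: float = 0.05,
    pooled: bool = False,
):
    """Bonferroni-screened Pearson correlations of SCIM recovery vs bins.

    ``initial`` and ``delta`` are subjects x bins DataFrames of normalized
    levels and their between-timepoint changes; ``pct_diffs`` is the
    per-subject SCIM percent difference. Each predictor family (initial,
    delta) is tested over ``tested_bins`` at the per-family Bonferroni
    threshold alpha/len(tested_bins) (``pooled=True`` divides by twice
    that, a single family over both). p-values use the exact t-transform
    with n-2 degrees of freedom. Results are sorted by |R| descending;
    zero-variance predictors yield an undefined (NaN) R, never significant.
    """
    tested_bins = list(tested_bins)
    if not tested_bins:
        raise ValueError("tested_bins must be nonempty")
    subjects = list(pct_diffs.index)
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects")
    n_tests = len(tested_bins) * (2 if pooled else 1)
    threshold = alpha / n_tests
    yv = pct_diffs.to_numpy(float)

    results = []
    for predictor, frame in (("initial", initial), ("delta", delta)):
        for b in tested_bins:
            if b not in frame.columns:
                raise KeyError(f"bin {b!r} missing from the {predictor} matrix")
            r, p = _pearson(frame.loc[subjects, b].to_numpy(float), yv)
            results.append(
                CorrelationResult(
                    bin_id=b,
                    predictor=predictor,
                    r=r,
                    p=p,
                    threshold=threshold,
                    significant=bool(np.isfinite(p) and p < threshold),
                )
            )
    results.sort(key=lambda c: (-(abs(c.r) if np.isfinite(c.r) else -1.0), c.bin_id))
    return results
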