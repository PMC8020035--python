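"""Bin-table preprocessing: total-metabolome normalization, log, pareto.

The fixed preprocessing order for paired urine bin tables is

    normalize to total metabolome (water/urea-region bins excluded)
    -> log10 with a half-minimum offset
    -> pareto scaling (mean-center, divide by sqrt of the sample SD).

Each step is an sklearn-style transformer so the chain composes with
``sklearn.pipeline``; :func:`preprocess` runs the whole chain on a
:class:`~uromet.spectra.BinTable` and returns a :class:`ProcessedMatrix`
carrying everything needed to invert or audit the scaling.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .spectra import BinTable

__all__ = [
    "TotalAreaNormalizer",
    "Log10Shift",
    "ParetoScaler",
    "ProcessedMatrix",
    "normalize_total",
    "log_transform",
    "pareto_scale",
    "preprocess",
]


class TotalAreaNormalizer(TransformerMixin, BaseEstimator):
    """Row-normalize each sample to its total retained-bin signal.

    Stateless: each row is divided by its own sum, so every transformed row
    sums to one and within-sample ratios are preserved. Rows with a
    non-positive total are rejected (a urine spectrum with no retained
    signal is not interpretable).
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X, sample_ids=None):
        X = np.asarray(X, dtype=float)
        totals = X.sum(axis=1)
        bad = np.flatnonzero(totals <= 0)
        if bad.size:
            names = (
                ", ".join(str(sample_ids[i]) for i in bad)
                if sample_ids is not None
                else ", ".join(f"row {i}" for i in bad)
            )
            raise ValueError(f"zero retained total for sample(s): {names}")
        return X / totals[:, None]


class Log10Shift(TransformerMixin, BaseEstimator):
    """x -> log10(x + eps) with eps = half the smallest positive value seen in fit.

    Monotone and zero-safe; negative inputs are rejected. The fitted offset
    ``epsilon_`` is recorded for provenance.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if np.any(X < 0):
            raise ValueError("log transform requires non-negative values")
        pos = X[X > 0]
        self.epsilon_ = float(pos.min() / 2.0) if pos.size else 1.0
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if np.any(X < 0):
            raise ValueError("log transform requires non-negative values")
        return np.log10(X + self.epsilon_)


class ParetoScaler(TransformerMixin, BaseEstimator):
    """Mean-center each column and divide by the square root of its sample SD.

    Pareto scaling damps the dominance of high-abundance bins less
    aggressively than unit-variance scaling: the scaled column variance
    equals the original SD rather than one. Columns with zero SD carry no
    information and are dropped (``retained_`` marks the survivors).
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("pareto scaling needs at least 2 samples")
        self.mean_ = X.mean(axis=0)
        self.sd_ = X.std(axis=0, ddof=1)
        self.retained_ = self.sd_ > 0
        if not np.all(self.retained_):
            warnings.warn(
                f"dropping {int((~self.retained_).sum())} zero-variance column(s)",
                stacklevel=2,
            )
        self.scale_ = np.sqrt(self.sd_[self.retained_])
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return (X[:, self.retained_] - self.mean_[self.retained_]) / self.scale_

    def inverse_transform(self, X):
        return np.asarray(X, dtype=float) * self.scale_ + self.mean_[self.retained_]


@dataclass
class ProcessedMatrix:
    """Fully preprocessed samples x bins matrix plus scaling provenance."""

    data: np.ndarray
    bin_ids: list
    sample_ids: list
    subjects: list
    timepoints: list
    means: np.ndarray
    sds: np.ndarray
    epsilon: float
    excluded_bins: list = field(default_factory=list)
    dropped_bins: list = field(default_factory=list)
    normalized: np.ndarray | None = None  # row-normalized matrix pre log/pareto
    normalized_bin_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.data)):
            raise ValueError("processed matrix must be finite")

    @property
    def labels(self) -> np.ndarray:
        return np.asarray(self.timepoints)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data, index=self.sample_ids, columns=self.bin_ids)
        df.insert(0, "subject", self.subjects)
        df.insert(1, "timepoint", self.timepoints)
        return df

    def to_csv(self, path, sidecar=None) -> None:
        self.to_frame().to_csv(path, index_label="sample")
        if sidecar is not None:
            with open(sidecar, "w") as fh:
                json.dump(
                    {
                        "means": self.means.tolist(),
                        "sds": self.sds.tolist(),
                        "epsilon": self.epsilon,
                        "excluded_bins": list(self.excluded_bins),
                        "dropped_bins": list(self.dropped_bins),
                    },
                    fh,
                    indent=1,
                )


def load_processed(path, sidecar, normalized_csv=None) -> ProcessedMatrix:
    """Round-trip a :class:`ProcessedMatrix` back from its CSV + JSON sidecar."""
    df = pd.read_csv(path, index_col="sample")
    subjects = df.pop("subject").tolist()
    timepoints = df.pop("timepoint").astype(str).tolist()
    with open(sidecar) as fh:
        meta = json.load(fh)
    normalized, norm_ids = None, []
    if normalized_csv is not None:
        ndf = pd.read_csv(normalized_csv, index_col=0)
        normalized = ndf.to_numpy(float)
        norm_ids = list(ndf.columns)
    return ProcessedMatrix(
        data=df.to_numpy(float),
        bin_ids=list(df.columns),
        sample_ids=df.index.tolist(),
        subjects=subjects,
        timepoints=timepoints,
        means=np.asarray(meta["means"], dtype=float),
        sds=np.asarray(meta["sds"], dtype=float),
        epsilon=float(meta["epsilon"]),
        excluded_bins=list(meta.get("excluded_bins", [])),
        dropped_bins=list(meta.get("dropped_bins", [])),
        normalized=normalized,
        normalized_bin_ids=norm_ids,
    )


def normalize_total(table: BinTable, excluded=None) -> BinTable:
    """Drop excluded bins and divide each sample by its retained-bin total.

    ``excluded`` defaults to the bin set's own noise/exclusion flags (water
    and urea regions are marked there via
    :func:`uromet.spectra.exclude_regions`).
    """
    retain = table.bins.retained if excluded is None else np.array(
        [i not in set(excluded) for i in range(len(table.bins))]
    )
    data = table.data[:, retain]
    norm = TotalAreaNormalizer().fit(data).transform(data, sample_ids=table.sample_ids)
    from .spectra import BinSet

    bins = BinSet(
        edges=table.bins.edges[retain],
        index=table.bins.index[retain],
        is_noise=np.zeros(int(retain.sum()), dtype=bool),
        params=dict(table.bins.params),
    )
    return BinTable(
        data=norm,
        bins=bins,
        sample_ids=list(table.sample_ids),
        subjects=list(table.subjects),
        timepoints=list(table.timepoints),
    )


def log_transform(X):
    """Functional form of :class:`Log10Shift` (fit and transform in one)."""
    t = Log10Shift().fit(X)
    return t.transform(X), t.epsilon_


def pareto_scale(X):
    """Functional form of :class:`ParetoScaler`; returns (scaled, scaler)."""
    scaler = ParetoScaler().fit(X)
    return scaler.transform(X), scaler


def preprocess(table: BinTable, excluded=None) -> ProcessedMatrix:
    """normalize -> log10 -> pareto on a bin table, with provenance."""
    all_ids = table.bin_ids
    retain_mask = table.bins.retained if excluded is None else np.array(
        [i not in set(excluded) for i in range(len(table.bins))]
    )
    excluded_ids = [bid for bid, keep in zip(all_ids, retain_mask) if not keep]
    retained_ids = [bid for bid, keep in zip(all_ids, retain_mask) if keep]

    norm_table = normalize_total(table, excluded=excluded)
    logged, eps = log_transform(norm_table.data)
    scaler = ParetoScaler().fit(logged)
    scaled = scaler.transform(logged)
    kept = scaler.retained_
    return ProcessedMatrix(
        data=scaled,
        bin_ids=[b for b, k in zip(retained_ids, kept) if k],
        sample_ids=list(table.sample_ids),
        subjects=list(table.subjects),
        timepoints=list(table.timepoints),
        means=scaler.mean_[kept],
        sds=scaler.sd_[kept],
        epsilon=eps,
        excluded_bins=excluded_ids,
        dropped_bins=[b for b, k in zip(retained_ids, kept) if not k],
        normalized=norm_table.data,
        normalized_bin_ids=retained_ids,
    )
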