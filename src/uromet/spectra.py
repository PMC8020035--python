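"""Post-acquisition spectral processing for 1D frequency-domain NMR.

Spectra enter this module already Fourier-transformed, phased and
baseline-corrected; what remains before statistics is the reduction of each
spectrum to a vector of bin integrals on a common chemical-shift grid:

1. recursive segment-wise alignment of every spectrum to a reference, to
   remove sample-to-sample positional noise (pH- and ionic-strength-driven
   drift of peak positions);
2. adaptive binning of the cohort mean spectrum — bin boundaries are placed
   at troughs of the smoothed mean so that multiplets are not split across
   bins;
3. trapezoidal integration of every sample over the shared bin edges.

A reproducible "manual edit" step (merge / split / exclude directives)
replaces interactive bin curation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "BinSet",
    "BinTable",
    "SegmentShift",
    "align_to_reference",
    "adaptive_bin",
    "integrate",
    "apply_manual_edits",
    "exclude_regions",
    "mean_spectrum",
]


@dataclass
class Spectrum:
    """A single 1D spectrum: chemical-shift axis (ppm) plus real intensities."""

    ppm: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    subject: str = ""
    timepoint: str = ""

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.ppm.shape != self.intensity.shape:
            raise ValueError("ppm and intensity must be 1-D arrays of equal length")
        d = np.diff(self.ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm axis must be strictly monotone")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")

    @property
    def ascending(self) -> bool:
        return bool(self.ppm[1] > self.ppm[0])

    def to_csv(self, path) -> None:
        pd.DataFrame({"ppm": self.ppm, "intensity": self.intensity}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, sample_id: str = "", subject: str = "", timepoint: str = "") -> "Spectrum":
        df = pd.read_csv(path)
        return cls(
            ppm=df["ppm"].to_numpy(),
            intensity=df["intensity"].to_numpy(),
            sample_id=sample_id,
            subject=subject,
            timepoint=timepoint,
        )


def _check_common_axis(spectra) -> np.ndarray:
    axis = spectra[0].ppm
    for s in spectra[1:]:
        if s.ppm.shape != axis.shape or not np.allclose(s.ppm, axis, rtol=0, atol=1e-12):
            raise ValueError("all spectra must share an identical ppm axis")
    return axis


def mean_spectrum(spectra) -> Spectrum:
    """Point-wise mean of a cohort of spectra on a common axis."""
    axis = _check_common_axis(list(spectra))
    stack = np.vstack([s.intensity for s in spectra])
    return Spectrum(ppm=axis, intensity=stack.mean(axis=0), sample_id="mean")


# ---------------------------------------------------------------------------
# Recursive segment-wise alignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SegmentShift:
    """One leaf segment of the recursive alignment: [start, stop) in points."""

    start: int
    stop: int
    shift: int
    correlation: float
    aligned: bool


def _shift_with_edge_padding(seg: np.ndarray, shift: int) -> np.ndarray:
    if shift == 0:
        return seg.copy()
    if shift > 0:
        return np.concatenate([np.full(shift, seg[0]), seg[:-shift]])
    return np.concatenate([seg[-shift:], np.full(-shift, seg[-1])])


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(a @ b / (na * nb))


def _best_shift(seg: np.ndarray, ref: np.ndarray, max_pts: int):
    """Integer shift in [-max_pts, max_pts] maximizing correlation with *ref*.

    Ties are broken toward the smaller absolute shift (zero first), so the
    search enumerates shifts by increasing |shift| and only a strictly larger
    correlation replaces the incumbent.
    """
    best_s, best_c = 0, _corr(seg, ref)
    zero_c = best_c
    for mag in range(1, max_pts + 1):
        for s in (mag, -mag):
            c = _corr(_shift_with_edge_padding(seg, s), ref)
            if c > best_c + 1e-15:
                best_s, best_c = s, c
    return best_s, best_c, zero_c


def align_to_reference(
    spectrum: Spectrum,
    reference: Spectrum,
    max_shift: float = 0.03,
    min_segment: int = 64,
    tol: float = 1e-3,
    min_corr: float = 0.6,
    return_segments: bool = False,
):
    """Recursive segment-wise peak alignment of one spectrum to a reference.

    The spectrum is recursively split at the lowest-intensity point of the
    current segment; a terminal segment (shorter than ``2 * min_segment``, or
    one whose best in-window correlation gain over no shift is below ``tol``)
    is shifted by the integer-point offset maximizing cross-correlation with
    the reference within ``±max_shift`` ppm, with gaps filled by edge-value
    padding. Segments whose best achievable correlation stays below
    ``min_corr`` are left unshifted and flagged as unalignable.

    Parameters
    ----------
    max_shift : float
        Search window half-width in ppm.
    min_segment : int
        Minimum segment length in points; segments are not split below
        ``2 * min_segment``.
    """
    _check_common_axis([spectrum, reference])
    if max_shift <= 0:
        raise ValueError("max_shift must be > 0")
    step = abs(float(spectrum.ppm[1] - spectrum.ppm[0]))
    max_pts = max(1, int(round(max_shift / step)))

    x = spectrum.intensity.copy()
    ref = reference.intensity
    out = x.copy()
    segments: list[SegmentShift] = []

    def leaf(lo: int, hi: int) -> None:
        s, c, _ = _best_shift(x[lo:hi], ref[lo:hi], max_pts)
        if c < min_corr:
            segments.append(SegmentShift(lo, hi, 0, c, aligned=False))
            out[lo:hi] = x[lo:hi]
        else:
            segments.append(SegmentShift(lo, hi, s, c, aligned=True))
            out[lo:hi] = _shift_with_edge_padding(x[lo:hi], s)

    def recurse(lo: int, hi: int) -> None:
        n = hi - lo
        if n < 2 * min_segment:
            leaf(lo, hi)
            return
        s, c, c0 = _best_shift(x[lo:hi], ref[lo:hi], max_pts)
        if c - c0 <= tol and s == 0:
            leaf(lo, hi)
            return
        # split at the lowest-intensity interior point, away from the borders
        interior = x[lo + min_segment : hi - min_segment]
        cut = lo + min_segment + int(np.argmin(interior))
        recurse(lo, cut)
        recurse(cut, hi)

    recurse(0, x.size)
    aligned = replace(spectrum, intensity=out)
    if return_segments:
        return aligned, sorted(segments, key=lambda g: g.start)
    return aligned


# ---------------------------------------------------------------------------
# Adaptive binning
# ---------------------------------------------------------------------------


@dataclass
class BinSet:
    """Bin edges on the ppm axis plus per-bin noise / exclusion flags.

    Edges are half-open ``[lo, hi)`` intervals stored ascending and
    non-overlapping; ``index`` holds the corresponding (start, stop) point
    indices on the ascending-sorted axis, with adjacent bins sharing a
    boundary point so that integrals are exactly additive.
    """

    edges: np.ndarray  # (n_bins, 2) ppm, ascending
    index: np.ndarray  # (n_bins, 2) int positions on the ascending axis
    is_noise: np.ndarray  # bool, entirely-below-threshold bins
    is_excluded: np.ndarray = None  # bool, manual / region exclusions
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float).reshape(-1, 2)
        self.index = np.asarray(self.index, dtype=int).reshape(-1, 2)
        self.is_noise = np.asarray(self.is_noise, dtype=bool)
        if self.is_excluded is None:
            self.is_excluded = np.zeros(len(self.edges), dtype=bool)
        self.is_excluded = np.asarray(self.is_excluded, dtype=bool)
        if np.any(self.edges[:, 1] <= self.edges[:, 0]):
            raise ValueError("each bin must satisfy lo < hi")
        if np.any(self.edges[1:, 0] < self.edges[:-1, 1] - 1e-12):
            raise ValueError("bins must be sorted and non-overlapping")

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def retained(self) -> np.ndarray:
        """Signal bins that survive noise and manual exclusion."""
        return ~(self.is_noise | self.is_excluded)

    @property
    def widths(self) -> np.ndarray:
        return self.edges[:, 1] - self.edges[:, 0]

    def to_json(self, path) -> None:
        payload = {
            "edges": self.edges.tolist(),
            "index": self.index.tolist(),
            "is_noise": self.is_noise.tolist(),
            "is_excluded": self.is_excluded.tolist(),
            "params": self.params,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "BinSet":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            edges=np.array(d["edges"]),
            index=np.array(d["index"]),
            is_noise=np.array(d["is_noise"], dtype=bool),
            is_excluded=np.array(d["is_excluded"], dtype=bool),
            params=d.get("params", {}),
        )


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y.astype(float)
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.concatenate([np.full(pad, y[0]), y, np.full(pad, y[-1])])
    out = np.convolve(padded, kernel, mode="valid")
    return out[: y.size]


def adaptive_bin(
    spectrum: Spectrum,
    min_width: float = 0.02,
    noise_threshold: float | None = None,
    smooth_window: int = 11,
) -> BinSet:
    """Adaptive binning of a (mean) spectrum: boundaries at smoothed troughs.

    The intensity trace is smoothed with a moving average of ``smooth_window``
    points and bin boundaries are placed at its interior local minima. Bins
    whose smoothed maximum stays below ``noise_threshold`` are flagged as
    noise bins (excluded from the metabolome but still reported); adjacent
    noise bins are coalesced. Any bin narrower than ``min_width`` ppm is
    merged with a neighbour, preferentially across its weaker (higher-valued)
    trough and into a bin of the same noise classification.

    ``noise_threshold`` defaults to 3x the median absolute deviation of the
    smoothed trace around its median — a robust noise-floor estimate.
    """
    ppm = spectrum.ppm
    y = spectrum.intensity
    order = np.argsort(ppm)
    ppm = ppm[order]
    y = y[order]
    span = ppm[-1] - ppm[0]
    if min_width >= span:
        raise ValueError("min_width must be smaller than the spectral window")

    s = _moving_average(y, smooth_window)
    if noise_threshold is None:
        med = np.median(s)
        noise_threshold = float(med + 3.0 * np.median(np.abs(s - med)) * 1.4826)

    # interior local minima: strict on the left, permissive on the right so a
    # flat trace yields no boundaries and plateaus contribute a single trough
    i = np.arange(1, s.size - 1)
    minima = i[(s[i] < s[i - 1]) & (s[i] <= s[i + 1])]
    bounds = np.concatenate([[0], minima, [s.size - 1]])
    bounds = np.unique(bounds)

    idx = np.column_stack([bounds[:-1], bounds[1:]])
    is_noise = np.array([s[a : b + 1].max() < noise_threshold for a, b in idx])

    def merge(k: int, j: int):
        nonlocal idx, is_noise
        a, b = min(k, j), max(k, j)
        merged = np.array([idx[a, 0], idx[b, 1]])
        new_noise = s[merged[0] : merged[1] + 1].max() < noise_threshold
        idx = np.vstack([idx[:a], merged, idx[b + 1 :]])
        is_noise = np.concatenate([is_noise[:a], [new_noise], is_noise[b + 1 :]])

    # coalesce runs of noise bins
    k = 0
    while k < len(idx) - 1:
        if is_noise[k] and is_noise[k + 1]:
            merge(k, k + 1)
        else:
            k += 1

    # enforce the minimum bin width
    def width(k: int) -> float:
        return ppm[idx[k, 1]] - ppm[idx[k, 0]]

    while len(idx) > 1:
        narrow = [k for k in range(len(idx)) if width(k) < min_width]
        if not narrow:
            break
        k = min(narrow, key=width)  # narrowest first; ties toward the left
        neighbours = [j for j in (k - 1, k + 1) if 0 <= j < len(idx)]
        same = [j for j in neighbours if is_noise[j] == is_noise[k]]
        pool = same if same else neighbours
        # merge across the weaker trough (higher smoothed boundary value)
        j = max(pool, key=lambda j: s[idx[k, 0]] if j < k else s[idx[k, 1]])
        merge(k, j)

    edges = np.column_stack([ppm[idx[:, 0]], ppm[idx[:, 1]]])
    return BinSet(
        edges=edges,
        index=idx,
        is_noise=is_noise,
        params={
            "min_width": float(min_width),
            "noise_threshold": float(noise_threshold),
            "smooth_window": int(smooth_window),
        },
    )


def exclude_regions(bins: BinSet, regions) -> BinSet:
    """Mark every bin overlapping one of the ppm ``regions`` as excluded.

    Typical use: the water (4.5-5.0 ppm) and urea (5.5-6.0 ppm) resonance
    regions, which are left out of the total-metabolome normalization.
    """
    excluded = bins.is_excluded.copy()
    for lo, hi in regions:
        lo, hi = min(lo, hi), max(lo, hi)
        overlap = (bins.edges[:, 0] < hi) & (bins.edges[:, 1] > lo)
        excluded |= overlap
    return replace(bins, is_excluded=excluded)


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------


@dataclass
class BinTable:
    """Samples x bins matrix of trapezoidal bin integrals with paired metadata."""

    data: np.ndarray  # (n_samples, n_bins)
    bins: BinSet
    sample_ids: list
    subjects: list
    timepoints: list

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("bin integrals must be finite")
        if self.data.shape != (len(self.sample_ids), len(self.bins)):
            raise ValueError("data shape does not match samples x bins")

    @property
    def bin_ids(self) -> list[str]:
        return [f"bin_{k:03d}" for k in range(len(self.bins))]

    @property
    def bin_centers(self) -> np.ndarray:
        return self.bins.edges.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data, index=self.sample_ids, columns=self.bin_ids)
        df.insert(0, "subject", self.subjects)
        df.insert(1, "timepoint", self.timepoints)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="sample")

    @classmethod
    def from_csv(cls, path, bins: BinSet) -> "BinTable":
        df = pd.read_csv(path, index_col="sample")
        subjects = df.pop("subject").tolist()
        timepoints = df.pop("timepoint").astype(str).tolist()
        return cls(
            data=df.to_numpy(float),
            bins=bins,
            sample_ids=df.index.tolist(),
            subjects=subjects,
            timepoints=timepoints,
        )


def integrate(spectra, bins: BinSet) -> BinTable:
    """Trapezoidal integral of every spectrum over every bin.

    Adjacent bins share their boundary grid point, so integrals are exactly
    additive: splitting a bin at an interior grid point yields two integrals
    that sum to the original.
    """
    spectra = list(spectra)
    axis = _check_common_axis(spectra)
    order = np.argsort(axis)
    ppm = axis[order]
    if bins.index[:, 1].max() >= ppm.size or bins.index.min() < 0:
        raise ValueError("bin edges fall outside the spectral axis")
    rows = []
    for s in spectra:
        y = s.intensity[order]
        rows.append(
            [np.trapezoid(y[a : b + 1], ppm[a : b + 1]) for a, b in bins.index]
        )
    return BinTable(
        data=np.array(rows),
        bins=bins,
        sample_ids=[s.sample_id for s in spectra],
        subjects=[s.subject for s in spectra],
        timepoints=[s.timepoint for s in spectra],
    )


# ---------------------------------------------------------------------------
# Reproducible manual bin curation
# ---------------------------------------------------------------------------


def apply_manual_edits(bins: BinSet, edits) -> BinSet:
    """Apply a deterministic edit script to a bin set.

    Each edit is a tuple: ``("merge", i, j)`` with adjacent bin indices,
    ``("split", i, ppm)`` with an interior split point, or ``("exclude", i)``.
    An empty script is the identity. Indices refer to the bin set as it
    stands when the directive is applied (edits compose sequentially).
    """
    edges = bins.edges.copy()
    idx = bins.index.copy()
    noise = bins.is_noise.copy()
    excl = bins.is_excluded.copy()

    for edit in edits:
        op = edit[0]
        if op == "merge":
            _, i, j = edit
            i, j = sorted((int(i), int(j)))
            if j != i + 1:
                raise ValueError("can only merge adjacent bins")
            edges[i] = (edges[i, 0], edges[j, 1])
            idx[i] = (idx[i, 0], idx[j, 1])
            noise[i] = noise[i] and noise[j]
            excl[i] = excl[i] and excl[j]
            edges = np.delete(edges, j, axis=0)
            idx = np.delete(idx, j, axis=0)
            noise = np.delete(noise, j)
            excl = np.delete(excl, j)
        elif op == "split":
            _, i, at = edit
            i = int(i)
            lo, hi = edges[i]
            if not (lo < at < hi):
                raise ValueError("split point must lie inside the bin")
            # snap to the nearest interior grid index
            a, b = idx[i]
            if b - a < 2:
                raise ValueError("bin too narrow to split on the grid")
            frac = (at - lo) / (hi - lo)
            cut = a + int(round(frac * (b - a)))
            cut = min(max(cut, a + 1), b - 1)
            edges = np.insert(edges, i + 1, (at, hi), axis=0)
            edges[i] = (lo, at)
            idx = np.insert(idx, i + 1, (cut, b), axis=0)
            idx[i] = (a, cut)
            noise = np.insert(noise, i + 1, noise[i])
            excl = np.insert(excl, i + 1, excl[i])
        elif op == "exclude":
            _, i = edit
            excl[int(i)] = True
        else:
            raise ValueError(f"unknown edit directive: {op!r}")

    return BinSet(edges=edges, index=idx, is_noise=noise, is_excluded=excl,
                  params=dict(bins.params))
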