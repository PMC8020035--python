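"""Alignment, adaptive binning, integration and manual-edit contracts."""

import numpy as np
import pytest

from uromet.simulate import default_axis
from uromet.spectra import (BinSet, Spectrum, adaptive_bin, align_to_reference,
                            apply_manual_edits, exclude_regions, integrate,
                            mean_spectrum)


def lorentzian(x, center, fwhm=0.02):
    hw = fwhm / 2.0
    return hw**2 / ((x - center) ** 2 + hw**2)


@pytest.fixture()
def x():
    return default_axis()


class TestAlignment:
    def test_self_alignment_is_identity(self, x):
        ref = Spectrum(x, lorentzian(x, 4.0))
        out, segs = align_to_reference(ref, ref, return_segments=True)
        np.testing.assert_array_equal(out.intensity, ref.intensity)
        assert all(s.shift == 0 for s in segs)

    def test_recovers_constructed_displacement(self, x):
        """A +5-point displaced peak is shifted back onto the reference apex."""
        ref = Spectrum(x, lorentzian(x, 4.0))
        displaced = Spectrum(x, np.roll(ref.intensity, 5))
        out, segs = align_to_reference(displaced, ref, max_shift=0.05,
                                       return_segments=True)
        assert np.argmax(out.intensity) == np.argmax(ref.intensity)
        # exhaustive oracle: the best whole-spectrum shift is exactly -5
        shifts = range(-10, 11)
        corr = [np.corrcoef(np.roll(displaced.intensity, s), ref.intensity)[0, 1]
                for s in shifts]
        assert list(shifts)[int(np.argmax(corr))] == -5
        assert -5 in {s.shift for s in segs}

    def test_out_of_window_shift_left_unchanged_and_flagged(self, x):
        ref = Spectrum(x, lorentzian(x, 4.0, fwhm=0.01))
        displaced = Spectrum(x, np.roll(ref.intensity, 20))
        step = x[1] - x[0]
        out, segs = align_to_reference(displaced, ref, max_shift=10 * step,
                                       min_segment=2048, return_segments=True)
        np.testing.assert_array_equal(out.intensity, displaced.intensity)
        assert any(not s.aligned for s in segs)

    def test_total_intensity_preserved_within_padding(self, x):
        ref = Spectrum(x, lorentzian(x, 4.0) + 0.5 * lorentzian(x, 7.0))
        displaced = Spectrum(x, np.roll(ref.intensity, 4))
        out = align_to_reference(displaced, ref, max_shift=0.05)
        assert abs(out.intensity.sum() - displaced.intensity.sum()) \
            <= 0.01 * displaced.intensity.sum()

    def test_mismatched_axes_rejected(self, x):
        a = Spectrum(x, np.zeros_like(x))
        b = Spectrum(x + 0.1, np.zeros_like(x))
        with pytest.raises(ValueError, match="identical ppm axis"):
            align_to_reference(a, b)


class TestAdaptiveBin:
    def test_two_separated_peaks_two_signal_bins(self, x):
        y = lorentzian(x, 3.0) + lorentzian(x, 5.0)
        bins = adaptive_bin(Spectrum(x, y), min_width=0.02, noise_threshold=0.01)
        signal = bins.edges[~bins.is_noise]
        assert len(signal) == 2
        # each signal bin contains one apex
        for apex in (3.0, 5.0):
            assert sum(lo <= apex < hi for lo, hi in signal) == 1
        # boundary coincides with the exhaustive inter-peak minimum
        between = (x > 3.0) & (x < 5.0)
        true_min = x[between][np.argmin(y[between])]
        boundary = signal[0][1]
        assert abs(boundary - true_min) < 0.01

    def test_flat_zero_spectrum_has_no_signal_bins(self, x):
        bins = adaptive_bin(Spectrum(x, np.zeros_like(x)), noise_threshold=0.5)
        assert int((~bins.is_noise).sum()) == 0

    def test_shallow_narrow_split_is_merged(self, x):
        """A sub-min_width dip inside a peak cluster does not survive merging."""
        y = (lorentzian(x, 4.0) + lorentzian(x, 4.06) + lorentzian(x, 4.12)
             + lorentzian(x, 5.0))
        narrow = adaptive_bin(Spectrum(x, y), min_width=0.001,
                              noise_threshold=0.01, smooth_window=3)
        merged = adaptive_bin(Spectrum(x, y), min_width=0.1,
                              noise_threshold=0.01, smooth_window=3)
        n_narrow = int((~narrow.is_noise).sum())
        n_merged = int((~merged.is_noise).sum())
        assert n_narrow == 4  # each intra-cluster dip creates its own bin
        assert n_merged < n_narrow  # sub-min_width bins merged away
        assert all(w >= 0.1 for w in merged.widths[~merged.is_noise])

    def test_binning_is_deterministic(self, x, rng):
        y = np.abs(rng.normal(0, 1, x.size))
        a = adaptive_bin(Spectrum(x, y), min_width=0.05)
        b = adaptive_bin(Spectrum(x, y), min_width=0.05)
        np.testing.assert_array_equal(a.edges, b.edges)
        np.testing.assert_array_equal(a.is_noise, b.is_noise)

    def test_min_width_wider_than_window_rejected(self, x):
        with pytest.raises(ValueError, match="min_width"):
            adaptive_bin(Spectrum(x, np.zeros_like(x)), min_width=100.0)


def simple_bins(x, cuts):
    """Bin set from explicit interior cut indices (test helper)."""
    bounds = [0] + list(cuts) + [x.size - 1]
    idx = np.column_stack([bounds[:-1], bounds[1:]])
    edges = np.column_stack([x[idx[:, 0]], x[idx[:, 1]]])
    return BinSet(edges=edges, index=idx, is_noise=np.zeros(len(idx), bool))


class TestIntegrate:
    def test_unit_rectangle(self):
        x = np.linspace(0.0, 1.0, 101)
        bins = simple_bins(x, [])
        table = integrate([Spectrum(x, np.ones_like(x), sample_id="s")], bins)
        assert table.data[0, 0] == pytest.approx(1.0)

    def test_split_additivity(self, x, rng):
        y = np.abs(rng.normal(0, 1, x.size))
        whole = simple_bins(x, [])
        halves = simple_bins(x, [700])
        t1 = integrate([Spectrum(x, y, sample_id="s")], whole)
        t2 = integrate([Spectrum(x, y, sample_id="s")], halves)
        assert t2.data[0].sum() == pytest.approx(t1.data[0, 0], abs=1e-12)

    def test_zero_spectrum_zero_row(self, x):
        bins = simple_bins(x, [500, 1000])
        table = integrate([Spectrum(x, np.zeros_like(x), sample_id="s")], bins)
        np.testing.assert_array_equal(table.data, 0.0)

    def test_edges_outside_axis_rejected(self, x):
        bad = BinSet(edges=np.array([[0.5, 9.5]]),
                     index=np.array([[0, x.size + 5]]),
                     is_noise=np.array([False]))
        with pytest.raises(ValueError, match="outside"):
            integrate([Spectrum(x, np.zeros_like(x))], bad)


class TestManualEdits:
    @pytest.fixture()
    def bins(self, x):
        return simple_bins(x, [500, 1000, 1500])

    def test_empty_edit_list_is_identity(self, bins):
        out = apply_manual_edits(bins, [])
        np.testing.assert_array_equal(out.edges, bins.edges)

    def test_merge_adjacent(self, bins):
        out = apply_manual_edits(bins, [("merge", 0, 1)])
        assert len(out) == len(bins) - 1
        assert out.edges[0, 0] == bins.edges[0, 0]
        assert out.edges[0, 1] == bins.edges[1, 1]

    def test_merge_non_adjacent_rejected(self, bins):
        with pytest.raises(ValueError, match="adjacent"):
            apply_manual_edits(bins, [("merge", 0, 2)])

    def test_split_then_integrals_conserve(self, bins, x, rng):
        y = np.abs(rng.normal(0, 1, x.size))
        mid = float(bins.edges[1].mean())
        out = apply_manual_edits(bins, [("split", 1, mid)])
        assert len(out) == len(bins) + 1
        t_orig = integrate([Spectrum(x, y, sample_id="s")], bins)
        t_new = integrate([Spectrum(x, y, sample_id="s")], out)
        assert t_new.data[0, 1] + t_new.data[0, 2] == pytest.approx(
            t_orig.data[0, 1], abs=1e-12)

    def test_exclude_marks_without_changing_edges(self, bins):
        out = apply_manual_edits(bins, [("exclude", 2)])
        np.testing.assert_array_equal(out.edges, bins.edges)
        assert out.is_excluded[2] and not out.is_excluded[0]


class TestExcludeRegions:
    def test_water_region_marked(self, x):
        bins = simple_bins(x, [1000])
        out = exclude_regions(bins, [(4.5, 5.0)])
        overlaps = (bins.edges[:, 0] < 5.0) & (bins.edges[:, 1] > 4.5)
        np.testing.assert_array_equal(out.is_excluded, overlaps)


def test_mean_spectrum_pointwise(x):
    a = Spectrum(x, np.zeros_like(x))
    b = Spectrum(x, np.ones_like(x))
    m = mean_spectrum([a, b])
    np.testing.assert_allclose(m.intensity, 0.5)
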