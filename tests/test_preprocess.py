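"""Preprocessing-chain tests: common axis, resampling, alignment,
calibration, peak picking, feature extraction, robust TIC normalization."""

import math
from dataclasses import replace

import numpy as np
import pytest

from sddmark import preprocess as prep
from sddmark import synthetic_msi as syn
from sddmark.msio import CentroidSpectrum, IMSDataset


def _spectrum(mz, intensity, pixel=(0, 0)):
    return CentroidSpectrum(mz=np.asarray(mz, float),
                            intensity=np.asarray(intensity, float), pixel=pixel)


def _dataset(spectra, polarity="positive", grid=None):
    if grid is None:
        w = max(s.pixel[0] for s in spectra) + 1
        h = max(s.pixel[1] for s in spectra) + 1
        grid = (w, h)
    return IMSDataset(spectra=spectra, polarity=polarity,
                      mz_range=(300.0, 2000.0), grid_shape=grid)


@pytest.fixture(scope="module")
def axis():
    return prep.build_common_axis(300.0, 2000.0, 1.5)


class TestCommonAxis:
    def test_degenerate_range_single_edge(self):
        axis = prep.build_common_axis(500.0, 500.0, 1.5)
        assert axis.edges.size == 1 and axis.n_bins == 0

    def test_adjacent_edge_ratio_constant(self):
        axis = prep.build_common_axis(300.0, 2000.0, 1.5)
        ratios = axis.edges[1:] / axis.edges[:-1]
        assert np.abs(ratios - (1 + 1.5e-6)).max() < 1e-12

    def test_edge_count_against_log_oracle(self):
        # Independent closed form: ceil(ln(max/min)/ln(1+r)) + 1 edges.
        axis = prep.build_common_axis(300.0, 2000.0, 1.5)
        expected = math.ceil(math.log(2000 / 300) / math.log(1 + 1.5e-6)) + 1
        assert axis.edges.size == expected
        assert abs(axis.edges.size - 1_264_747) <= 2

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(ValueError):
            prep.build_common_axis(300.0, 2000.0, 0.0)


class TestResample:
    def test_empty_spectrum_zero_vector(self, axis):
        out = prep.resample(_spectrum([], []), axis)
        assert out.shape == (axis.n_bins,) and not out.any()

    def test_total_intensity_conserved_exactly(self, axis):
        rng = np.random.default_rng(5)
        mz = np.sort(rng.uniform(300, 1999, size=500))
        inten = rng.exponential(10, size=500)
        out = prep.resample(_spectrum(mz, inten), axis)
        assert out.sum() == pytest.approx(inten.sum(), rel=0, abs=1e-9)

    def test_close_centroids_share_one_bin(self, axis):
        # Two peaks 0.5 ppm apart around a bin center land in one 1.5 ppm bin.
        bin_idx = 600_000
        center = math.sqrt(axis.edges[bin_idx] * axis.edges[bin_idx + 1])
        pair = [center * (1 - 0.25e-6), center * (1 + 0.25e-6)]
        expected_bin = axis.bin_of(np.array(pair))
        assert expected_bin[0] == expected_bin[1]
        out = prep.resample(_spectrum(pair, [2.0, 3.0]), axis)
        assert out[expected_bin[0]] == 5.0
        assert np.count_nonzero(out) == 1

    def test_out_of_range_peaks_dropped(self, axis):
        out = prep.resample(_spectrum([100.0, 400.0], [1.0, 2.0]), axis)
        assert out.sum() == 2.0


class TestMeanSpectrum:
    def test_single_pixel_equals_binned_spectrum(self, axis):
        s = _spectrum([400.0, 800.0], [4.0, 6.0])
        ds = _dataset([s])
        assert np.array_equal(prep.mean_spectrum(ds, axis), prep.resample(s, axis))

    def test_identical_pixels_average_to_either(self, axis):
        s1 = _spectrum([400.0], [4.0], pixel=(0, 0))
        s2 = _spectrum([400.0], [4.0], pixel=(1, 0))
        ds = _dataset([s1, s2])
        assert np.array_equal(prep.mean_spectrum(ds, axis), prep.resample(s1, axis))

    def test_mixed_polarity_rejected(self, axis):
        a = _dataset([_spectrum([400.0], [1.0])])
        b = _dataset([_spectrum([400.0], [1.0])], polarity="negative")
        with pytest.raises(ValueError, match="polarit"):
            prep.mean_spectrum([a, b], axis)


class TestAlignmentPeakSelection:
    def test_occupancy_filtering_oracle(self):
        """Eight candidates with known occupancies; the six at >= 0.5 win."""
        peak_mz = np.array([350.0, 450.0, 550.0, 650.0, 750.0, 850.0, 950.0, 1050.0])
        occupancies = [1.0, 0.9, 0.8, 0.7, 0.6, 0.55, 0.4, 0.3]
        n_pix = 20
        spectra = []
        for i in range(n_pix):
            present = [mz for mz, occ in zip(peak_mz, occupancies)
                       if i < round(occ * n_pix)]
            spectra.append(_spectrum(present, [10.0] * len(present), pixel=(i, 0)))
        ds = _dataset(spectra, grid=(n_pix, 1))
        model = prep.select_alignment_peaks(ds, n_peaks=6, min_fraction=0.5)
        assert np.allclose(np.sort(model.reference_peaks), peak_mz[:6], rtol=2e-6)
        assert (model.occupancy >= 0.5).all()

    def test_uniform_six_peaks_returned_exactly(self):
        peak_mz = [400.0, 500.0, 600.0, 700.0, 800.0, 900.0]
        spectra = [_spectrum(peak_mz, [5.0] * 6, pixel=(i, 0)) for i in range(10)]
        ds = _dataset(spectra, grid=(10, 1))
        model = prep.select_alignment_peaks(ds, n_peaks=6, min_fraction=0.5)
        assert np.allclose(np.sort(model.reference_peaks), peak_mz, rtol=2e-6)

    def test_insufficient_candidates_error_reports_count(self):
        spectra = [_spectrum([400.0, 500.0], [5.0, 5.0], pixel=(i, 0))
                   for i in range(10)]
        ds = _dataset(spectra, grid=(10, 1))
        with pytest.raises(ValueError, match="2 candidate"):
            prep.select_alignment_peaks(ds, n_peaks=6, min_fraction=0.5)


def _grid_search_shift(spectrum, refs, max_shift_ppm=30.0):
    """Independent oracle: exhaustive scan over candidate scalar shifts."""
    best_shift, best_cost = 0.0, np.inf
    for shift in np.arange(-max_shift_ppm, max_shift_ppm + 0.005, 0.01):
        corrected = spectrum.mz / (1 + shift * 1e-6)
        cost, matched = 0.0, 0
        for ref in refs:
            dev = np.abs(corrected - ref) / ref * 1e6
            if dev.min() <= max_shift_ppm:
                cost += dev.min()
                matched += 1
        if matched >= 2 and cost / matched < best_cost:
            best_cost, best_shift = cost / matched, shift
    return best_shift


class TestAlignPixel:
    refs = np.array([400.0, 600.0, 800.0, 1000.0, 1200.0, 1400.0])

    def test_zero_drift_no_change(self):
        s = _spectrum(self.refs, np.full(6, 5.0))
        out, shift = prep.align_pixel(s, self.refs)
        assert abs(shift) <= 0.5
        assert np.allclose(out.mz, s.mz, rtol=1e-9)

    def test_known_shift_recovered_matches_grid_search(self):
        drifted = _spectrum(self.refs * (1 + 10e-6), np.full(6, 5.0))
        out, shift = prep.align_pixel(drifted, self.refs)
        assert shift == pytest.approx(10.0, abs=1.0)
        oracle = _grid_search_shift(drifted, self.refs)
        assert shift == pytest.approx(oracle, abs=0.1)
        assert np.allclose(out.mz, self.refs, rtol=1e-9)

    def test_partial_reference_coverage_still_aligns(self):
        present = self.refs[:3] * (1 + 8e-6)
        s = _spectrum(present, np.full(3, 5.0))
        _out, shift = prep.align_pixel(s, self.refs)
        assert shift == pytest.approx(8.0, abs=1.0)

    def test_too_few_matches_returns_unchanged(self):
        s = _spectrum([1700.0], [5.0])
        out, shift = prep.align_pixel(s, self.refs)
        assert shift == 0.0 and np.array_equal(out.mz, s.mz)


class TestCalibrate:
    cal = syn.default_calibrants()["mz"].to_numpy()

    def _flat_dataset(self, error=None):
        cfg = syn.PhantomConfig(grid_width=20, grid_height=20, n_deposits=1,
                                deposit_size_px=(2, 3), drift_ppm_range=0.0,
                                noise_floor=0.0, spike_rate=0.0, seed=4)
        ds, _ = syn.generate_phantom(cfg)
        if error is None:
            return ds
        spectra = [
            CentroidSpectrum(mz=s.mz * (1 + error(s.mz) * 1e-6),
                             intensity=s.intensity, pixel=s.pixel)
            for s in ds.spectra
        ]
        return replace(ds, spectra=spectra)

    def test_zero_error_identity(self):
        ds = self._flat_dataset()
        out, model = prep.calibrate(ds, self.cal)
        assert np.abs(model.residual_ppm).max() < 1e-6
        assert np.allclose(model.coefficients, (0.0, 0.0), atol=1e-6)
        for a, b in zip(out.spectra, ds.spectra):
            assert np.allclose(a.mz, b.mz, rtol=1e-10)

    def test_linear_error_recovered_closed_form(self):
        a_true, b_true = 5.0, 0.001
        ds = self._flat_dataset(lambda mz: a_true + b_true * mz)
        _out, model = prep.calibrate(ds, self.cal)
        a_fit, b_fit = model.coefficients
        assert a_fit == pytest.approx(a_true, abs=0.05)
        assert b_fit == pytest.approx(b_true, rel=0.05)
        assert np.abs(model.residual_ppm).max() < 0.1

    def test_fewer_than_four_calibrants_rejected(self):
        ds = self._flat_dataset()
        with pytest.raises(ValueError, match="at least 4"):
            prep.calibrate(ds, self.cal[:3])

    def test_unmatched_calibrants_rejected(self):
        ds = self._flat_dataset()
        bogus = np.array([311.1, 333.3, 355.5, 377.7])
        with pytest.raises(ValueError, match="matched"):
            prep.calibrate(ds, bogus)


class TestPickPeaks:
    def test_flat_zero_spectrum_empty(self, axis):
        assert prep.pick_peaks(np.zeros(axis.n_bins), axis).size == 0

    def test_planted_gaussian_peaks_found_within_ppm(self, axis):
        centers_mz = [400.0, 550.0, 700.0, 850.0, 1000.0]
        spec = np.zeros(axis.n_bins)
        rng = np.random.default_rng(0)
        spec += np.abs(rng.normal(0, 1.0, axis.n_bins))  # noise floor
        for mz in centers_mz:
            apex = int(axis.bin_of(np.array([mz]))[0])
            for off in range(-5, 6):
                spec[apex + off] += 200.0 * math.exp(-(off**2) / 4.0)
        picked = prep.pick_peaks(spec, axis, snr_threshold=10)
        assert picked.size == len(centers_mz)
        for mz in centers_mz:
            err = np.abs(picked - mz).min() / mz * 1e6
            assert err < 1.0

    def test_isotope_pair_kept_as_two_features(self, axis):
        mono = 500.0
        iso = mono + 1.003355
        spec = np.zeros(axis.n_bins)
        spec[axis.bin_of(np.array([mono]))[0]] = 100.0
        spec[axis.bin_of(np.array([iso]))[0]] = 25.0
        picked = prep.pick_peaks(spec, axis)
        assert picked.size == 2
        assert np.abs(picked[1] - picked[0] - 1.003355) / mono * 1e6 < 2.0

    def test_noiseless_phantom_recovers_exact_species_count(
        self, noiseless_phantom, axis
    ):
        _config, dataset, truth = noiseless_phantom
        avg = prep.mean_spectrum(dataset, axis)
        picked = prep.pick_peaks(avg, axis)
        assert picked.size == len(truth.peak_table)


class TestExtractFeatures:
    def test_pixel_with_no_nearby_peaks_zero_row(self):
        ds = _dataset([
            _spectrum([400.0], [5.0], pixel=(0, 0)),
            _spectrum([900.0], [7.0], pixel=(1, 0)),
        ])
        m = prep.extract_features(ds, np.array([400.0]), tol_ppm=7.0)
        assert m.values[0, 0] == 5.0 and m.values[1, 0] == 0.0

    def test_centroid_at_center_fully_assigned(self):
        ds = _dataset([_spectrum([400.0, 500.0], [5.0, 3.0])])
        m = prep.extract_features(ds, np.array([400.0, 500.0]))
        assert np.array_equal(m.values, [[5.0, 3.0]])

    def test_duplicate_features_rejected(self):
        ds = _dataset([_spectrum([400.0], [5.0])])
        with pytest.raises(ValueError, match="duplicate"):
            prep.extract_features(ds, np.array([400.0, 400.0]))

    def test_windows_clipped_at_midpoints(self):
        # A centroid between two features 5 ppm apart is counted once.
        f1 = 600.0
        f2 = 600.0 * (1 + 5e-6)
        centroid = 600.0 * (1 + 2e-6)
        ds = _dataset([_spectrum([centroid], [9.0])])
        m = prep.extract_features(ds, np.array([f1, f2]), tol_ppm=7.0)
        assert m.values.sum() == 9.0
        assert np.count_nonzero(m.values) == 1

    def test_marker_feature_zero_outside_deposits(self, preprocessed):
        matrix, truth = preprocessed
        col = matrix.feature_column(truth.true_marker_mz[0])
        img = matrix.map_image(col)
        assert img[~truth.deposit_mask].max() <= img[truth.deposit_mask].mean() * 0.02


class TestRobustTicNormalize:
    def _two_pixel_matrix(self, row_a, row_b):
        from sddmark.msio import FeatureMatrix

        return FeatureMatrix(
            values=np.array([row_a, row_b], dtype=float),
            feature_mz=np.arange(400.0, 400.0 + len(row_a)),
            feature_tol_ppm=7.0,
            pixel_index=np.array([[0, 0], [1, 0]]),
            grid_shape=(2, 1),
        )

    def test_identical_pixels_identical_factors(self):
        m = self._two_pixel_matrix([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        _out, factors = prep.robust_tic_normalize(m)
        assert factors[0] == factors[1]

    def test_doubled_pixel_equalized(self):
        row = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        m = self._two_pixel_matrix(row, 2 * row)
        out, factors = prep.robust_tic_normalize(m)
        assert factors[1] == pytest.approx(factors[0] / 2)
        assert np.allclose(out.values[0], out.values[1])

    def test_idempotence(self, preprocessed):
        matrix, _truth = preprocessed
        again, factors = prep.robust_tic_normalize(matrix)
        assert np.abs(factors - 1.0).max() < 1e-6

    def test_single_spike_changes_factor_less_than_5_percent(self):
        rng = np.random.default_rng(9)
        base = rng.exponential(10, size=200)
        spiked = np.concatenate([base, [100 * base.max()]])
        m = self._two_pixel_matrix(
            np.concatenate([base, [0.0]]), spiked
        )
        _out, factors = prep.robust_tic_normalize(m)
        # Oracle: recompute the 5-95th TIC with and without the spike.
        def tic(v):
            v = v[v > 0]
            p5, p95 = np.percentile(v, [5, 95])
            return v[(v >= p5) & (v <= p95)].sum()

        assert abs(tic(spiked) - tic(base)) / tic(base) < 0.05
        assert abs(factors[1] - factors[0]) / factors[0] < 0.05

    def test_all_zero_pixel_gets_unit_factor_with_warning(self):
        m = self._two_pixel_matrix([1, 2, 3, 4, 5], [0, 0, 0, 0, 0])
        with pytest.warns(UserWarning, match="all-zero"):
            _out, factors = prep.robust_tic_normalize(m)
        assert factors[1] == 1.0


class TestFilterFeatures:
    def test_rare_features_removed(self):
        from sddmark.msio import FeatureMatrix

        values = np.zeros((100, 3))
        values[:, 0] = 1.0
        values[:50, 1] = 1.0
        values[0, 2] = 99.0  # single-pixel spike feature
        m = FeatureMatrix(
            values=values, feature_mz=np.array([400.0, 500.0, 600.0]),
            feature_tol_ppm=7.0,
            pixel_index=np.array([[i % 10, i // 10] for i in range(100)]),
            grid_shape=(10, 10),
        )
        out = prep.filter_features(m, min_occupancy=0.02)
        assert list(out.feature_mz) == [400.0, 500.0]
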