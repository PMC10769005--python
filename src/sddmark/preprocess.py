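"""Spectral preprocessing: alignment, calibration, resampling, peak picking,
feature extraction, and robust TIC normalization.

The chain mirrors standard centroid-mode IMS practice: pick internal
reference peaks from the raw mean spectrum (high pixel occupancy), estimate
one scalar ppm shift per pixel against them, remove the remaining systematic
mass error with a >=4-point calibrant fit (ppm error linear in m/z), resample
everything onto a shared geometric mass axis (~1.5 ppm bins), peak-pick the
dataset mean spectrum, extract per-pixel feature intensities in +/-7 ppm
windows, and normalize pixels by a 5-95th percentile total ion current.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import find_peaks

from .msio import CentroidSpectrum, FeatureMatrix, IMSDataset

__all__ = [
    "MassAxis",
    "AlignmentModel",
    "CalibrationModel",
    "build_common_axis",
    "resample",
    "mean_spectrum",
    "select_alignment_peaks",
    "align_pixel",
    "align_dataset",
    "calibrate",
    "pick_peaks",
    "extract_features",
    "robust_tic_normalize",
    "mass_error_at",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MassAxis:
    """Geometric (constant-ppm) mass axis: edges[i+1] = edges[i]*(1 + r*1e-6)."""

    edges: np.ndarray
    spacing_ppm: float

    @property
    def n_bins(self) -> int:
        return max(self.edges.size - 1, 0)

    def bin_of(self, mz: np.ndarray) -> np.ndarray:
        """Bin index per m/z; -1 for out-of-range values."""
        mz = np.asarray(mz, dtype=np.float64)
        idx = np.searchsorted(self.edges, mz, side="right") - 1
        idx[(mz < self.edges[0]) | (mz >= self.edges[-1])] = -1
        return idx

    def centers(self) -> np.ndarray:
        return np.sqrt(self.edges[:-1] * self.edges[1:])


@dataclass
class AlignmentModel:
    """Reference peaks plus the estimated scalar ppm shift per pixel."""

    reference_peaks: np.ndarray
    occupancy: np.ndarray
    min_fraction: float
    per_pixel_shift_ppm: np.ndarray | None = None


@dataclass
class CalibrationModel:
    """Linear-in-m/z ppm error model fitted on >=4 calibrant species."""

    calibrant_mz: np.ndarray
    matched_mz: np.ndarray
    coefficients: tuple[float, float]  # err_ppm(mz) = a + b*mz
    residual_ppm: np.ndarray

    def error_ppm(self, mz: np.ndarray) -> np.ndarray:
        a, b = self.coefficients
        return a + b * np.asarray(mz, dtype=np.float64)

    @property
    def median_abs_residual_ppm(self) -> float:
        return float(np.median(np.abs(self.residual_ppm)))


def build_common_axis(mz_min: float, mz_max: float, spacing_ppm: float = 1.5) -> MassAxis:
    """Geometric mass axis from mz_min to (just past) mz_max.

    Bin count is ceil(ln(mz_max/mz_min) / ln(1 + r*1e-6)); with the default
    1.5 ppm spacing over m/z 300-2000 that is ~1.26 million bins.
    """
    if spacing_ppm <= 0:
        raise ValueError("spacing_ppm must be positive")
    if not (0 < mz_min <= mz_max):
        raise ValueError("require 0 < mz_min <= mz_max")
    ratio = 1.0 + spacing_ppm * 1e-6
    if mz_min == mz_max:
        return MassAxis(edges=np.array([mz_min]), spacing_ppm=spacing_ppm)
    n = int(np.ceil(np.log(mz_max / mz_min) / np.log(ratio)))
    edges = mz_min * np.exp(np.arange(n + 1) * np.log1p(spacing_ppm * 1e-6))
    return MassAxis(edges=edges, spacing_ppm=spacing_ppm)


def resample(spectrum: CentroidSpectrum, axis: MassAxis) -> np.ndarray:
    """Bin a centroid spectrum onto the axis; total in-range intensity conserved."""
    out = np.zeros(axis.n_bins, dtype=np.float64)
    if len(spectrum) == 0 or axis.n_bins == 0:
        return out
    idx = axis.bin_of(spectrum.mz)
    in_range = idx >= 0
    dropped = int(np.sum(~in_range))
    if dropped:
        log.debug("resample: dropped %d out-of-range peaks", dropped)
    np.add.at(out, idx[in_range], spectrum.intensity[in_range])
    return out


def mean_spectrum(datasets: IMSDataset | list[IMSDataset], axis: MassAxis) -> np.ndarray:
    """Arithmetic mean binned spectrum over all pixels of all datasets."""
    if isinstance(datasets, IMSDataset):
        datasets = [datasets]
    if not datasets:
        raise ValueError("no datasets supplied")
    polarities = {d.polarity for d in datasets}
    if len(polarities) > 1:
        raise ValueError(f"mixed polarities {sorted(polarities)} cannot be averaged")
    total = np.zeros(axis.n_bins, dtype=np.float64)
    n = 0
    for ds in datasets:
        for s in ds.spectra:
            n += 1
            if len(s) == 0:
                continue
            idx = axis.bin_of(s.mz)
            in_range = idx >= 0
            np.add.at(total, idx[in_range], s.intensity[in_range])
    if n == 0:
        raise ValueError("datasets contain no spectra")
    return total / n


def pick_peaks(
    avg_spectrum: np.ndarray,
    axis: MassAxis,
    snr_threshold: float = 3.0,
    min_prominence: float = 0.0,
) -> np.ndarray:
    """Peak-pick a binned mean spectrum; returns apex m/z values (ascending).

    Noise is estimated as 1.4826 x MAD of the binned spectrum (zero on
    sparse/noiseless data, in which case every local maximum survives). The
    apex m/z is the intensity-weighted centroid over apex +/- 1 bin, so the
    reported position is finer than the bin width. Isotope peaks are kept.
    """
    avg_spectrum = np.asarray(avg_spectrum, dtype=np.float64)
    if avg_spectrum.size != axis.n_bins:
        raise ValueError("spectrum length does not match axis")
    if not np.any(avg_spectrum > 0):
        return np.empty(0)
    mad = np.median(np.abs(avg_spectrum - np.median(avg_spectrum)))
    noise = 1.4826 * mad
    height = max(snr_threshold * noise, np.finfo(float).tiny)
    prominence = max(min_prominence, snr_threshold * noise, np.finfo(float).tiny)
    # Pad so single-bin peaks at the array ends are still local maxima.
    padded = np.concatenate([[0.0], avg_spectrum, [0.0]])
    apex, _props = find_peaks(padded, height=height, prominence=prominence)
    apex = apex - 1
    centers = axis.centers()
    out = []
    for a in apex:
        lo, hi = max(a - 1, 0), min(a + 2, avg_spectrum.size)
        weights = avg_spectrum[lo:hi]
        out.append(float(np.average(centers[lo:hi], weights=weights)))
    return np.asarray(sorted(out))


def _occupancy(dataset: IMSDataset, candidates: np.ndarray, tol_ppm: float) -> np.ndarray:
    """Fraction of pixels containing a peak within tol_ppm of each candidate."""
    lo = candidates * (1 - tol_ppm * 1e-6)
    hi = candidates * (1 + tol_ppm * 1e-6)
    counts = np.zeros(candidates.size, dtype=np.int64)
    for s in dataset.spectra:
        counts += np.searchsorted(s.mz, hi, side="right") > np.searchsorted(
            s.mz, lo, side="left"
        )
    return counts / max(len(dataset), 1)


def select_alignment_peaks(
    dataset: IMSDataset,
    n_peaks: int = 6,
    min_fraction: float = 0.5,
    tol_ppm: float = 30.0,
    min_spacing_mz: float = 50.0,
    axis: MassAxis | None = None,
) -> AlignmentModel:
    """Choose internal reference peaks for per-pixel m/z alignment.

    Candidates are the peaks of the un-aligned mean spectrum; of those with
    pixel occupancy >= min_fraction, the n_peaks most-occupied are taken
    greedily while enforcing a minimum mutual spacing so the set spans the
    acquired range.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    if axis is None:
        axis = build_common_axis(*dataset.mz_range, spacing_ppm=1.5)
    avg = mean_spectrum(dataset, axis)
    candidates = pick_peaks(avg, axis)
    if candidates.size == 0:
        raise ValueError("no candidate peaks found in the mean spectrum")
    occ = _occupancy(dataset, candidates, tol_ppm)
    eligible = occ >= min_fraction
    if int(eligible.sum()) < n_peaks:
        raise ValueError(
            f"only {int(eligible.sum())} candidate peaks reach occupancy "
            f">= {min_fraction} (need {n_peaks})"
        )
    order = np.lexsort((candidates[eligible], -occ[eligible]))
    cand = candidates[eligible][order]
    cand_occ = occ[eligible][order]
    chosen_mz: list[float] = []
    chosen_occ: list[float] = []
    for mz, o in zip(cand, cand_occ):
        if all(abs(mz - c) >= min_spacing_mz for c in chosen_mz):
            chosen_mz.append(float(mz))
            chosen_occ.append(float(o))
        if len(chosen_mz) == n_peaks:
            break
    if len(chosen_mz) < n_peaks:
        # Spacing was too restrictive for this dataset; fill by occupancy.
        for mz, o in zip(cand, cand_occ):
            if mz not in chosen_mz:
                chosen_mz.append(float(mz))
                chosen_occ.append(float(o))
            if len(chosen_mz) == n_peaks:
                break
    order = np.argsort(chosen_mz)
    return AlignmentModel(
        reference_peaks=np.asarray(chosen_mz)[order],
        occupancy=np.asarray(chosen_occ)[order],
        min_fraction=min_fraction,
    )


def align_pixel(
    spectrum: CentroidSpectrum,
    reference_peaks: np.ndarray,
    max_shift_ppm: float = 30.0,
) -> tuple[CentroidSpectrum, float]:
    """Estimate and remove one scalar ppm shift for a single pixel.

    The shift is the median ppm deviation of the reference peaks matched
    within max_shift_ppm; applied as mz <- mz / (1 + shift*1e-6). With fewer
    than two matched references the spectrum is returned unchanged.
    """
    reference_peaks = np.asarray(reference_peaks, dtype=np.float64)
    if len(spectrum) == 0:
        return spectrum, 0.0
    deviations = []
    for ref in reference_peaks:
        j = np.searchsorted(spectrum.mz, ref)
        best = None
        for k in (j - 1, j):
            if 0 <= k < len(spectrum):
                dev = (spectrum.mz[k] - ref) / ref * 1e6
                if abs(dev) <= max_shift_ppm and (best is None or abs(dev) < abs(best)):
                    best = dev
        if best is not None:
            deviations.append(best)
    if len(deviations) < 2:
        log.warning(
            "pixel %s: only %d/%d reference peaks matched; not aligned",
            spectrum.pixel, len(deviations), reference_peaks.size,
        )
        return spectrum, 0.0
    shift = float(np.median(deviations))
    shifted = CentroidSpectrum(
        mz=spectrum.mz / (1.0 + shift * 1e-6),
        intensity=spectrum.intensity,
        pixel=spectrum.pixel,
    )
    return shifted, shift


def align_dataset(
    dataset: IMSDataset,
    model: AlignmentModel,
    max_shift_ppm: float = 30.0,
) -> tuple[IMSDataset, AlignmentModel]:
    """Apply scalar-shift alignment to every pixel; records per-pixel shifts."""
    shifted = []
    shifts = np.zeros(len(dataset))
    for i, s in enumerate(dataset.spectra):
        new, shift = align_pixel(s, model.reference_peaks, max_shift_ppm)
        shifted.append(new)
        shifts[i] = shift
    out = replace(dataset, spectra=shifted)
    return out, AlignmentModel(
        reference_peaks=model.reference_peaks,
        occupancy=model.occupancy,
        min_fraction=model.min_fraction,
        per_pixel_shift_ppm=shifts,
    )


def calibrate(
    dataset: IMSDataset,
    calibrants: np.ndarray,
    search_window_ppm: float = 30.0,
    min_pixel_fraction: float = 0.1,
) -> tuple[IMSDataset, CalibrationModel]:
    """Fit and remove the systematic ppm mass error using calibrant species.

    Each calibrant's observed position is the median, over pixels, of the
    nearest centroid within the search window (sub-bin accuracy, robust to
    interloping peaks); the ppm error is modeled as a + b*mz (least squares
    over >=4 matched calibrants) and inverted on every spectrum. Calibrants
    found in fewer than ``min_pixel_fraction`` of pixels are not used.
    """
    calibrants = np.sort(np.asarray(calibrants, dtype=np.float64))
    if calibrants.size < 4:
        raise ValueError("calibration requires at least 4 calibrant species")
    matched_theo, matched_obs = [], []
    n_pixels = max(len(dataset), 1)
    for cal in calibrants:
        hits = []
        lo, hi = cal * (1 - search_window_ppm * 1e-6), cal * (1 + search_window_ppm * 1e-6)
        for s in dataset.spectra:
            a = np.searchsorted(s.mz, lo, side="left")
            b = np.searchsorted(s.mz, hi, side="right")
            if b > a:
                window = s.mz[a:b]
                hits.append(window[np.argmin(np.abs(window - cal))])
        if len(hits) >= min_pixel_fraction * n_pixels:
            matched_theo.append(cal)
            matched_obs.append(float(np.median(hits)))
    if len(matched_theo) < 4:
        raise ValueError(
            f"only {len(matched_theo)}/{calibrants.size} calibrants matched "
            f"within {search_window_ppm} ppm (need >= 4)"
        )
    theo = np.asarray(matched_theo)
    obs = np.asarray(matched_obs)
    err_ppm = (obs - theo) / theo * 1e6
    b, a = np.polyfit(obs, err_ppm, deg=1)
    model_coeffs = (float(a), float(b))

    def _correct(mz: np.ndarray) -> np.ndarray:
        return mz / (1.0 + (a + b * mz) * 1e-6)

    corrected = [
        CentroidSpectrum(mz=_correct(s.mz), intensity=s.intensity, pixel=s.pixel)
        for s in dataset.spectra
    ]
    residual = (_correct(obs) - theo) / theo * 1e6
    if np.any(np.abs(residual) > 5.0):
        warnings.warn(
            f"post-calibration residual exceeds 5 ppm (max "
            f"{np.abs(residual).max():.2f} ppm)"
        )
    out = replace(dataset, spectra=corrected)
    return out, CalibrationModel(
        calibrant_mz=theo,
        matched_mz=obs,
        coefficients=model_coeffs,
        residual_ppm=residual,
    )


def extract_features(
    dataset: IMSDataset,
    feature_mz: np.ndarray,
    tol_ppm: float = 7.0,
) -> FeatureMatrix:
    """Sum each pixel's centroid intensities within +/- tol_ppm of each feature.

    Windows are clipped at midpoints between adjacent features so no centroid
    is counted twice.
    """
    feature_mz = np.asarray(feature_mz, dtype=np.float64)
    if feature_mz.size == 0:
        raise ValueError("empty feature list")
    if np.any(np.diff(feature_mz) <= 0):
        if np.any(np.diff(np.sort(feature_mz)) == 0):
            raise ValueError("duplicate feature m/z values")
        feature_mz = np.sort(feature_mz)
    lo = feature_mz * (1.0 - tol_ppm * 1e-6)
    hi = feature_mz * (1.0 + tol_ppm * 1e-6)
    if feature_mz.size > 1:
        mid = 0.5 * (feature_mz[:-1] + feature_mz[1:])
        np.minimum(hi[:-1], mid, out=hi[:-1])
        np.maximum(lo[1:], mid, out=lo[1:])
    values = np.zeros((len(dataset), feature_mz.size))
    for i, s in enumerate(dataset.spectra):
        if len(s) == 0:
            continue
        cs = np.concatenate([[0.0], np.cumsum(s.intensity)])
        a = np.searchsorted(s.mz, lo, side="left")
        b = np.searchsorted(s.mz, hi, side="right")
        values[i] = cs[b] - cs[a]
    return FeatureMatrix(
        values=values,
        feature_mz=feature_mz,
        feature_tol_ppm=tol_ppm,
        pixel_index=dataset.pixel_index(),
        grid_shape=dataset.grid_shape,
    )


def filter_features(matrix: FeatureMatrix, min_occupancy: float = 0.02) -> FeatureMatrix:
    """Drop features with nonzero intensity in fewer than a fraction of pixels.

    Removes speckle features originating from single-pixel outlier spikes,
    which otherwise dominate variance-based factorizations; genuine tissue
    peaks occupy at least a stratum's worth of pixels.
    """
    if not 0 <= min_occupancy <= 1:
        raise ValueError("min_occupancy must be in [0, 1]")
    occupancy = np.mean(matrix.values > 0, axis=0)
    keep = occupancy >= min_occupancy
    if not np.any(keep):
        raise ValueError("occupancy filter removed every feature")
    return FeatureMatrix(
        values=matrix.values[:, keep],
        feature_mz=matrix.feature_mz[keep],
        feature_tol_ppm=matrix.feature_tol_ppm,
        pixel_index=matrix.pixel_index,
        grid_shape=matrix.grid_shape,
        normalized=matrix.normalized,
        norm_factors=matrix.norm_factors,
    )


def _robust_tic(values: np.ndarray) -> float:
    """5-95th percentile TIC of one pixel's positive intensities."""
    v = values[values > 0]
    if v.size == 0:
        return 0.0
    p5, p95 = np.percentile(v, [5.0, 95.0])
    window = v[(v >= p5) & (v <= p95)]
    return float(window.sum())


def robust_tic_normalize(
    data: FeatureMatrix | IMSDataset,
) -> tuple[FeatureMatrix | IMSDataset, np.ndarray]:
    """Normalize pixels by the 5-95th percentile total ion current.

    Each pixel's TIC sums only its intensities between its own 5th and 95th
    intensity percentiles, making single outlier spikes nearly invisible to
    the correction. factor(pixel) = median_pixels(TIC) / TIC(pixel); all of
    the pixel's intensities (including those outside the percentile window)
    are multiplied by the factor so columns stay mutually comparable.
    """
    if isinstance(data, FeatureMatrix):
        tics = np.array([_robust_tic(row) for row in data.values])
    else:
        tics = np.array([_robust_tic(s.intensity) for s in data.spectra])
    positive = tics > 0
    if not np.any(positive):
        raise ValueError("no pixel has positive intensity")
    target = float(np.median(tics[positive]))
    factors = np.ones_like(tics)
    factors[positive] = target / tics[positive]
    if np.any(~positive):
        warnings.warn(
            f"{int(np.sum(~positive))} all-zero pixel(s) left unnormalized (factor 1)"
        )
    if isinstance(data, FeatureMatrix):
        out = FeatureMatrix(
            values=data.values * factors[:, None],
            feature_mz=data.feature_mz,
            feature_tol_ppm=data.feature_tol_ppm,
            pixel_index=data.pixel_index,
            grid_shape=data.grid_shape,
            normalized=True,
            norm_factors=factors,
        )
        return out, factors
    spectra = [
        CentroidSpectrum(mz=s.mz, intensity=s.intensity * f, pixel=s.pixel)
        for s, f in zip(data.spectra, factors)
    ]
    return replace(data, spectra=spectra), factors


def mass_error_at(
    dataset: IMSDataset,
    reference_mz: np.ndarray,
    window_ppm: float = 8.0,
) -> np.ndarray:
    """Per-(pixel, reference) ppm errors of the nearest peak within a window.

    Used to audit alignment + calibration quality at calibrant positions;
    returns the flat array of all matched ppm errors.
    """
    reference_mz = np.asarray(reference_mz, dtype=np.float64)
    errors = []
    for s in dataset.spectra:
        if len(s) == 0:
            continue
        for ref in reference_mz:
            j = np.searchsorted(s.mz, ref)
            best = None
            for k in (j - 1, j):
                if 0 <= k < len(s):
                    dev = (s.mz[k] - ref) / ref * 1e6
                    if abs(dev) <= window_ppm and (
                        best is None or abs(dev) < abs(best)
                    ):
                        best = dev
            if best is not None:
                errors.append(best)
    return np.asarray(errors)
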