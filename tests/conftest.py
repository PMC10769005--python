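"""Shared fixtures: small seeded phantoms and their preprocessed products.

Session scope amortizes phantom generation and preprocessing across test
modules; everything is generated programmatically from fixed seeds.
"""

from __future__ import annotations

import numpy as np
import pytest

from sddmark import labeling as lab
from sddmark import preprocess as prep
from sddmark import synthetic_msi as syn

SMALL = dict(grid_width=100, grid_height=60, n_deposits=6, deposit_size_px=(5, 8))


@pytest.fixture(scope="session")
def small_phantom():
    """Noisy 100x60 phantom under default study conditions, seed 1."""
    config = syn.PhantomConfig(seed=1, **SMALL)
    dataset, truth = syn.generate_phantom(config)
    return config, dataset, truth


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Same geometry with drift, noise, and spikes all switched off."""
    config = syn.PhantomConfig(
        seed=1, drift_ppm_range=0.0, noise_floor=0.0, spike_rate=0.0,
        intensity_sigma=0.0, **SMALL
    )
    dataset, truth = syn.generate_phantom(config)
    return config, dataset, truth


@pytest.fixture(scope="session")
def preprocessed(small_phantom):
    """Aligned, calibrated, peak-picked, filtered, normalized small phantom."""
    _config, dataset, truth = small_phantom
    axis = prep.build_common_axis(*dataset.mz_range, spacing_ppm=1.5)
    model = prep.select_alignment_peaks(dataset, axis=axis)
    aligned, model = prep.align_dataset(dataset, model)
    calibrants = syn.default_calibrants()["mz"].to_numpy()
    aligned, _cal = prep.calibrate(aligned, calibrants)
    avg = prep.mean_spectrum(aligned, axis)
    peaks = prep.pick_peaks(avg, axis)
    matrix = prep.extract_features(aligned, peaks)
    matrix = prep.filter_features(matrix)
    matrix, _factors = prep.robust_tic_normalize(matrix)
    return matrix, truth


@pytest.fixture(scope="session")
def trained(preprocessed):
    """Labels, split, and fitted classifier on the small phantom."""
    from sddmark import classify as clf

    matrix, truth = preprocessed
    nmf = lab.nmf_patterns(matrix, rank=8, seed=1)
    mask = lab.mask_from_pattern(nmf)
    labels = lab.balance_labels(mask, seed=1)
    (pix_tr, y_tr), (pix_te, y_te) = clf.split_train_test(labels, seed=1)
    model = clf.train(matrix, pix_tr, y_tr, pix_te, y_te, seed=1)
    return matrix, truth, labels, model


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a, b = a.astype(bool), b.astype(bool)
    denom = a.sum() + b.sum()
    return 2.0 * np.logical_and(a, b).sum() / denom if denom else 1.0
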