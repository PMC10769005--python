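"""Training-label construction: NMF latent patterns -> positive mask ->
balanced negative sampling.

The positive (SDD) class comes from thresholding one spatial component of a
non-negative matrix factorization of the normalized feature matrix; a
user-supplied correction mask can veto pixels. The negative (background)
class is sampled uniformly from the remaining pixels to match the positive
class size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import NMF

from .msio import (
    LABEL_BACKGROUND,
    LABEL_SDD,
    LABEL_UNLABELED,
    FeatureMatrix,
    LabelMask,
)

__all__ = [
    "NMFResult",
    "TrainingLabels",
    "nmf_patterns",
    "select_component",
    "mask_from_pattern",
    "balance_labels",
]


@dataclass
class NMFResult:
    """Non-negative factorization of a feature matrix into spatial patterns."""

    rank: int
    spatial_scores: np.ndarray  # (n_pixels, rank)
    spectral_loadings: np.ndarray  # (rank, n_features)
    reconstruction_error: float
    pixel_index: np.ndarray
    grid_shape: tuple[int, int]
    seed: int

    def score_image(self, component: int) -> np.ndarray:
        w, h = self.grid_shape
        img = np.zeros((h, w))
        img[self.pixel_index[:, 1], self.pixel_index[:, 0]] = self.spatial_scores[
            :, component
        ]
        return img


@dataclass
class TrainingLabels:
    """Balanced positive/negative pixel sets, as (x, y) coordinate arrays."""

    positive_pixels: np.ndarray  # (n_pos, 2)
    negative_pixels: np.ndarray  # (n_neg, 2)
    seed: int

    def __post_init__(self) -> None:
        pos = {tuple(p) for p in self.positive_pixels}
        neg = {tuple(p) for p in self.negative_pixels}
        if pos & neg:
            raise ValueError("positive and negative pixel sets overlap")

    @property
    def balance_ratio(self) -> float:
        return len(self.negative_pixels) / max(len(self.positive_pixels), 1)


def nmf_patterns(matrix: FeatureMatrix, rank: int = 8, seed: int = 0,
                 max_iter: int = 400) -> NMFResult:
    """Seeded multiplicative-update NMF of the (normalized) feature matrix."""
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if rank > min(matrix.n_pixels, matrix.n_features):
        raise ValueError("rank exceeds matrix dimensions")
    model = NMF(
        n_components=rank,
        init="random",
        solver="mu",
        beta_loss="frobenius",
        max_iter=max_iter,
        tol=1e-6,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*Maximum number of iterations.*")
        scores = model.fit_transform(matrix.values)
    return NMFResult(
        rank=rank,
        spatial_scores=scores,
        spectral_loadings=model.components_,
        reconstruction_error=float(model.reconstruction_err_),
        pixel_index=matrix.pixel_index,
        grid_shape=matrix.grid_shape,
        seed=seed,
    )


def select_component(nmf: NMFResult) -> int:
    """Pick the component whose active region looks most lesion-like.

    Components are first screened for contrast: only those whose Otsu-active
    region captures at least 80% of the component's total score mass (the
    anatomical patterns, as opposed to diffuse noise components) compete.
    Among those, the winner maximizes the coefficient of variation of the
    active region's per-column pixel count: tissue strata are horizontal
    bands, translation-invariant along the section (CV ~ 0), whereas dome
    lesions — isolated or confluent — give a strongly oscillating column
    profile. This is the automated stand-in for the human choice of the
    lesion pattern; an explicit component override is available everywhere
    it is consumed.
    """
    from skimage.filters import threshold_otsu

    def _metrics(c: int) -> tuple[float, float]:
        img = nmf.score_image(c)
        if np.ptp(img) <= 0 or img.sum() <= 0:
            return 0.0, -np.inf
        binary = img > threshold_otsu(img.ravel())
        mass_fraction = float(img[binary].sum() / img.sum())
        column_counts = binary.sum(axis=0)
        mean = column_counts.mean()
        if mean <= 0:
            return mass_fraction, -np.inf
        return mass_fraction, float(column_counts.std() / mean)

    stats = [_metrics(c) for c in range(nmf.rank)]
    candidates = [c for c in range(nmf.rank) if stats[c][0] >= 0.8]
    if not candidates:
        candidates = list(range(nmf.rank))
    return max(candidates, key=lambda c: stats[c][1])


def mask_from_pattern(
    nmf: NMFResult,
    component: int | None = None,
    threshold_quantile: float | None = None,
    correction: LabelMask | None = None,
) -> LabelMask:
    """Threshold one NMF spatial pattern into an SDD-positive mask.

    With ``threshold_quantile=None`` the cut is chosen by Otsu's method on
    the component's scores (data-driven lesion/background split); a fixed
    quantile is available for manual control. A correction mask can remove
    (background/unlabeled there) or add (SDD there) pixels, standing in for
    the histology-guided manual correction step.
    """
    if component is None:
        component = select_component(nmf)
    if not 0 <= component < nmf.rank:
        raise ValueError(f"component {component} out of range (rank {nmf.rank})")
    scores = nmf.spatial_scores[:, component]
    if threshold_quantile is None:
        from skimage.filters import threshold_otsu

        thr = float(threshold_otsu(scores)) if np.ptp(scores) > 0 else np.inf
        positive = scores > thr
    else:
        if not 0 <= threshold_quantile <= 1:
            raise ValueError("threshold_quantile must be in [0, 1]")
        thr = np.quantile(scores, threshold_quantile)
        positive = scores > thr
    if not np.any(positive):
        warnings.warn("threshold above maximum score: empty positive mask")
    w, h = nmf.grid_shape
    labels = np.zeros((h, w), dtype=np.int64)
    pix = nmf.pixel_index[positive]
    labels[pix[:, 1], pix[:, 0]] = LABEL_SDD
    source = "nmf"
    if correction is not None:
        if correction.labels.shape != labels.shape:
            raise ValueError("correction mask shape mismatch")
        labels[correction.labels == LABEL_BACKGROUND] = LABEL_UNLABELED
        labels[correction.labels == LABEL_SDD] = LABEL_SDD
        source = "manual-correction"
    return LabelMask(labels=labels, source=source)


def balance_labels(mask: LabelMask, seed: int = 0) -> TrainingLabels:
    """Sample negatives uniformly from non-positive pixels, one per positive.

    SDD pixels are excluded from the background class by construction. If
    fewer non-positive pixels exist than positives, all are used (warned).
    """
    pos = mask.positive_pixels()
    if len(pos) == 0:
        raise ValueError("mask has no positive (SDD) pixels")
    ys, xs = np.nonzero(mask.labels != LABEL_SDD)
    pool = np.stack([xs, ys], axis=1)
    if len(pool) == 0:
        raise ValueError("mask has no non-positive pixels to sample negatives from")
    n = len(pos)
    rng = np.random.default_rng(seed)
    if len(pool) < n:
        warnings.warn(
            f"only {len(pool)} non-positive pixels available for {n} positives"
        )
        neg = pool
    else:
        neg = pool[rng.choice(len(pool), size=n, replace=False)]
    return TrainingLabels(positive_pixels=pos, negative_pixels=neg, seed=seed)
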