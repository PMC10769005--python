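"""Containers and file IO for centroided imaging mass spectrometry data.

The in-memory model is deliberately small: an :class:`IMSDataset` is a list of
per-pixel :class:`CentroidSpectrum` peak lists on a shared grid, and the
classifier input is a dense pixels x features :class:`FeatureMatrix`.
imzML/ibd files (processed mode only) are read and written through pyimzml.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CentroidSpectrum",
    "IMSDataset",
    "FeatureMatrix",
    "LabelMask",
    "LABEL_UNLABELED",
    "LABEL_BACKGROUND",
    "LABEL_SDD",
    "read_imzml",
    "write_imzml",
    "export_ion_image",
]

LABEL_UNLABELED = 0
LABEL_BACKGROUND = 1
LABEL_SDD = 2

# PNG gray levels for the three label states.
_LABEL_TO_GRAY = {LABEL_UNLABELED: 0, LABEL_BACKGROUND: 128, LABEL_SDD: 255}
_GRAY_TO_LABEL = {v: k for k, v in _LABEL_TO_GRAY.items()}


@dataclass
class CentroidSpectrum:
    """One pixel's centroided peak list.

    ``mz`` is kept strictly increasing; constructor sorts and co-permutes
    intensities if needed and merges nothing.
    """

    mz: np.ndarray
    intensity: np.ndarray
    pixel: tuple[int, int]  # (x, y), 0-based, x = column

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if self.mz.size > 1 and np.any(np.diff(self.mz) <= 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return int(self.mz.size)

    @property
    def tic(self) -> float:
        return float(self.intensity.sum())


@dataclass
class IMSDataset:
    """A collection of centroid spectra on a rectangular pixel grid."""

    spectra: list[CentroidSpectrum]
    polarity: str  # "positive" | "negative"
    mz_range: tuple[float, float]
    grid_shape: tuple[int, int]  # (width, height)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.polarity not in ("positive", "negative"):
            raise ValueError("polarity must be 'positive' or 'negative'")
        w, h = self.grid_shape
        seen: set[tuple[int, int]] = set()
        for s in self.spectra:
            x, y = s.pixel
            if not (0 <= x < w and 0 <= y < h):
                raise ValueError(f"pixel {s.pixel} outside grid {self.grid_shape}")
            if s.pixel in seen:
                raise ValueError(f"duplicate pixel coordinate {s.pixel}")
            seen.add(s.pixel)

    def __len__(self) -> int:
        return len(self.spectra)

    def pixel_index(self) -> np.ndarray:
        """(n_pixels, 2) array of (x, y) in spectrum order."""
        return np.array([s.pixel for s in self.spectra], dtype=np.int64)

    def map_image(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter one value per spectrum onto an (height, width) image."""
        w, h = self.grid_shape
        img = np.full((h, w), fill, dtype=np.float64)
        for s, v in zip(self.spectra, values):
            x, y = s.pixel
            img[y, x] = v
        return img


@dataclass
class FeatureMatrix:
    """Dense pixels x picked-features intensity table (classifier input)."""

    values: np.ndarray  # (n_pixels, n_features), >= 0
    feature_mz: np.ndarray  # strictly increasing
    feature_tol_ppm: float
    pixel_index: np.ndarray  # (n_pixels, 2) of (x, y)
    grid_shape: tuple[int, int]
    normalized: bool = False
    norm_factors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.feature_mz = np.asarray(self.feature_mz, dtype=np.float64)
        self.pixel_index = np.asarray(self.pixel_index, dtype=np.int64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape != (len(self.pixel_index), len(self.feature_mz)):
            raise ValueError("values shape inconsistent with pixel_index / feature_mz")
        if np.any(self.values < 0):
            raise ValueError("feature intensities must be non-negative")
        if self.feature_mz.size > 1 and np.any(np.diff(self.feature_mz) <= 0):
            raise ValueError("feature_mz must be strictly increasing")
        if self.normalized and self.norm_factors is None:
            raise ValueError("normalized matrix must carry norm_factors")

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def feature_column(self, mz: float, tol_ppm: float | None = None) -> int:
        """Index of the feature nearest ``mz`` within tolerance."""
        tol = self.feature_tol_ppm if tol_ppm is None else tol_ppm
        idx = int(np.argmin(np.abs(self.feature_mz - mz)))
        err_ppm = abs(self.feature_mz[idx] - mz) / mz * 1e6
        if err_ppm > tol:
            raise KeyError(f"no feature within {tol} ppm of m/z {mz}")
        return idx

    def map_image(self, column: int) -> np.ndarray:
        w, h = self.grid_shape
        img = np.zeros((h, w), dtype=np.float64)
        img[self.pixel_index[:, 1], self.pixel_index[:, 0]] = self.values[:, column]
        return img

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[f"{mz:.5f}" for mz in self.feature_mz])
        df.insert(0, "x", self.pixel_index[:, 0])
        df.insert(1, "y", self.pixel_index[:, 1])
        return df


@dataclass
class LabelMask:
    """Per-pixel {SDD, background, unlabeled} assignment with provenance."""

    labels: np.ndarray  # (height, width) of label codes
    source: str  # "nmf" | "file" | "manual-correction"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D image")
        valid = {LABEL_UNLABELED, LABEL_BACKGROUND, LABEL_SDD}
        if not set(np.unique(self.labels)) <= valid:
            raise ValueError("labels must be in {unlabeled, background, SDD}")

    @property
    def counts(self) -> dict[str, int]:
        return {
            "SDD": int(np.sum(self.labels == LABEL_SDD)),
            "background": int(np.sum(self.labels == LABEL_BACKGROUND)),
            "unlabeled": int(np.sum(self.labels == LABEL_UNLABELED)),
        }

    def positive_pixels(self) -> np.ndarray:
        ys, xs = np.nonzero(self.labels == LABEL_SDD)
        return np.stack([xs, ys], axis=1)

    def to_png(self, path: str | Path) -> None:
        from PIL import Image

        gray = np.zeros(self.labels.shape, dtype=np.uint8)
        for code, level in _LABEL_TO_GRAY.items():
            gray[self.labels == code] = level
        Image.fromarray(gray, mode="L").save(Path(path))

    @classmethod
    def from_png(cls, path: str | Path, source: str = "file") -> "LabelMask":
        from PIL import Image

        gray = np.asarray(Image.open(Path(path)).convert("L"))
        labels = np.zeros(gray.shape, dtype=np.int64)
        for level, code in _GRAY_TO_LABEL.items():
            labels[gray == level] = code
        return cls(labels=labels, source=source)

    def to_csv(self, path: str | Path) -> None:
        ys, xs = np.nonzero(self.labels != LABEL_UNLABELED)
        names = {LABEL_SDD: "SDD", LABEL_BACKGROUND: "background"}
        df = pd.DataFrame(
            {"x": xs, "y": ys, "label": [names[int(v)] for v in self.labels[ys, xs]]}
        )
        df.to_csv(Path(path), index=False)


def read_imzml(path: str | Path) -> IMSDataset:
    """Read a processed-mode (centroided) imzML/ibd pair.

    Continuous-mode files are rejected: this pipeline operates on centroid
    peak lists, not profile spectra. imzML 1-based pixel positions are
    converted to the package's 0-based (x=column, y=row) convention.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = ImzMLParser(str(path))
    try:
        mode_flags = parser.metadata.file_description.param_by_name
    except AttributeError:  # older pyimzml
        mode_flags = {}
    if "continuous" in mode_flags or getattr(parser, "continuous_mode", False):
        raise ValueError(
            f"{path.name} is continuous-mode imzML; only processed-mode "
            "(centroided) data are supported"
        )

    spectra: list[CentroidSpectrum] = []
    mz_lo, mz_hi = np.inf, -np.inf
    for i, (x, y, _z) in enumerate(parser.coordinates):
        mz, inten = parser.getspectrum(i)
        mz = np.asarray(mz, dtype=np.float64)
        inten = np.clip(np.asarray(inten, dtype=np.float64), 0.0, None)
        spectra.append(CentroidSpectrum(mz=mz, intensity=inten, pixel=(x - 1, y - 1)))
        if mz.size:
            mz_lo = min(mz_lo, float(mz[0]))
            mz_hi = max(mz_hi, float(mz[-1]))
    if not spectra:
        raise ValueError(f"{path.name} contains no spectra")

    width = max(s.pixel[0] for s in spectra) + 1
    height = max(s.pixel[1] for s in spectra) + 1

    polarity = "positive"
    meta = {}
    try:
        meta = dict(parser.metadata.pretty().get("scan_settings", {}))
    except Exception:
        pass
    scan_polarity = _polarity_from_metadata(parser)
    if scan_polarity:
        polarity = scan_polarity

    if not np.isfinite(mz_lo):
        mz_lo, mz_hi = 0.0, 0.0
    return IMSDataset(
        spectra=spectra,
        polarity=polarity,
        mz_range=(mz_lo, mz_hi),
        grid_shape=(width, height),
        provenance={"source": str(path), **meta},
    )


def _polarity_from_metadata(parser) -> str | None:
    try:
        text = str(parser.metadata.pretty()).lower()
    except Exception:
        return None
    if "negative" in text:
        return "negative"
    if "positive" in text:
        return "positive"
    return None


def write_imzml(dataset: IMSDataset, path: str | Path) -> Path:
    """Write a processed-mode imzML/ibd pair (float64 m/z, float32 intensity).

    Pixels with no peaks are skipped (the format stores occupied pixels only).
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    if len(dataset) == 0:
        raise ValueError("refusing to write a dataset with no pixels")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with ImzMLWriter(
        str(path),
        polarity=dataset.polarity,
        mode="processed",
        mz_dtype=np.float64,
        intensity_dtype=np.float32,
    ) as writer:
        for s in dataset.spectra:
            if len(s) == 0:
                continue
            x, y = s.pixel
            writer.addSpectrum(s.mz, s.intensity, (x + 1, y + 1, 1))
    return path


def export_ion_image(
    matrix: FeatureMatrix,
    feature_mz: float,
    path: str | Path,
    tol_ppm: float | None = None,
    cmap: str = "viridis",
) -> Path:
    """Render one feature's ion image, scaled to its own maximum intensity.

    Pixels without spectra render as the colormap's zero/background color.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    col = matrix.feature_column(feature_mz, tol_ppm=tol_ppm)
    img = matrix.map_image(col)
    vmax = float(img.max())
    if vmax <= 0:
        warnings.warn(f"feature m/z {feature_mz} has all-zero intensity")
        vmax = 1.0
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    plt.imsave(path, img, vmin=0.0, vmax=vmax, cmap=cmap)
    return path
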