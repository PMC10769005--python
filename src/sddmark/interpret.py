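"""SHAP-based model interpretation: local values, global ranking with
direction, spatial SHAP maps, and the top-N marker shortlist.

Local Shapley values are exact path-dependent TreeSHAP values on the model's
log-odds margin, computed by the booster itself (``pred_contribs``), so the
additivity identity base + sum(values) == margin holds to float precision at
every pixel. The global score of a feature is the mean absolute local value
over all pixels; its direction (red/blue in the bar-plot convention) is the
sign of the Pearson correlation between the feature's intensity and its
local SHAP value.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import xgboost as xgb

from .annotate import C13_MASS_DIFF, Annotation
from .classify import ClassifierModel
from .msio import FeatureMatrix

__all__ = [
    "ShapResult",
    "local_shap",
    "global_ranking",
    "shap_map",
    "save_shap_map",
    "shortlist",
]


@dataclass
class ShapResult:
    """Per-pixel per-feature log-odds contributions plus global summary."""

    local_values: np.ndarray  # (n_pixels, n_features)
    base_value: float
    feature_mz: np.ndarray
    pixel_index: np.ndarray
    grid_shape: tuple[int, int]
    global_score: np.ndarray | None = None
    direction: np.ndarray | None = None  # +1 / -1 / 0 (none)
    ranking: np.ndarray | None = None  # feature indices, best first


def local_shap(model: ClassifierModel, matrix: FeatureMatrix) -> ShapResult:
    """Exact TreeSHAP values for every pixel on the margin (log-odds) scale."""
    model._check(matrix)
    booster = model.booster.get_booster()
    contribs = booster.predict(xgb.DMatrix(matrix.values), pred_contribs=True)
    base = float(contribs[0, -1])
    return ShapResult(
        local_values=np.asarray(contribs[:, :-1], dtype=np.float64),
        base_value=base,
        feature_mz=matrix.feature_mz.copy(),
        pixel_index=matrix.pixel_index.copy(),
        grid_shape=matrix.grid_shape,
    )


def global_ranking(shap: ShapResult, matrix: FeatureMatrix) -> ShapResult:
    """Rank features by mean |local SHAP|; attach intensity-correlation sign.

    Ties in the global score break toward the lower m/z. Features the model
    never uses (all-zero SHAP column) get direction 0 ("none") and sort last.
    """
    vals = shap.local_values
    score = np.mean(np.abs(vals), axis=0)
    direction = np.zeros(vals.shape[1], dtype=np.int64)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        x = matrix.values[:, j]
        if np.ptp(col) == 0 or np.ptp(x) == 0:
            continue
        r = np.corrcoef(x, col)[0, 1]
        if np.isfinite(r) and r != 0:
            direction[j] = 1 if r > 0 else -1
    order = np.lexsort((shap.feature_mz, -score))
    shap.global_score = score
    shap.direction = direction
    shap.ranking = order
    return shap


def shap_map(shap: ShapResult, feature_mz: float, tol_ppm: float = 7.0) -> np.ndarray:
    """One feature's local SHAP values scattered onto the pixel grid."""
    j = int(np.argmin(np.abs(shap.feature_mz - feature_mz)))
    if abs(shap.feature_mz[j] - feature_mz) / feature_mz * 1e6 > tol_ppm:
        raise KeyError(f"no feature within {tol_ppm} ppm of m/z {feature_mz}")
    w, h = shap.grid_shape
    img = np.zeros((h, w))
    img[shap.pixel_index[:, 1], shap.pixel_index[:, 0]] = shap.local_values[:, j]
    return img


def save_shap_map(shap: ShapResult, feature_mz: float, path: str | Path) -> Path:
    """Render a SHAP map with a symmetric diverging scale (red +, blue -)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    img = shap_map(shap, feature_mz)
    limit = float(np.abs(img).max()) or 1.0
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    plt.imsave(path, img, vmin=-limit, vmax=limit, cmap="RdBu_r")
    return path


def shortlist(
    shap: ShapResult,
    annotations: list[Annotation] | None = None,
    top_n: int = 20,
    isotope_tol_ppm: float = 7.0,
) -> pd.DataFrame:
    """Top-N ranked features with direction, annotation, and isotope links.

    A shortlist row whose m/z sits k x 1.0033548 above another shortlisted
    (or annotated) feature within tolerance is flagged as that feature's
    carbon-13 isotopologue.
    """
    if shap.ranking is None or shap.global_score is None:
        raise ValueError("run global_ranking before building a shortlist")
    ann_by_mz: dict[float, Annotation] = {}
    if annotations:
        for a in annotations:
            ann_by_mz[a.feature_mz] = a
    top = shap.ranking[: max(top_n, 0)]
    dir_names = {1: "positive", -1: "negative", 0: "none"}
    rows = []
    top_mz = shap.feature_mz[top]
    for rank, j in enumerate(top, start=1):
        mz = float(shap.feature_mz[j])
        annotation = ""
        a = _nearest_annotation(ann_by_mz, mz)
        if a is not None and a.matched:
            annotation = a.label
        isotope_of = ""
        for k in (1, 2, 3):
            target = mz - k * C13_MASS_DIFF
            base = top_mz[np.abs(top_mz - target) / target * 1e6 <= isotope_tol_ppm]
            if base.size:
                isotope_of = f"{base[0]:.4f}"
                break
        rows.append(
            {
                "rank": rank,
                "mz": mz,
                "tol_ppm": isotope_tol_ppm,
                "global_score": float(shap.global_score[j]),
                "direction": dir_names[int(shap.direction[j])]
                if shap.direction is not None
                else "none",
                "annotation": annotation,
                "isotope_of_mz": isotope_of,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "rank", "mz", "tol_ppm", "global_score", "direction",
            "annotation", "isotope_of_mz",
        ],
    )


def _nearest_annotation(ann_by_mz: dict[float, Annotation], mz: float):
    best, best_err = None, np.inf
    for amz, a in ann_by_mz.items():
        err = abs(amz - mz) / mz * 1e6
        if err < best_err and err <= a.tol_ppm:
            best, best_err = a, err
    return best
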