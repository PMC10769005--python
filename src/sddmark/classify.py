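"""Per-pixel SDD vs background gradient-boosted classification.

One XGBoost model per (polarity) dataset, trained on a stratified 67/33
split of the balanced labels. Per-node column subsampling is on by default
so that near-collinear isotopologue features share splits (and hence later
share SHAP attribution) instead of one isotope absorbing the whole signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import xgboost as xgb
from sklearn.metrics import (
    balanced_accuracy_score,
    f1_score,
    precision_score,
    recall_score,
)
from sklearn.model_selection import train_test_split

from .labeling import TrainingLabels
from .msio import FeatureMatrix

__all__ = [
    "DEFAULT_HYPERPARAMETERS",
    "ClassifierModel",
    "ClassifierMetrics",
    "split_train_test",
    "train",
    "evaluate",
    "predict_map",
]

DEFAULT_HYPERPARAMETERS: dict = {
    "n_estimators": 200,
    "max_depth": 4,
    "learning_rate": 0.1,
    "objective": "binary:logistic",
    "colsample_bynode": 0.2,
    "tree_method": "hist",
}


@dataclass
class ClassifierModel:
    """Fitted booster plus everything needed to reproduce and audit it."""

    booster: xgb.XGBClassifier
    feature_mz: np.ndarray
    hyperparameters: dict
    train_pixels: np.ndarray  # (n, 2) of (x, y)
    test_pixels: np.ndarray
    train_y: np.ndarray
    test_y: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        train_set = {tuple(p) for p in self.train_pixels}
        test_set = {tuple(p) for p in self.test_pixels}
        if train_set & test_set:
            raise ValueError("train and test pixel sets overlap")

    def _check(self, matrix: FeatureMatrix) -> None:
        if matrix.n_features != self.feature_mz.size or not np.allclose(
            matrix.feature_mz, self.feature_mz
        ):
            raise ValueError("feature matrix does not match the model's features")

    def predict_proba(self, matrix: FeatureMatrix) -> np.ndarray:
        self._check(matrix)
        return self.booster.predict_proba(matrix.values)[:, 1]

    def predict_margin(self, matrix: FeatureMatrix) -> np.ndarray:
        """Raw log-odds output (the scale on which SHAP values are additive)."""
        self._check(matrix)
        booster = self.booster.get_booster()
        return booster.predict(xgb.DMatrix(matrix.values), output_margin=True)

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.booster.get_booster().save_model(directory / "model.json")
        manifest = {
            "feature_mz": self.feature_mz.tolist(),
            "hyperparameters": {
                k: v for k, v in self.hyperparameters.items() if not callable(v)
            },
            "seed": self.seed,
            "n_train": int(len(self.train_pixels)),
            "n_test": int(len(self.test_pixels)),
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return directory


@dataclass(frozen=True)
class ClassifierMetrics:
    """Held-out metrics for the SDD (positive) class."""

    balanced_accuracy: float
    precision: float
    recall: float
    f1: float
    n_test: int

    def __post_init__(self) -> None:
        if self.precision + self.recall > 0:
            hm = 2 * self.precision * self.recall / (self.precision + self.recall)
            if abs(hm - self.f1) > 1e-9:
                raise ValueError("f1 inconsistent with precision/recall")

    def as_dict(self) -> dict:
        return {
            "balanced_accuracy": self.balanced_accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "n_test": self.n_test,
        }


def split_train_test(
    labels: TrainingLabels,
    train_fraction: float = 0.67,
    seed: int = 0,
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Stratified random split of labeled pixels; returns ((pix, y), (pix, y))."""
    pixels = np.concatenate([labels.positive_pixels, labels.negative_pixels])
    y = np.concatenate(
        [
            np.ones(len(labels.positive_pixels), dtype=np.int64),
            np.zeros(len(labels.negative_pixels), dtype=np.int64),
        ]
    )
    if np.sum(y == 1) < 2 or np.sum(y == 0) < 2:
        raise ValueError("need at least two pixels per class to split")
    pix_tr, pix_te, y_tr, y_te = train_test_split(
        pixels, y, train_size=train_fraction, stratify=y, random_state=seed
    )
    return (pix_tr, y_tr), (pix_te, y_te)


def _rows_for_pixels(matrix: FeatureMatrix, pixels: np.ndarray) -> np.ndarray:
    w, _h = matrix.grid_shape
    lookup = {(int(x), int(y)): i for i, (x, y) in enumerate(matrix.pixel_index)}
    try:
        return np.array([lookup[(int(x), int(y))] for x, y in pixels], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"labeled pixel {exc.args[0]} absent from matrix") from exc


def train(
    matrix: FeatureMatrix,
    train_pixels: np.ndarray,
    train_y: np.ndarray,
    test_pixels: np.ndarray | None = None,
    test_y: np.ndarray | None = None,
    hyperparameters: dict | None = None,
    seed: int = 0,
) -> ClassifierModel:
    """Fit the gradient-boosted tree classifier on the training pixels.

    Deterministic given the seed: the booster runs single-threaded with the
    histogram tree method and a fixed random state.
    """
    params = dict(DEFAULT_HYPERPARAMETERS)
    if hyperparameters:
        params.update(hyperparameters)
    rows = _rows_for_pixels(matrix, train_pixels)
    y = np.asarray(train_y, dtype=np.int64)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    clf = xgb.XGBClassifier(random_state=seed, n_jobs=1, **params)
    clf.fit(matrix.values[rows], y)
    return ClassifierModel(
        booster=clf,
        feature_mz=matrix.feature_mz.copy(),
        hyperparameters=params,
        train_pixels=np.asarray(train_pixels),
        test_pixels=np.asarray(test_pixels) if test_pixels is not None else np.empty((0, 2), dtype=np.int64),
        train_y=y,
        test_y=np.asarray(test_y, dtype=np.int64) if test_y is not None else np.empty(0, dtype=np.int64),
        seed=seed,
    )


def evaluate(
    model: ClassifierModel,
    matrix: FeatureMatrix,
    test_pixels: np.ndarray | None = None,
    test_y: np.ndarray | None = None,
    threshold: float = 0.5,
) -> ClassifierMetrics:
    """Held-out metrics: balanced accuracy plus SDD-class precision/recall/F1."""
    if test_pixels is None:
        test_pixels, test_y = model.test_pixels, model.test_y
    if len(test_pixels) == 0:
        raise ValueError("empty test set")
    train_set = {tuple(p) for p in model.train_pixels}
    if any(tuple(p) in train_set for p in np.asarray(test_pixels)):
        raise ValueError("test pixels overlap the training set")
    rows = _rows_for_pixels(matrix, np.asarray(test_pixels))
    proba = model.booster.predict_proba(matrix.values[rows])[:, 1]
    pred = (proba >= threshold).astype(np.int64)
    y = np.asarray(test_y, dtype=np.int64)
    return ClassifierMetrics(
        balanced_accuracy=float(balanced_accuracy_score(y, pred)),
        precision=float(precision_score(y, pred, zero_division=0)),
        recall=float(recall_score(y, pred, zero_division=0)),
        f1=float(f1_score(y, pred, zero_division=0)),
        n_test=int(len(y)),
    )


def predict_map(model: ClassifierModel, matrix: FeatureMatrix) -> np.ndarray:
    """Per-pixel SDD probability rendered on the (height, width) grid."""
    proba = model.predict_proba(matrix)
    w, h = matrix.grid_shape
    img = np.zeros((h, w))
    img[matrix.pixel_index[:, 1], matrix.pixel_index[:, 0]] = proba
    return img
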