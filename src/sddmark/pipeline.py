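"""End-to-end orchestration: simulate -> preprocess -> label -> train ->
explain -> annotate, with a validated config and a reproducible report.

Every constant the workflow depends on (6 alignment peaks at >=50%
occupancy, >=4 calibrants, 1.5 ppm axis spacing, +/-7 ppm feature windows,
67/33 split, top-20 shortlist) is a named config default, never hard-coded
in a stage.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import annotate as ann
from . import classify as clf
from . import interpret as interp
from . import labeling as lab
from . import msio
from . import preprocess as prep
from . import synthetic_msi as syn

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "run_phantom_analysis"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhantomSection(_Section):
    grid_width: int = 200
    grid_height: int = 120
    n_deposits: int = 12
    deposit_size_px: tuple[int, int] = (8, 12)
    drift_ppm_range: float = 15.0
    pixel_scale_range: tuple[float, float] = (0.5, 2.0)
    intensity_sigma: float = 0.25
    noise_floor: float = 1.0
    spike_rate: float = 0.02
    polarity: str = "positive"


class PreprocessSection(_Section):
    axis_spacing_ppm: float = 1.5
    n_alignment_peaks: int = 6
    min_occupancy: float = 0.5
    max_shift_ppm: float = 30.0
    feature_tol_ppm: float = 7.0
    snr_threshold: float = 3.0
    min_prominence: float = 0.0
    min_feature_occupancy: float = 0.02
    calibrate: bool = True


class LabelingSection(_Section):
    rank: int = 8
    component: int | None = None
    threshold_quantile: float | None = None


class ClassifySection(_Section):
    train_fraction: float = 0.67
    n_estimators: int = 200
    max_depth: int = 4
    learning_rate: float = 0.1
    colsample_bynode: float = 0.2


class InterpretSection(_Section):
    top_n: int = 20


class AnnotateSection(_Section):
    tol_ppm: float = 10.0
    max_isotopes: int = 3


class RunConfig(_Section):
    """Schema-validated configuration for one end-to-end run."""

    seed: int = 0
    output_dir: str | None = None
    phantom: PhantomSection = PhantomSection()
    preprocess: PreprocessSection = PreprocessSection()
    labeling: LabelingSection = LabelingSection()
    classify: ClassifySection = ClassifySection()
    interpret: InterpretSection = InterpretSection()
    annotate: AnnotateSection = AnnotateSection()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)


@dataclass
class RunReport:
    """What one pipeline run produced, with the numbers worth comparing."""

    seed: int
    stage_timings: dict[str, float]
    n_pixels: int
    n_picked_peaks: int
    calibration_residual_ppm: float | None
    label_counts: dict[str, int]
    metrics: dict
    shortlist: pd.DataFrame
    marker_recovery: dict | None = None
    manifest: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "seed": self.seed,
            "stage_timings_s": self.stage_timings,
            "n_pixels": self.n_pixels,
            "n_picked_peaks": self.n_picked_peaks,
            "calibration_residual_ppm": self.calibration_residual_ppm,
            "label_counts": self.label_counts,
            "classifier_metrics": self.metrics,
            "shortlist": self.shortlist.to_dict(orient="records"),
            "marker_recovery": self.marker_recovery,
            "manifest": self.manifest,
        }
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(payload, indent=2))
        return path


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages in order on a freshly simulated phantom.

    Deterministic for a fixed config and seed (single-threaded training).
    Artifacts (imzML, masks, shortlist CSV, report JSON) are written when
    ``config.output_dir`` is set.
    """
    timings: dict[str, float] = {}
    manifest: dict[str, str] = {}
    out = Path(config.output_dir) if config.output_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    def _stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - annotate stage name
                raise StageError(name, exc) from exc
            timings[name] = round(time.perf_counter() - t0, 3)
            log.info("stage %s done in %.2fs", name, timings[name])
            return result

        return wrap

    # --- simulate -----------------------------------------------------------
    pc = config.phantom
    phantom_cfg = syn.PhantomConfig(
        grid_width=pc.grid_width,
        grid_height=pc.grid_height,
        n_deposits=pc.n_deposits,
        deposit_size_px=pc.deposit_size_px,
        drift_ppm_range=pc.drift_ppm_range,
        pixel_scale_range=pc.pixel_scale_range,
        intensity_sigma=pc.intensity_sigma,
        noise_floor=pc.noise_floor,
        spike_rate=pc.spike_rate,
        polarity=pc.polarity,
        seed=config.seed,
    )
    dataset, truth = _stage("simulate")(lambda: syn.generate_phantom(phantom_cfg))
    if out:
        path = msio.write_imzml(dataset, out / "phantom.imzML")
        manifest["imzml"] = str(path)
        np.savetxt(out / "deposit_mask.csv", truth.deposit_mask, fmt="%d", delimiter=",")
        manifest["deposit_mask"] = str(out / "deposit_mask.csv")
        truth.peak_table.to_csv(out / "peak_table.csv", index=False)
        manifest["peak_table"] = str(out / "peak_table.csv")

    # --- preprocess ---------------------------------------------------------
    pp = config.preprocess

    def _preprocess():
        axis = prep.build_common_axis(*dataset.mz_range, spacing_ppm=pp.axis_spacing_ppm)
        align_model = prep.select_alignment_peaks(
            dataset,
            n_peaks=pp.n_alignment_peaks,
            min_fraction=pp.min_occupancy,
            tol_ppm=pp.max_shift_ppm,
            axis=axis,
        )
        aligned, align_model = prep.align_dataset(
            dataset, align_model, max_shift_ppm=pp.max_shift_ppm
        )
        residual = None
        if pp.calibrate:
            calibrants = syn.default_calibrants()["mz"].to_numpy()
            aligned, cal_model = prep.calibrate(aligned, calibrants)
            residual = cal_model.median_abs_residual_ppm
        avg = prep.mean_spectrum(aligned, axis)
        peaks = prep.pick_peaks(
            avg, axis, snr_threshold=pp.snr_threshold, min_prominence=pp.min_prominence
        )
        matrix = prep.extract_features(aligned, peaks, tol_ppm=pp.feature_tol_ppm)
        matrix = prep.filter_features(matrix, min_occupancy=pp.min_feature_occupancy)
        matrix, factors = prep.robust_tic_normalize(matrix)
        return matrix, peaks, residual

    matrix, peaks, cal_residual = _stage("preprocess")(_preprocess)
    log.info("picked %d peaks", peaks.size)

    # --- label --------------------------------------------------------------
    lc = config.labeling

    def _label():
        nmf = lab.nmf_patterns(matrix, rank=lc.rank, seed=config.seed)
        mask = lab.mask_from_pattern(
            nmf, component=lc.component, threshold_quantile=lc.threshold_quantile
        )
        labels = lab.balance_labels(mask, seed=config.seed)
        return nmf, mask, labels

    _nmf, mask, labels = _stage("label")(_label)
    if out:
        mask.to_png(out / "labels.png")
        mask.to_csv(out / "labels.csv")
        manifest["labels"] = str(out / "labels.csv")

    # --- train --------------------------------------------------------------
    cc = config.classify

    def _train():
        (pix_tr, y_tr), (pix_te, y_te) = clf.split_train_test(
            labels, train_fraction=cc.train_fraction, seed=config.seed
        )
        hp = {
            "n_estimators": cc.n_estimators,
            "max_depth": cc.max_depth,
            "learning_rate": cc.learning_rate,
            "colsample_bynode": cc.colsample_bynode,
        }
        model = clf.train(
            matrix, pix_tr, y_tr, pix_te, y_te, hyperparameters=hp, seed=config.seed
        )
        metrics = clf.evaluate(model, matrix)
        return model, metrics

    model, metrics = _stage("train")(_train)
    if out:
        model.save(out / "model")
        manifest["model"] = str(out / "model")

    # --- explain ------------------------------------------------------------
    def _explain():
        shap = interp.local_shap(model, matrix)
        shap = interp.global_ranking(shap, matrix)
        return shap

    shap = _stage("explain")(_explain)

    # --- annotate -----------------------------------------------------------
    ac = config.annotate

    def _annotate():
        species = [
            sp.as_lipid(k)
            for sp in phantom_cfg.species_panel
            for k in range(min(sp.n_isotopes, ac.max_isotopes))
        ]
        top = shap.ranking[: config.interpret.top_n]
        return ann.annotate_peaks(
            [float(m) for m in shap.feature_mz[top]], species, tol_ppm=ac.tol_ppm
        )

    annotations = _stage("annotate")(_annotate)
    table = interp.shortlist(shap, annotations, top_n=config.interpret.top_n)
    if out:
        table.to_csv(out / "shortlist.csv", index=False)
        manifest["shortlist"] = str(out / "shortlist.csv")
        if len(table):
            interp.save_shap_map(shap, float(table.iloc[0]["mz"]), out / "shap_map_top1.png")
            manifest["shap_map_top1"] = str(out / "shap_map_top1.png")

    recovery = _marker_recovery(table, truth, tol_ppm=pp.feature_tol_ppm)
    report = RunReport(
        seed=config.seed,
        stage_timings=timings,
        n_pixels=len(dataset),
        n_picked_peaks=int(peaks.size),
        calibration_residual_ppm=cal_residual,
        label_counts=mask.counts,
        metrics=metrics.as_dict(),
        shortlist=table,
        marker_recovery=recovery,
        manifest=manifest,
    )
    if out:
        report.to_json(out / "report.json")
    return report


def _marker_recovery(table: pd.DataFrame, truth: syn.GroundTruth, tol_ppm: float) -> dict:
    """Compare the shortlist against the phantom's planted marker m/z."""
    short_mz = table["mz"].to_numpy() if len(table) else np.empty(0)
    directions = table["direction"].to_numpy() if len(table) else np.empty(0)
    found, found_positive = [], []
    for true_mz in truth.true_marker_mz:
        if short_mz.size == 0:
            found.append(False)
            found_positive.append(False)
            continue
        err = np.abs(short_mz - true_mz) / true_mz * 1e6
        hit = err <= tol_ppm
        found.append(bool(hit.any()))
        found_positive.append(bool((hit & (directions == "positive")).any()))
    return {
        "n_true_markers": int(len(truth.true_marker_mz)),
        "n_recovered": int(sum(found)),
        "n_recovered_positive": int(sum(found_positive)),
        "all_recovered_positive": bool(
            len(found_positive) > 0 and all(found_positive)
        ),
    }


def run_phantom_analysis(
    seed: int,
    grid: tuple[int, int] = (200, 120),
    n_deposits: int = 12,
    deposit_size_px: tuple[int, int] = (8, 12),
    output_dir: str | None = None,
) -> RunReport:
    """Convenience wrapper: default study-condition run at a chosen scale."""
    config = RunConfig(
        seed=seed,
        output_dir=output_dir,
        phantom=PhantomSection(
            grid_width=grid[0],
            grid_height=grid[1],
            n_deposits=n_deposits,
            deposit_size_px=deposit_size_px,
        ),
    )
    return run_pipeline(config)
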