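"""The chained workflow: despeckle -> background correction -> adaptive
threshold -> label -> area filter -> seed selection -> per-cell measurement.

Each stage failure is re-raised with the stage name so callers (and the
CLI exit status) can attribute errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import preprocess, quantify_stats, segment
from .config import effective_sigma_large

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    corrected: np.ndarray
    background: np.ndarray
    despeckled: np.ndarray
    threshold_mask: np.ndarray
    labels_all: np.ndarray
    labels_selected: np.ndarray
    detected: list[tuple[int, int]]
    missed: list[tuple[int, int]]
    measurements: list[quantify_stats.CellMeasurement]
    params_used: dict = field(default_factory=dict)


def run_pipeline(
    img: np.ndarray,
    seeds: segment.SeedSet,
    config: dict,
    tune: bool = False,
) -> PipelineResult:
    """Run the full quantification chain on one image.

    With ``tune=True`` the segmentation (w, s) come from the grid tuner
    instead of the fixed ``segment`` block.
    """
    pre_cfg = config["preprocess"]
    seg_cfg = config["segment"]

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(name, exc) from exc

    if pre_cfg.get("despeckle_method", "gaussian") == "median":
        despeckled = stage("despeckle", preprocess.median_despeckle, img)
    else:
        despeckled = stage(
            "despeckle", preprocess.despeckle, img, pre_cfg["sigma_small"]
        )

    pparams = preprocess.PreprocessParams(
        sigma_small=pre_cfg["sigma_small"],
        sigma_large=effective_sigma_large(config),
        background_mode=pre_cfg["background_mode"],
        expected_cell_diameter=pre_cfg["expected_cell_diameter"],
    )
    background = stage("estimate_background", preprocess.estimate_background, despeckled, pparams)
    corrected = stage(
        "correct_background",
        preprocess.correct_background,
        despeckled,
        background,
        subtract=pre_cfg.get("subtract", False),
    )

    if tune:
        report = stage(
            "tune",
            segment.tune_parameters,
            corrected,
            seeds,
            config["tune"]["window_sizes"],
            config["tune"]["sensitivities"],
            min_area=seg_cfg["min_area"],
            max_area=seg_cfg["max_area"],
            connectivity=seg_cfg["connectivity"],
        )
        w, s = report.best_window, report.best_sensitivity
        log.info("tuned parameters: w=%d s=%.3f rate=%.2f", w, s, report.best_rate)
    else:
        w, s = seg_cfg["window_size"], seg_cfg["sensitivity"]

    sparams = segment.SegmentationParams(
        window_size=w,
        sensitivity=s,
        connectivity=seg_cfg["connectivity"],
        min_area=seg_cfg["min_area"],
        max_area=seg_cfg["max_area"],
    )
    mask = stage("threshold", segment.bradley_threshold, corrected, sparams)
    labels = stage("label", segment.label_components, mask, sparams.connectivity)
    labels = stage("area_filter", segment.filter_by_area, labels, sparams.min_area, sparams.max_area)
    selected, detected, missed = stage("seed_select", segment.select_by_seeds, labels, seeds)
    for pt in missed:
        log.warning("MISSED seed=%s", pt)
    measurements = stage("measure", quantify_stats.measure_cells, corrected, selected)

    return PipelineResult(
        corrected=corrected,
        background=background,
        despeckled=despeckled,
        threshold_mask=mask,
        labels_all=labels,
        labels_selected=selected,
        detected=detected,
        missed=missed,
        measurements=measurements,
        params_used={"window_size": w, "sensitivity": s, **{k: seg_cfg[k] for k in ("connectivity", "min_area", "max_area")}},
    )
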