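"""Cohort-level reporting: per-recording pipeline rows, column medians,
classifier and correlation summaries in the cohort-table layout."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    AnnotationTrack,
    CohortRecord,
    Limb,
    PressureRecording,
    resample_uniform,
)
from .io import cohort_to_frame
from .motion import run_motion_pipeline
from .position import (
    LoocvResult,
    average_active_sensors,
    classify_position_loocv,
    detect_active,
    detect_out_of_bed,
    estimate_noise,
    feature_correlations,
    window_medians,
)

__all__ = [
    "PipelineConfig",
    "CohortReport",
    "cohort_medians",
    "run_full_pipeline",
    "cohort_report",
    "report_to_json",
]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the per-recording pipeline, recorded in each report."""

    win_s: float = 10.0
    active_frac: float = 0.8
    noise_method: str = "robust_mad"
    oob_rel_threshold: float = 0.25
    percentile: float = 95.0
    head_row_end: str = "low"
    error_window_min: float = 5.0
    seed: int = 0

    def as_dict(self) -> dict[str, object]:
        return {
            "win_s": self.win_s,
            "active_frac": self.active_frac,
            "noise_method": self.noise_method,
            "oob_rel_threshold": self.oob_rel_threshold,
            "percentile": self.percentile,
            "head_row_end": self.head_row_end,
            "error_window_min": self.error_window_min,
            "seed": self.seed,
            "schema_version": SCHEMA_VERSION,
        }


@dataclass
class CohortReport:
    rows: pd.DataFrame
    medians: dict[str, float]
    classifier: LoocvResult | None = None
    correlations: dict[str, float] | None = None
    config: dict[str, object] = field(default_factory=dict)


def cohort_medians(records: Sequence[CohortRecord] | pd.DataFrame) -> dict[str, float]:
    """Sample median of every numeric cohort column (midpoint of the middle
    order statistics for even n); empty columns are reported as NaN."""
    df = records if isinstance(records, pd.DataFrame) else cohort_to_frame(list(records))
    out: dict[str, float] = {}
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]) or col == "infant_id":
            continue
        vals = df[col].dropna()
        out[col] = float(vals.median()) if len(vals) else float("nan")
    return out


def run_full_pipeline(
    rec: PressureRecording,
    annotations: AnnotationTrack,
    config: PipelineConfig | None = None,
) -> dict[str, object]:
    """All stages on one recording: resample, activity, out-of-bed, COM,
    sub-area scores, binarization and annotation errors. Deterministic given
    recording, annotations and config."""
    config = config or PipelineConfig()
    if not rec.uniform:
        rec = resample_uniform(rec)
    noise_sd = estimate_noise(rec, method=config.noise_method)
    # noiseless or fully clipped sensors estimate 0; floor keeps the activity
    # rule defined (any strictly positive pressure then counts as active)
    noise_sd = np.maximum(noise_sd, 1e-9)
    maps = window_medians(rec, win_s=config.win_s)
    activity = detect_active(
        rec, noise_sd, win_s=config.win_s, frac=config.active_frac
    )
    avg_active = average_active_sensors(activity, annotations)
    oob = detect_out_of_bed(maps, rel_threshold=config.oob_rel_threshold)
    motion = run_motion_pipeline(
        rec,
        annotations,
        win_s=config.win_s,
        percentile=config.percentile,
        head_row_end=config.head_row_end,  # type: ignore[arg-type]
    )
    errors = motion["errors_pct"]
    return {
        "avg_active_sensors": avg_active,
        "out_of_bed_intervals": oob,
        "errors_pct": errors,
        "still_windows": motion["still_windows"],
        "com_distribution": motion["com_distribution"],
        "n_windows": len(maps),
        "config": config.as_dict(),
    }


def pipeline_row(
    infant_id: int,
    ga_weeks: float,
    weight_g: float,
    position: str,
    result: dict[str, object],
) -> CohortRecord:
    """Shape one pipeline result as a cohort-table row."""
    errors = result["errors_pct"]
    return CohortRecord(
        infant_id=infant_id,
        ga_weeks=ga_weeks,
        weight_g=weight_g,
        position=position,
        avg_active_sensors=float(result["avg_active_sensors"]),
        limb_errors={limb: errors[limb.value] for limb in Limb},
        still_error=errors["still"],
    )


def cohort_report(
    records: Sequence[CohortRecord],
    classify: bool = True,
    seed: int = 0,
) -> CohortReport:
    """Medians, LOOCV classifier and feature correlations for a cohort."""
    df = cohort_to_frame(list(records))
    report = CohortReport(
        rows=df,
        medians=cohort_medians(df),
        config={"seed": seed, "schema_version": SCHEMA_VERSION},
    )
    if classify:
        report.classifier = classify_position_loocv(records, seed=seed)
        report.correlations = feature_correlations(records)
    return report


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def report_to_json(report: dict[str, object] | CohortReport, path=None) -> str:
    """Serialize a report dict (or CohortReport) to stable JSON."""
    if isinstance(report, CohortReport):
        payload = {
            "medians": report.medians,
            "config": report.config,
            "rows": report.rows.to_dict(orient="records"),
        }
        if report.classifier is not None:
            payload["classifier"] = {
                "accuracy": report.classifier.accuracy,
                "accuracy_pct": report.classifier.accuracy_pct,
                "n_correct": report.classifier.n_correct,
                "n": report.classifier.n,
                "confusion": report.classifier.confusion.tolist(),
                "params": _jsonable(report.classifier.params),
                "features": list(report.classifier.features),
            }
        if report.correlations is not None:
            payload["correlations"] = report.correlations
    else:
        payload = _jsonable(report)
    text = json.dumps(payload, indent=2, sort_keys=True, default=_jsonable)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def content_hash(report_json: str) -> str:
    """Stable hash of a serialized report, for determinism checks."""
    return hashlib.sha256(report_json.encode()).hexdigest()
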