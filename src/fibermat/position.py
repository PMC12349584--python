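"""Posture-related quantities from 10 s-window pressure distributions.

A sensor counts as *active* in a window when its reading exceeds twice its
noise standard deviation for at least 80 % of the window. The per-infant
average number of active sensors separates broad supine/prone footprints from
narrow lateral ones and, together with gestational age and weight, feeds a
small gradient-boosted-tree classifier (lateral vs. non-lateral) evaluated by
leave-one-out cross-validation. Out-of-bed intervals show up as a collapse of
the total window pressure against a running in-bed reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core import (
    EXCLUDED_CATEGORIES,
    AnnotationTrack,
    CalibrationError,
    CohortRecord,
    EmptyGridError,
    InsufficientDataError,
    PressureRecording,
)

__all__ = [
    "WindowMedianMap",
    "ActivityMap",
    "LoocvResult",
    "DEFAULT_XGB_PARAMS",
    "window_medians",
    "detect_active",
    "estimate_noise",
    "average_active_sensors",
    "detect_out_of_bed",
    "classify_position_loocv",
    "feature_correlations",
]


@dataclass
class WindowMedianMap:
    """Per-sensor median pressure over one 10 s window (NaN = excluded)."""

    window_index: int
    start_s: float
    medians: np.ndarray


@dataclass
class ActivityMap:
    """Boolean activity map for one window."""

    window_index: int
    start_s: float
    active: np.ndarray

    @property
    def n_active(self) -> int:
        return int(self.active.sum())


def _require_uniform(rec: PressureRecording) -> None:
    if not rec.uniform:
        raise InsufficientDataError(
            "recording must be resampled to a uniform rate first"
        )


def window_medians(
    rec: PressureRecording, win_s: float = 10.0
) -> list[WindowMedianMap]:
    """Per-sensor medians over non-overlapping windows (trailing partial
    window dropped)."""
    _require_uniform(rec)
    if rec.grid.n_valid == 0:
        raise EmptyGridError("all sensors are excluded")
    n_per = int(round(win_s * rec.grid.sample_rate))
    k = rec.n_frames // n_per
    if k < 1:
        raise InsufficientDataError(
            f"recording of {rec.n_frames} frames is shorter than one "
            f"{win_s} s window"
        )
    vals = rec.masked_values()[: k * n_per].reshape(
        k, n_per, rec.grid.n_rows, rec.grid.n_cols
    )
    if rec.grid.excluded:
        with warnings.catch_warnings():
            # excluded sensors are deliberately all-NaN
            warnings.simplefilter("ignore", RuntimeWarning)
            meds = np.nanmedian(vals, axis=1)
    else:
        meds = np.median(vals, axis=1)
    t0 = float(rec.timestamps[0])
    return [
        WindowMedianMap(window_index=i, start_s=t0 + i * win_s, medians=meds[i])
        for i in range(k)
    ]


def estimate_noise(
    rec: PressureRecording,
    method: str = "robust_mad",
    empty_interval: tuple[float, float] | None = None,
) -> np.ndarray:
    """Per-sensor noise standard deviation (NaN for excluded sensors).

    ``empty_segment`` takes the sample standard deviation over a declared
    empty interval (>= 10 s). ``robust_mad`` scales the median absolute
    deviation of per-sensor first differences: for white noise the first
    difference has sd ``sqrt(2) * sigma``, so
    ``sigma = 1.4826 * MAD(diff) / sqrt(2)``; differencing removes slow drift
    and the static footprint, so the estimate works on loaded recordings.
    """
    vals = rec.masked_values()
    if method == "empty_segment":
        if empty_interval is None:
            raise CalibrationError("empty_segment needs a declared empty interval")
        lo, hi = empty_interval
        if hi - lo < 10.0:
            raise InsufficientDataError("empty interval shorter than 10 s")
        m = (rec.timestamps >= lo) & (rec.timestamps < hi)
        if m.sum() < 2:
            raise InsufficientDataError("empty interval contains too few samples")
        return np.std(vals[m], axis=0, ddof=1)
    if method == "robust_mad":
        if rec.n_frames < 3:
            raise InsufficientDataError("need at least 3 frames for robust_mad")
        d = np.diff(vals, axis=0)
        mad = np.nanmedian(np.abs(d - np.nanmedian(d, axis=0)), axis=0)
        return 1.4826 * mad / np.sqrt(2.0)
    raise ValueError(f"unknown noise estimation method {method!r}")


def detect_active(
    rec: PressureRecording,
    noise_sd: float | np.ndarray,
    win_s: float = 10.0,
    frac: float = 0.8,
) -> list[ActivityMap]:
    """Activity rule: pressure above ``2 * noise_sd`` for at least ``frac`` of
    the window duration. Excluded sensors are never active."""
    _require_uniform(rec)
    mask = rec.grid.valid_mask()
    sd = np.broadcast_to(
        np.asarray(noise_sd, dtype=float), (rec.grid.n_rows, rec.grid.n_cols)
    )
    if np.any(~(sd[mask] > 0)):
        raise CalibrationError(
            "noise_sd must be positive for every valid sensor; run "
            "estimate_noise on the recording first"
        )
    n_per = int(round(win_s * rec.grid.sample_rate))
    k = rec.n_frames // n_per
    if k < 1:
        raise InsufficientDataError("recording shorter than one window")
    above = rec.values[: k * n_per] > 2.0 * sd
    counts = above.reshape(k, n_per, *above.shape[1:]).sum(axis=1)
    active = (counts >= frac * n_per) & mask
    t0 = float(rec.timestamps[0])
    return [
        ActivityMap(window_index=i, start_s=t0 + i * win_s, active=active[i])
        for i in range(k)
    ]


def average_active_sensors(
    maps: Sequence[ActivityMap],
    annotations: AnnotationTrack | None = None,
) -> float:
    """Mean active-sensor count over analyzable windows.

    Windows aligned with epochs annotated as intervention, camera movement or
    bad viewing angle are removed before averaging.
    """
    counts = []
    for i, amap in enumerate(maps):
        if annotations is not None and i < annotations.n_epochs:
            if annotations.epochs[i].category in EXCLUDED_CATEGORIES:
                continue
        counts.append(amap.n_active)
    if not counts:
        raise InsufficientDataError("no analyzable windows")
    return float(np.mean(counts))


def detect_out_of_bed(
    maps: Sequence[WindowMedianMap],
    rel_threshold: float = 0.25,
) -> list[tuple[float, float]]:
    """Out-of-bed intervals from collapsed total window pressure.

    A window is out-of-bed when its total median pressure falls below
    ``rel_threshold`` times the running in-bed reference (the median total
    pressure over the in-bed windows seen so far). Contiguous out-of-bed
    windows are merged into ``(start_s, end_s)`` intervals.
    """
    if len(maps) < 6:
        raise InsufficientDataError("need at least 6 windows")
    win_s = (
        maps[1].start_s - maps[0].start_s if len(maps) > 1 else 10.0
    )
    totals = np.array([np.nansum(m.medians) for m in maps])
    in_bed: list[float] = [totals[0]]
    flags = [False]
    for tot in totals[1:]:
        ref = float(np.median(in_bed))
        oob = tot < rel_threshold * ref
        flags.append(bool(oob))
        if not oob:
            in_bed.append(tot)
    if len(in_bed) == 1 and len(maps) > 1 and all(flags[1:]):
        warnings.warn("no in-bed reference: every later window is below "
                      "threshold relative to the first", stacklevel=2)
    intervals: list[tuple[float, float]] = []
    start = None
    for m, f in zip(maps, flags):
        if f and start is None:
            start = m.start_s
        elif not f and start is not None:
            intervals.append((start, m.start_s))
            start = None
    if start is not None:
        intervals.append((start, maps[-1].start_s + win_s))
    return intervals


# ---------------------------------------------------------------------------
# Posture classification
# ---------------------------------------------------------------------------

#: Default gradient-boosted-tree configuration for the lateral vs. non-lateral
#: posture classifier. The learning task does not determine these: they were
#: fixed once by a coarse grid search on the bundled cohort table (see the
#: methods note) and are recorded in every classifier result. With neither
#: row nor column subsampling the fit is deterministic, so the random seed
#: does not affect predictions.
DEFAULT_XGB_PARAMS: dict[str, object] = {
    "n_estimators": 100,
    "max_depth": 3,
    "learning_rate": 0.3,
    "min_child_weight": 2,
    "reg_lambda": 1.0,
    "scale_pos_weight": 9 / 8,
    "base_score": 0.3,
    "subsample": 1.0,
    "colsample_bytree": 1.0,
    "tree_method": "hist",
}

DEFAULT_FEATURES = ("avg_active_sensors", "ga_weeks", "weight_g")


@dataclass
class LoocvResult:
    """Leave-one-out cross-validation outcome.

    ``confusion[i, j]`` counts actual class ``i``, predicted class ``j`` with
    index 1 = lateral (the positive class) and 0 = non-lateral.
    """

    accuracy: float
    confusion: np.ndarray
    n: int
    n_correct: int
    params: dict[str, object]
    features: tuple[str, ...]

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * self.accuracy


def classify_position_loocv(
    cohort: Sequence[CohortRecord],
    features: Sequence[str] = DEFAULT_FEATURES,
    params: dict[str, object] | None = None,
    seed: int = 0,
) -> LoocvResult:
    """LOOCV of a gradient-boosted tree classifier, lateral vs. non-lateral.

    Each infant is held out in turn; the classifier is trained on the
    remaining ``n - 1`` with the documented default hyperparameters (or
    ``params``) and a fixed seed, and predicts the held-out posture class.
    Folds whose training set lacks a class are skipped with a warning.
    """
    from xgboost import XGBClassifier

    merged = dict(DEFAULT_XGB_PARAMS)
    if params:
        merged.update(params)
    merged.setdefault("random_state", seed)

    X = np.array(
        [[getattr(r, f) for f in features] for r in cohort], dtype=float
    )
    y = np.array([1 if r.is_lateral else 0 for r in cohort], dtype=int)
    if np.sum(y == 1) < 2 or np.sum(y == 0) < 2:
        raise InsufficientDataError("need at least 2 records per class")

    confusion = np.zeros((2, 2), dtype=int)
    n_used = 0
    n_correct = 0
    for i in range(len(y)):
        train = np.ones(len(y), dtype=bool)
        train[i] = False
        if len(np.unique(y[train])) < 2:
            warnings.warn(f"fold {i} skipped: a class is absent from training",
                          stacklevel=2)
            continue
        clf = XGBClassifier(**merged)
        clf.fit(X[train], y[train])
        pred = int(clf.predict(X[i : i + 1])[0])
        confusion[y[i], pred] += 1
        n_used += 1
        n_correct += int(pred == y[i])
    return LoocvResult(
        accuracy=n_correct / n_used,
        confusion=confusion,
        n=n_used,
        n_correct=n_correct,
        params=merged,
        features=tuple(features),
    )


def feature_correlations(cohort: Sequence[CohortRecord]) -> dict[str, float]:
    """Pearson correlation of the average active-sensor count with weight and
    with gestational age (two-sided p-values)."""
    if len(cohort) < 3:
        raise InsufficientDataError("need at least 3 records for a correlation")
    active = np.array([r.avg_active_sensors for r in cohort])
    weight = np.array([r.weight_g for r in cohort])
    ga = np.array([r.ga_weeks for r in cohort])
    rw, pw = stats.pearsonr(active, weight)
    rg, pg = stats.pearsonr(active, ga)
    return {
        "r_weight": float(rw),
        "p_weight": float(pw),
        "r_ga": float(rg),
        "p_ga": float(pg),
    }
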