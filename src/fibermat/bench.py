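"""Quantitative analysis of the five device bench tests.

Every test except precision is evaluated on a single *motion score*: the
recording is resampled to a uniform rate, each sensor is smoothed with a
centered 3 s moving median (step one sample, shrinking windows at the edges),
the valid sensors are averaged into one trace, and the trace's minimum is
subtracted as baseline correction. Precision works on the raw (interpolated
only) per-sensor signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from .core import (
    EmptyGridError,
    InsufficientDataError,
    PressureRecording,
)
from .synthetic import Segment

__all__ = [
    "MotionScore",
    "BenchReport",
    "moving_median",
    "motion_score",
    "drift_report",
    "linearity_report",
    "reproducibility_report",
    "motion_sensitivity_report",
    "precision_report",
]


@dataclass
class MotionScore:
    """Baseline-corrected average sensor trace (min exactly 0)."""

    timestamps: np.ndarray
    score: np.ndarray

    def segment(self, lo: float, hi: float) -> np.ndarray:
        m = (self.timestamps >= lo) & (self.timestamps < hi)
        return self.score[m]


@dataclass
class BenchReport:
    kind: str
    metrics: dict[str, object]
    per_sensor: dict[str, np.ndarray] = field(default_factory=dict)


def moving_median(x: np.ndarray, w: int) -> np.ndarray:
    """Centered moving median with shrinking windows at the edges.

    Sample ``i`` gets the median of ``x[i - (w-1)//2 : i + w//2 + 1]``
    clipped to the array bounds, so no data is fabricated at the boundaries.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if w < 1:
        raise ValueError("window must be >= 1")
    lo, hi = (w - 1) // 2, w // 2
    out = np.empty(n)
    if w <= n:
        out[lo : n - hi] = np.median(sliding_window_view(x, w), axis=-1)
        left_edge = range(lo)
        right_edge = range(n - hi, n)
    else:
        left_edge = range(n)
        right_edge = range(0)
    for i in left_edge:
        out[i] = np.median(x[: i + hi + 1])
    for i in right_edge:
        out[i] = np.median(x[max(i - lo, 0) :])
    return out


def motion_score(rec: PressureRecording, median_window_s: float = 3.0) -> MotionScore:
    """Derive the single motion-score trace from all valid sensors.

    Per-sensor centered moving median over a 3 s window (at 50 Hz: 150
    samples; the window scales with the recording's rate), mean across valid
    sensors, then subtraction of the global minimum.
    """
    if not rec.uniform:
        raise InsufficientDataError("resample the recording to a uniform rate first")
    if rec.grid.n_valid == 0:
        raise EmptyGridError("all sensors are excluded")
    fs = rec.grid.sample_rate
    w = max(3, int(round(median_window_s * fs)))
    if rec.n_frames < w:
        raise InsufficientDataError(
            f"recording of {rec.n_frames} samples is shorter than the "
            f"{median_window_s} s median window"
        )
    mask = rec.grid.valid_mask()
    smoothed = np.empty((rec.n_frames, int(mask.sum())))
    for k, (i, j) in enumerate(zip(*np.nonzero(mask))):
        smoothed[:, k] = moving_median(rec.values[:, i, j], w)
    score = smoothed.mean(axis=1)
    score -= score.min()
    return MotionScore(timestamps=rec.timestamps.copy(), score=score)


# ---------------------------------------------------------------------------
# Drift
# ---------------------------------------------------------------------------


def _block_medians(ms: MotionScore, block_s: float) -> np.ndarray:
    t = ms.timestamps - ms.timestamps[0]
    n_blocks = int(np.floor((t[-1] + (t[1] - t[0])) / block_s + 1e-9))
    meds = []
    for k in range(n_blocks):
        m = (t >= k * block_s) & (t < (k + 1) * block_s)
        if np.any(m):
            meds.append(np.median(ms.score[m]))
    return np.array(meds)


def drift_report(ms: MotionScore) -> BenchReport:
    """Median drift percentage per hour (and per 24 h when long enough).

    Hourly drift ``k`` is ``100 * (m_{k+1} - m_k) / m_1`` with ``m_k`` the
    median score of hour ``k``; the first hour's median is the reference
    (configurable full-scale references are deliberately not used — the score
    is already baseline-corrected). When the reference is zero the report
    falls back to absolute differences and flags it.
    """
    hourly = _block_medians(ms, 3600.0)
    if len(hourly) < 2:
        raise InsufficientDataError("drift analysis needs at least 2 full hours")
    metrics: dict[str, object] = {"hourly_medians": hourly}

    def _drift(meds: np.ndarray) -> tuple[float, bool]:
        ref = meds[0]
        deltas = np.diff(meds)
        if ref == 0:
            return float(np.median(deltas)), True
        return float(np.median(100.0 * deltas / ref)), False

    med_h, absolute = _drift(hourly)
    metrics["median_hourly_drift_pct" if not absolute else "median_hourly_drift_abs"] = med_h
    metrics["reference_zero"] = absolute
    daily = _block_medians(ms, 86400.0)
    if len(daily) >= 2:
        med_d, absolute_d = _drift(daily)
        key = "median_daily_drift_pct" if not absolute_d else "median_daily_drift_abs"
        metrics[key] = med_d
    return BenchReport(kind="drift", metrics=metrics)


# ---------------------------------------------------------------------------
# Linearity
# ---------------------------------------------------------------------------

#: Seconds discarded after each load change before estimating a plateau
#: (loads are placed by hand; settling is implied).
SETTLE_S = 10.0

#: A plateau increase below this fraction of the previous increase flags
#: saturation.
SATURATION_FRACTION = 0.05


def _plateau(values: np.ndarray, t: np.ndarray, seg: Segment) -> float:
    m = (t >= seg.start_s + SETTLE_S) & (t < seg.end_s - SETTLE_S)
    if not np.any(m):
        raise InsufficientDataError(
            f"segment {seg.start_s}-{seg.end_s} s too short for a plateau"
        )
    return float(np.median(values[m]))


def _saturated_step(levels: np.ndarray) -> int | None:
    """First step whose increase is < 5 % of the previous increase."""
    inc = np.diff(levels)
    for k in range(1, len(inc)):
        if inc[k - 1] > 0 and inc[k] < SATURATION_FRACTION * inc[k - 1]:
            return k + 1  # 1-based step index of the flat step
    return None


def linearity_report(
    ms: MotionScore,
    schedule: Sequence[Segment],
    rec: PressureRecording | None = None,
) -> BenchReport:
    """Plateau levels vs. applied mass: least-squares fit and saturation flags.

    Each step's level is the median score over the step's central portion
    (10 s discarded after each load change). Passing the raw recording adds a
    per-sensor saturation map.
    """
    t = ms.timestamps
    if schedule[0].start_s < t[0] - 1e-9 or schedule[-1].end_s > t[-1] + 1.0:
        raise InsufficientDataError("schedule extends outside the recording span")
    masses = np.array([seg.mass_kg for seg in schedule])
    levels = np.array([_plateau(ms.score, t, seg) for seg in schedule])
    fit = stats.linregress(masses, levels)
    step_heights = np.diff(levels)
    sat_step = _saturated_step(levels)
    # the output stops rising one step after the mass that hit the ceiling
    sat_mass = float(masses[sat_step - 1]) if sat_step is not None else None
    report = BenchReport(
        kind="linearity",
        metrics={
            "masses_kg": masses,
            "plateau_levels": levels,
            "step_heights": step_heights,
            "slope": float(fit.slope),
            "intercept": float(fit.intercept),
            "r_squared": float(fit.rvalue**2),
            "saturated": sat_step is not None,
            "saturated_step": sat_step,
            "saturation_mass_kg": sat_mass,
        },
    )
    if rec is not None:
        mask = rec.grid.valid_mask()
        flags = np.zeros(mask.shape, dtype=bool)
        for i, j in zip(*np.nonzero(mask)):
            sensor_levels = np.array(
                [_plateau(rec.values[:, i, j], rec.timestamps, seg) for seg in schedule]
            )
            flags[i, j] = _saturated_step(sensor_levels) is not None
        report.per_sensor["saturation"] = flags
    return report


# ---------------------------------------------------------------------------
# Reproducibility / motion sensitivity
# ---------------------------------------------------------------------------


def _placements(
    schedule: Sequence[Segment],
) -> list[tuple[Segment, list[Segment]]]:
    """Loaded segments paired with their flanking empty segments."""
    out = []
    for k, seg in enumerate(schedule):
        if seg.mass_kg <= 0:
            continue
        flank = []
        if k > 0 and schedule[k - 1].mass_kg <= 0:
            flank.append(schedule[k - 1])
        if k + 1 < len(schedule) and schedule[k + 1].mass_kg <= 0:
            flank.append(schedule[k + 1])
        out.append((seg, flank))
    return out


#: Margin trimmed from both ends of every schedule segment before extracting
#: samples: the centered 3 s median smears load transitions into neighbors.
TRANSITION_GUARD_S = 3.0


def _concat_segments(ms: MotionScore, segs: Sequence[Segment]) -> np.ndarray:
    g = TRANSITION_GUARD_S
    return np.concatenate(
        [ms.segment(s.start_s + g, s.end_s - g) for s in segs]
    )


def reproducibility_report(
    ms: MotionScore, schedule: Sequence[Segment]
) -> BenchReport:
    """Per-placement amplitude (loaded median minus flanking-empty median) and
    the coefficient of variation across placements (population sd / mean)."""
    placements = _placements(schedule)
    if len(placements) < 2:
        raise InsufficientDataError("need at least 2 placements")
    amps = []
    for seg, flank in placements:
        loaded = np.median(_concat_segments(ms, [seg]))
        empty = np.median(_concat_segments(ms, flank))
        amps.append(loaded - empty)
    amps = np.array(amps)
    mean = amps.mean()
    cv = float(np.std(amps, ddof=0) / mean) if mean != 0 else np.nan
    return BenchReport(
        kind="reproducibility",
        metrics={"amplitudes": amps, "cv": cv},
    )


def motion_sensitivity_report(
    ms: MotionScore, schedule: Sequence[Segment]
) -> BenchReport:
    """Per-cycle motion index: score variance while the load is active over
    the variance of the flanking empty segments (NaN + flag when the empty
    variance is zero)."""
    placements = _placements(schedule)
    if not placements:
        raise InsufficientDataError("schedule has no loaded segments")
    indices, flags = [], []
    for seg, flank in placements:
        v_loaded = np.var(_concat_segments(ms, [seg]))
        v_empty = np.var(_concat_segments(ms, flank))
        if v_empty < 1e-18:  # noiseless reference: index undefined
            indices.append(np.nan)
            flags.append(True)
        else:
            indices.append(v_loaded / v_empty)
            flags.append(False)
    indices = np.array(indices)
    finite = indices[np.isfinite(indices)]
    return BenchReport(
        kind="motion_sensitivity",
        metrics={
            "indices": indices,
            "min_index": float(finite.min()) if finite.size else np.nan,
            "undefined": flags,
        },
    )


# ---------------------------------------------------------------------------
# Precision
# ---------------------------------------------------------------------------


def precision_report(
    rec: PressureRecording,
    traversal: Sequence[Segment],
    off_dwell_fraction: float = 0.10,
) -> BenchReport:
    """Response and crosstalk maps from a node-by-node traversal.

    The recording must be raw (interpolated only, no smoothing). The first and
    last (empty) traversal segments provide the per-sensor baseline medians.
    ``R[target]`` is the target's dwell median minus its baseline;
    ``X[neighbor, target]`` the same quantity at each 4-neighbor. The report
    carries the full 8 x 5 response map, the worst ``|X| / R`` ratio, and the
    sensors whose best off-dwell response exceeds ``off_dwell_fraction`` of
    their on-dwell response.
    """
    g = rec.grid
    dwells = [s for s in traversal if s.mass_kg > 0]
    empties = [s for s in traversal if s.mass_kg <= 0]
    if not dwells or not empties:
        raise InsufficientDataError("traversal needs dwells and empty segments")
    for s in dwells:
        if s.end_s - s.start_s < 2.0:
            raise InsufficientDataError(
                f"dwell at {s.sensors} shorter than 2 s"
            )
    t = rec.timestamps
    empty_mask = np.zeros(rec.n_frames, dtype=bool)
    for s in empties:
        empty_mask |= (t >= s.start_s) & (t < s.end_s)
    baseline = np.median(rec.values[empty_mask], axis=0)

    response = np.full((g.n_rows, g.n_cols), np.nan)
    off_response = np.zeros((g.n_rows, g.n_cols))
    max_ratio = 0.0
    for s in dwells:
        (r, c) = s.sensors[0]
        m = (t >= s.start_s) & (t < s.end_s)
        dwell_med = np.median(rec.values[m], axis=0) - baseline
        response[r - 1, c - 1] = dwell_med[r - 1, c - 1]
        others = np.ones_like(dwell_med, dtype=bool)
        others[r - 1, c - 1] = False
        off_response[others] = np.maximum(off_response[others], dwell_med[others])
        target = dwell_med[r - 1, c - 1]
        if target > 0:
            for nr, nc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if 1 <= nr <= g.n_rows and 1 <= nc <= g.n_cols:
                    ratio = abs(dwell_med[nr - 1, nc - 1]) / target
                    max_ratio = max(max_ratio, ratio)
    with np.errstate(invalid="ignore", divide="ignore"):
        offenders_mask = off_response > off_dwell_fraction * response
    offenders = [
        (int(i + 1), int(j + 1)) for i, j in zip(*np.nonzero(offenders_mask))
    ]
    return BenchReport(
        kind="precision",
        metrics={
            "max_crosstalk_ratio": float(max_ratio),
            "offenders": offenders,
            "off_dwell_fraction": off_dwell_fraction,
        },
        per_sensor={"response": response, "off_response": off_response},
    )
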