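"""Two-dimensional limb-motion pipeline.

For each non-overlapping 10 s window the pipeline

1. locates the pressure center of mass (COM) on the grid,

   ``rowCOM = (1/P_tot) * sum_ij i * P_ij``,
   ``colCOM = (1/P_tot) * sum_ij j * P_ij``,

   from the window's per-sensor median pressures;
2. snaps the COM to the nearest sensor and lays out a 6 x 3 area around it
   (clipped to 5 x 3 at the grid edge), split into four overlapping 3 x 2
   limb sub-areas (left/right pairs share the middle column);
3. band-passes every area sensor's raw 50 Hz trace (4th-order zero-phase
   Butterworth, 0.001-0.4 Hz), takes a 1 s rolling range (max - min) and
   smooths with a 3rd-order Savitzky-Golay filter;
4. scores each limb as the fraction of the area's summed filtered-signal
   variance captured by its sub-area,

   ``score = sum_{i=1..n} var_subarea_i / sum_{j=1..m} var_area_j``,

   with ``n = 6`` sub-area sensors and ``m = 18`` (or 15 at the edge) area
   sensors;
5. binarizes each limb's score series at its 95th percentile, marks windows
   where all four limbs are below threshold as still, and compares
   detected-movement percentages against manual annotations in 5 min windows:

   ``error_avg = (1/N) * sum_i (FMm%_i - MAm%_i)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d
from scipy.signal import butter, savgol_filter, sosfiltfilt

from .core import (
    EXCLUDED_CATEGORIES,
    AnnotationTrack,
    Category,
    ConfigurationError,
    EmptyGridError,
    InsufficientDataError,
    LIMBS,
    Limb,
    PressureRecording,
    SensorGridSpec,
)
from .position import WindowMedianMap, window_medians

__all__ = [
    "ComTrack",
    "AreaLayout",
    "SubAreaScoreSeries",
    "BinaryMotionTrack",
    "compute_com",
    "snap_com",
    "com_track",
    "layout_area",
    "filter_chain",
    "window_variances",
    "score_subareas",
    "score_series",
    "binarize",
    "still_periods",
    "movement_error",
    "com_distribution",
    "run_motion_pipeline",
]

#: Motion passband of the Butterworth stage (Hz).
BAND_HZ = (0.001, 0.4)
#: Savitzky-Golay smoothing: window length (samples at 50 Hz) and poly order.
SG_WINDOW = 51
SG_ORDER = 3


@dataclass
class ComTrack:
    """Per-window COM coordinates (continuous and snapped to a sensor)."""

    rows: np.ndarray  # continuous rowCOM, in [1, n_rows]
    cols: np.ndarray  # continuous colCOM, in [1, n_cols]
    snapped: list[tuple[int, int]]
    start_s: np.ndarray

    def __len__(self) -> int:
        return len(self.snapped)


@dataclass(frozen=True)
class AreaLayout:
    """The analysis area around a snapped COM and its four limb sub-areas."""

    area: tuple[tuple[int, int], ...]
    subareas: dict[Limb, tuple[tuple[int, int], ...]]
    m: int
    edge_case: bool
    widened: bool = False  # columns widened from a grid-edge COM

    @property
    def n(self) -> int:
        return 6


@dataclass
class SubAreaScoreSeries:
    """Per-window limb scores; a window is None when the area carries no
    variance at all (marked still directly)."""

    scores: list[dict[Limb, float] | None]
    start_s: np.ndarray

    def limb_array(self, limb: Limb) -> np.ndarray:
        return np.array(
            [np.nan if s is None else s[limb] for s in self.scores], dtype=float
        )

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class BinaryMotionTrack:
    """Binarized per-window, per-limb movement decisions."""

    moving: np.ndarray  # (n_windows, 4) bool, column order = LIMBS
    thresholds: dict[Limb, float]
    start_s: np.ndarray

    def limb_column(self, limb: Limb) -> np.ndarray:
        return self.moving[:, LIMBS.index(limb)]

    def __len__(self) -> int:
        return self.moving.shape[0]


def compute_com(wmap: WindowMedianMap) -> tuple[float, float]:
    """Pressure-weighted mean of 1-based row/column indices.

    Raises ``EmptyGridError`` when the window carries no pressure at all
    (``P_tot = 0``); the track-level wrapper handles carry-forward.
    """
    med = wmap.medians
    valid = ~np.isnan(med)
    if not np.any(valid):
        raise EmptyGridError("window has no valid sensors")
    p = np.where(valid, med, 0.0)
    p_tot = p.sum()
    if p_tot <= 0:
        raise EmptyGridError("total window pressure is zero")
    n_rows, n_cols = med.shape
    rows = np.arange(1, n_rows + 1)[:, None]
    cols = np.arange(1, n_cols + 1)[None, :]
    return float((rows * p).sum() / p_tot), float((cols * p).sum() / p_tot)


def snap_com(com: tuple[float, float], grid: SensorGridSpec) -> tuple[int, int]:
    """Round the continuous COM to the nearest sensor; exact .5 ties round
    toward the grid center (and to the lower index when still tied)."""

    def _snap(x: float, n: int) -> int:
        center = (1 + n) / 2
        lo = int(np.floor(x))
        frac = x - lo
        if frac > 0.5:
            out = lo + 1
        elif frac < 0.5:
            out = lo
        else:
            out = lo + 1 if abs(lo + 1 - center) < abs(lo - center) else lo
        return min(max(out, 1), n)

    return _snap(com[0], grid.n_rows), _snap(com[1], grid.n_cols)


def com_track(
    maps: Sequence[WindowMedianMap], grid: SensorGridSpec
) -> ComTrack:
    """COM per window; zero-pressure windows carry the previous window's COM
    forward (grid center with a warning if the first window is empty)."""
    rows, cols, snapped = [], [], []
    prev: tuple[float, float] | None = None
    for wmap in maps:
        try:
            com = compute_com(wmap)
        except EmptyGridError:
            if prev is None:
                warnings.warn(
                    "first window has zero total pressure; using grid center",
                    stacklevel=2,
                )
                com = ((1 + grid.n_rows) / 2, (1 + grid.n_cols) / 2)
            else:
                com = prev
        prev = com
        rows.append(com[0])
        cols.append(com[1])
        snapped.append(snap_com(com, grid))
    return ComTrack(
        rows=np.array(rows),
        cols=np.array(cols),
        snapped=snapped,
        start_s=np.array([m.start_s for m in maps]),
    )


def layout_area(
    com_snapped: tuple[int, int],
    grid: SensorGridSpec,
    head_row_end: Literal["low", "high"] = "low",
) -> AreaLayout:
    """Lay out the 6 x 3 analysis area around a snapped COM.

    Rows span ``[com_row - 3, com_row + 2]``; columns
    ``[com_col - 1, com_col + 1]``. A box exceeding the grid is clipped (not
    shifted) and, if clipping leaves fewer than 5 rows, extended toward the
    interior so the edge-case area is always 5 x 3 (m = 15; non-edge m = 18).
    A COM on an edge column widens the columns inward to keep 3 of them.
    Sub-areas are 3 x 2: arms on the head-end row half, legs on the other,
    left/right pairs sharing the middle column; at an edge the two row halves
    share the middle row so every sub-area keeps n = 6 sensors.
    """
    if grid.n_cols < 3:
        raise ConfigurationError("area layout needs a grid of at least 3 columns")
    if grid.n_rows < 5:
        raise ConfigurationError("area layout needs a grid of at least 5 rows")
    r, c = com_snapped
    if not grid.contains((r, c)):
        raise ConfigurationError(f"snapped COM {com_snapped} outside grid")

    lo, hi = r - 3, r + 2
    lo_c, hi_c = max(lo, 1), min(hi, grid.n_rows)
    n_rows = hi_c - lo_c + 1
    if n_rows < 5:
        if lo_c == 1:
            hi_c = min(lo_c + 4, grid.n_rows)
        else:
            lo_c = max(hi_c - 4, 1)
        n_rows = hi_c - lo_c + 1
    rows = list(range(lo_c, hi_c + 1))

    widened = False
    c_lo, c_hi = c - 1, c + 1
    if c_lo < 1:
        c_lo, c_hi = 1, 3
        widened = True
    elif c_hi > grid.n_cols:
        c_lo, c_hi = grid.n_cols - 2, grid.n_cols
        widened = True
    cols = list(range(c_lo, c_hi + 1))

    area = tuple((i, j) for i in rows for j in cols)
    head_half, foot_half = rows[:3], rows[-3:]
    arms_rows, legs_rows = (
        (head_half, foot_half) if head_row_end == "low" else (foot_half, head_half)
    )
    left_cols, right_cols = cols[:2], cols[-2:]
    subareas = {
        Limb.LA: tuple((i, j) for i in arms_rows for j in left_cols),
        Limb.RA: tuple((i, j) for i in arms_rows for j in right_cols),
        Limb.LL: tuple((i, j) for i in legs_rows for j in left_cols),
        Limb.RL: tuple((i, j) for i in legs_rows for j in right_cols),
    }
    return AreaLayout(
        area=area,
        subareas=subareas,
        m=len(area),
        edge_case=len(rows) < 6,
        widened=widened,
    )


def filter_chain(
    segment: np.ndarray,
    fs: float = 50.0,
    context_before: np.ndarray | None = None,
    context_after: np.ndarray | None = None,
    sg_window: int = SG_WINDOW,
) -> np.ndarray:
    """Butterworth bandpass -> 1 s rolling range -> Savitzky-Golay smoothing.

    The bandpass (4th order, 0.001-0.4 Hz) is applied zero-phase in
    second-order-section form over segment plus any warm-up context, then
    cropped back; the very low 0.001 Hz corner at 50 Hz sampling is numerically
    unstable in transfer-function form. The rolling range and the smoothing
    stage are length-preserving (centered windows, shrinking at the edges).
    """
    segment = np.asarray(segment, dtype=float)
    parts = [segment]
    n_before = 0
    if context_before is not None and len(context_before):
        parts.insert(0, np.asarray(context_before, dtype=float))
        n_before = len(context_before)
    if context_after is not None and len(context_after):
        parts.append(np.asarray(context_after, dtype=float))
    x = np.concatenate(parts) if len(parts) > 1 else segment
    if len(segment) < sg_window:
        raise InsufficientDataError(
            f"segment of {len(segment)} samples is shorter than the "
            f"{sg_window}-sample smoothing window"
        )
    sos = butter(4, BAND_HZ, btype="bandpass", fs=fs, output="sos")
    # ~30 s reflected padding tames start/end transients of the 0.001 Hz corner
    padlen = min(len(x) - 1, int(round(30 * fs)))
    y = sosfiltfilt(sos, x, padlen=padlen)
    y = y[n_before : n_before + len(segment)]
    w = max(2, int(round(fs)))
    rng = maximum_filter1d(y, size=w, mode="nearest") - minimum_filter1d(
        y, size=w, mode="nearest"
    )
    return savgol_filter(rng, window_length=sg_window, polyorder=SG_ORDER)


def bandpass_stage(x: np.ndarray, fs: float = 50.0) -> np.ndarray:
    """First (linear) stage of the chain alone, for response checks."""
    x = np.asarray(x, dtype=float)
    sos = butter(4, BAND_HZ, btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, x, padlen=min(len(x) - 1, int(round(30 * fs))))


def window_variances(
    filtered: np.ndarray, win_samples: int
) -> np.ndarray:
    """Per-window, per-sensor variance of filtered traces.

    ``filtered`` is ``(n_samples, n_rows, n_cols)`` (NaN for excluded
    sensors); the trailing partial window is dropped.
    """
    n = filtered.shape[0]
    k = n // win_samples
    if k < 1:
        raise InsufficientDataError("recording shorter than one window")
    trimmed = filtered[: k * win_samples].reshape(
        k, win_samples, *filtered.shape[1:]
    )
    return np.var(trimmed, axis=1)


def score_subareas(
    window_var: np.ndarray, layout: AreaLayout
) -> dict[Limb, float] | None:
    """Limb scores for one window: sub-area variance sums over the area total.

    Excluded sensors (NaN variance) contribute nothing to either sum. Returns
    None when the total area variance is zero (window is still by definition).
    """

    def _sum(cells) -> float:
        vals = np.array([window_var[r - 1, c - 1] for r, c in cells])
        return float(np.nansum(vals))

    total = _sum(layout.area)
    # variances below the numerical filter-residue floor count as zero
    if total <= 1e-12:
        return None
    return {limb: _sum(cells) / total for limb, cells in layout.subareas.items()}


def score_series(
    rec: PressureRecording,
    track: ComTrack,
    win_s: float = 10.0,
    head_row_end: Literal["low", "high"] = "low",
    sg_window: int = SG_WINDOW,
) -> SubAreaScoreSeries:
    """Filter every valid sensor trace and score the four limb sub-areas in
    each window, using that window's COM-anchored area."""
    if not rec.uniform:
        raise ConfigurationError("recording must be resampled to uniform rate")
    fs = rec.grid.sample_rate
    win_samples = int(round(win_s * fs))
    vals = rec.masked_values()
    filtered = np.full_like(vals, np.nan)
    mask = rec.grid.valid_mask()
    for i, j in zip(*np.nonzero(mask)):
        filtered[:, i, j] = filter_chain(vals[:, i, j], fs=fs, sg_window=sg_window)
    wvar = window_variances(filtered, win_samples)
    scores = []
    for k in range(min(len(track), wvar.shape[0])):
        layout = layout_area(track.snapped[k], rec.grid, head_row_end=head_row_end)
        scores.append(score_subareas(wvar[k], layout))
    return SubAreaScoreSeries(scores=scores, start_s=track.start_s[: len(scores)])


def binarize(series: SubAreaScoreSeries, percentile: float = 95.0) -> BinaryMotionTrack:
    """Threshold each limb's score series at its own 95th percentile (strict
    inequality, so all-equal scores yield no movement at all)."""
    n = len(series)
    if n < 20:
        warnings.warn(
            f"only {n} windows: the {percentile}th percentile threshold is "
            "poorly determined",
            stacklevel=2,
        )
    moving = np.zeros((n, len(LIMBS)), dtype=bool)
    thresholds: dict[Limb, float] = {}
    for col, limb in enumerate(LIMBS):
        s = series.limb_array(limb)
        defined = ~np.isnan(s)
        if not np.any(defined):
            thresholds[limb] = np.nan
            continue
        thr = float(np.percentile(s[defined], percentile))
        thresholds[limb] = thr
        moving[defined, col] = s[defined] > thr
    return BinaryMotionTrack(
        moving=moving, thresholds=thresholds, start_s=series.start_s
    )


def still_periods(track: BinaryMotionTrack) -> list[int]:
    """Window indices where no limb is moving."""
    return [int(i) for i in np.nonzero(~track.moving.any(axis=1))[0]]


def _ma_moving(epoch, limb: Limb, gross_all_limbs: bool = True) -> bool:
    if epoch.category is Category.GROSS:
        return True if gross_all_limbs else limb in epoch.limbs
    if epoch.category is Category.FINE:
        return limb in epoch.limbs
    return False


def movement_error(
    track: BinaryMotionTrack,
    annotations: AnnotationTrack,
    window_min: float = 5.0,
    gross_all_limbs: bool = True,
) -> dict[str, float]:
    """Average detected-movement percentage error (device minus annotation).

    Device track and annotations are aligned on the same 10 s epoch grid.
    Epochs annotated as intervention / camera movement / bad angle (and
    out-of-bed) are excluded from both signals. For each non-overlapping
    ``window_min``-minute block, the percentage of moving epochs among valid
    epochs is computed for both signals per limb; the error is their
    difference, averaged over blocks. Still periods (all four limbs below
    threshold vs. annotated still) are scored the same way under the key
    ``"still"``. Gross-movement epochs count as movement of all four limbs by
    default; fine movement counts only flagged limbs.
    """
    n = min(len(track), annotations.n_epochs)
    if n == 0:
        raise InsufficientDataError("no aligned epochs")
    epochs = annotations.epochs[:n]
    valid = np.array(
        [
            e.category not in EXCLUDED_CATEGORIES
            and e.category is not Category.OUT_OF_BED
            for e in epochs
        ]
    )
    per_block = int(round(window_min * 60.0 / annotations.epoch_length))
    n_blocks = n // per_block
    if n_blocks == 0:
        raise InsufficientDataError(
            f"need at least one full {window_min}-minute block ({per_block} epochs)"
        )
    fm_still = ~track.moving[:n].any(axis=1)
    errors: dict[str, list[float]] = {limb.value: [] for limb in LIMBS}
    errors["still"] = []
    for b in range(n_blocks):
        sl = slice(b * per_block, (b + 1) * per_block)
        v = valid[sl]
        n_valid = int(v.sum())
        if n_valid == 0:
            continue
        for col, limb in enumerate(LIMBS):
            fm_pct = 100.0 * np.sum(track.moving[sl, col][v]) / n_valid
            ma = np.array(
                [_ma_moving(e, limb, gross_all_limbs) for e in epochs[sl]]
            )
            ma_pct = 100.0 * np.sum(ma[v]) / n_valid
            errors[limb.value].append(fm_pct - ma_pct)
        fm_still_pct = 100.0 * np.sum(fm_still[sl][v]) / n_valid
        ma_still = np.array([e.category is Category.STILL for e in epochs[sl]])
        ma_still_pct = 100.0 * np.sum(ma_still[v]) / n_valid
        errors["still"].append(fm_still_pct - ma_still_pct)
    if not errors["still"]:
        raise InsufficientDataError("no block contains a valid epoch")
    return {k: float(np.mean(v)) for k, v in errors.items()}


def com_distribution(
    track: ComTrack, grid: SensorGridSpec
) -> dict[str, object]:
    """Histogram of snapped COM positions plus an edge-coverage summary."""
    counts = np.zeros((grid.n_rows, grid.n_cols), dtype=int)
    for r, c in track.snapped:
        counts[r - 1, c - 1] += 1
    edge_rows = [1, 2, grid.n_rows - 1, grid.n_rows]
    edge_cols = [1, grid.n_cols]
    return {
        "counts": counts,
        "edge_rows_empty": bool(
            all(counts[r - 1, :].sum() == 0 for r in edge_rows)
        ),
        "edge_cols_empty": bool(
            all(counts[:, c - 1].sum() == 0 for c in edge_cols)
        ),
    }


def run_motion_pipeline(
    rec: PressureRecording,
    annotations: AnnotationTrack | None = None,
    win_s: float = 10.0,
    percentile: float = 95.0,
    head_row_end: Literal["low", "high"] = "low",
) -> dict[str, object]:
    """COM track -> sub-area scores -> binarization (-> annotation errors)."""
    maps = window_medians(rec, win_s=win_s)
    track = com_track(maps, rec.grid)
    series = score_series(rec, track, win_s=win_s, head_row_end=head_row_end)
    binary = binarize(series, percentile=percentile)
    out: dict[str, object] = {
        "com": track,
        "scores": series,
        "binary": binary,
        "still_windows": still_periods(binary),
        "com_distribution": com_distribution(track, rec.grid),
    }
    if annotations is not None:
        out["errors_pct"] = movement_error(binary, annotations)
    return out
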