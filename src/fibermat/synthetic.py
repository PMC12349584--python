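"""Synthetic sensor-grid recordings with known ground truth.

Two families of scenarios are generated:

* **Infant scenarios** — a posture-dependent pressure footprint (broad
  quasi-Gaussian blob for supine/prone, a narrow column-aligned ridge for
  side-lying), optional limb-movement bursts as slow sinusoidal pressure
  fluctuations in the 0.001-0.4 Hz motion band, white per-sensor Gaussian
  noise, slow common-mode drift, constant edge artifacts (tucked bedsheets
  loading side sensors), and out-of-bed intervals modelled as a collapse of
  the footprint to a small residual amplitude. The matching annotation track
  (10 s epochs with limb flags) is returned alongside, so every pipeline stage
  can be scored against ground truth.
* **Bench scenarios** — the five quality-assurance tests run on the physical
  device: long-term drift of the empty mat, linearity under stacked
  calibration plates, reproducibility and motion sensitivity with a small
  programmable robot, and single-node precision/crosstalk traversal.

The simulator works at the pressure-reading level; it does not model the
optics of the fiber crossings. All randomness flows from the scenario seed,
so identical scenarios produce bit-identical recordings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .core import (
    AnnotationTrack,
    Category,
    ConfigurationError,
    Epoch,
    Limb,
    Position,
    PressureRecording,
    SensorGridSpec,
)
from .motion import layout_area, snap_com

__all__ = [
    "MovementEvent",
    "InfantScenario",
    "BenchScenario",
    "DeviceModel",
    "Segment",
    "simulate_infant",
    "simulate_bench",
    "limb_regions",
    "footprint_map",
    "designed_active_count",
    "linearity_schedule",
    "precision_schedule",
    "reproducibility_schedule",
    "motion_schedule",
    "drift_schedule",
    "LINEARITY_MASSES_KG",
    "ROBOT_MASS_KG",
    "PRECISION_WEIGHT_KG",
]

#: Cumulative plate masses of the linearity test: one 2.7 kg plate followed by
#: five 1.5 kg plates.
LINEARITY_MASSES_KG = (2.7, 4.2, 5.7, 7.2, 8.7, 10.2)

#: Mass of the programmable robot used as an infant stand-in (grams -> kg).
ROBOT_MASS_KG = 0.5124

#: Calibration weight traversed node by node in the precision test.
PRECISION_WEIGHT_KG = 0.100

# Footprint peak amplitude per gram of body weight (device units / g).
_GAIN_UNITS_PER_G = 0.02

# Footprint weights below this fraction of the peak are truncated to exactly
# zero, giving the footprint compact support on the grid.
_FOOTPRINT_CUTOFF = 0.05

# Residual amplitude fraction during out-of-bed intervals (bedsheet pressure).
_OUT_OF_BED_RESIDUAL = 0.08


@dataclass(frozen=True)
class MovementEvent:
    """A limb-movement burst: a raised-cosine pressure fluctuation.

    The burst adds ``amplitude * 0.5 * (1 - cos(2 pi f (t - start)))`` to every
    sensor of the limb's ground-truth sub-area for ``t`` in
    ``[start_s, start_s + duration_s)``; it starts and ends at zero pressure
    and its fundamental frequency lies inside the 0.001-0.4 Hz motion band.
    """

    limb: Limb
    start_s: float
    duration_s: float
    amplitude: float
    freq_hz: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "limb", Limb(self.limb))
        if not 0.001 < self.freq_hz < 0.4:
            raise ConfigurationError(
                f"event frequency {self.freq_hz} Hz outside the (0.001, 0.4) "
                "motion passband"
            )
        if self.amplitude <= 0:
            raise ConfigurationError("event amplitude must be positive")
        if self.duration_s <= 0:
            raise ConfigurationError("event duration must be positive")

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass(frozen=True)
class InfantScenario:
    """Ground-truth description of a simulated infant recording."""

    position: Position = Position.SUPINE
    weight_g: float = 1500.0
    head_row_end: Literal["low", "high"] = "low"
    duration_s: float = 600.0
    movement_events: tuple[MovementEvent, ...] = ()
    noise_sd: float = 1.0
    drift: tuple[float, float] | None = None  # (amplitude, period_s)
    edge_artifact: tuple[tuple[int, ...], tuple[int, ...], float] | None = None
    # (rows, cols, amplitude): constant load on whole rows and/or columns
    out_of_bed: tuple[float, float] | None = None  # (start_s, end_s)
    seed: int = 0
    sample_rate: float = 50.0
    timestamp_jitter: float = 0.02  # sd of inter-sample jitter, fraction of dt
    grid: SensorGridSpec = field(default_factory=SensorGridSpec)

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", Position(self.position))
        object.__setattr__(
            self, "movement_events", tuple(self.movement_events)
        )
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        for ev in self.movement_events:
            if ev.start_s < 0 or ev.end_s > self.duration_s:
                raise ConfigurationError(
                    f"event on {ev.limb.value} at {ev.start_s}-{ev.end_s} s lies "
                    f"outside the {self.duration_s} s recording"
                )
        if self.out_of_bed is not None:
            s, e = self.out_of_bed
            if not 0 <= s < e <= self.duration_s:
                raise ConfigurationError("out_of_bed interval outside recording")


def _footprint_center(grid: SensorGridSpec) -> tuple[float, float]:
    return (1 + grid.n_rows) / 2, (1 + grid.n_cols) / 2


def footprint_map(sc: InfantScenario) -> np.ndarray:
    """Noiseless static footprint (device units) for a scenario.

    Supine/prone: broad 2-D quasi-Gaussian blob; lateral: narrow ridge
    elongated along one column. Weights below 5 % of the peak are truncated to
    exactly zero so the footprint has compact support. The peak amplitude and
    spatial extent both grow with body weight.
    """
    g = sc.grid
    r0, c0 = _footprint_center(g)
    rows = np.arange(1, g.n_rows + 1)[:, None]
    cols = np.arange(1, g.n_cols + 1)[None, :]
    w = sc.weight_g / 1500.0
    if sc.position is Position.LATERAL:
        sigma_r, sigma_c = 0.9 + 0.2 * w, 0.35
    else:
        sigma_r, sigma_c = 0.75 + 0.2 * w, 0.65 + 0.15 * w
    shape = np.exp(
        -((rows - r0) ** 2 / (2 * sigma_r**2) + (cols - c0) ** 2 / (2 * sigma_c**2))
    )
    shape[shape < _FOOTPRINT_CUTOFF] = 0.0
    return sc.weight_g * _GAIN_UNITS_PER_G * shape


def designed_active_count(sc: InfantScenario) -> int:
    """Number of footprint sensors exceeding the 2 x noise activity threshold
    on the noiseless footprint (the ground-truth oracle for the active-sensor
    rule)."""
    fp = footprint_map(sc)
    return int(np.sum(fp > 2 * sc.noise_sd))


def limb_regions(sc: InfantScenario) -> dict[Limb, list[tuple[int, int]]]:
    """Ground-truth sensor sets for each limb.

    The infant lies along the rows. The limb geometry reuses the analysis-side
    area convention: a 6 x 3 (edge-clipped 5 x 3) box around the designed
    footprint center, split into four 3 x 2 blocks sharing the middle column.
    With ``head_row_end='low'`` the head points toward row 1, so arms occupy
    the low-row half and legs the high-row half; ``'high'`` mirrors this.
    Grid-left (lower column indices) hosts the left limbs.
    """
    g = sc.grid
    r0, c0 = _footprint_center(g)
    snap = snap_com((r0, c0), g)
    layout = layout_area(snap, g, head_row_end=sc.head_row_end)
    return {limb: sorted(layout.subareas[limb]) for limb in Limb}


def _check_events(sc: InfantScenario) -> None:
    if sc.position is Position.LATERAL:
        bad = [ev for ev in sc.movement_events if ev.limb in (Limb.LA, Limb.RA)]
        if bad:
            raise ConfigurationError(
                "arm events are inconsistent with the lateral position: "
                "in side-lying the arms bear no load on the mat "
                f"(offending limbs: {[ev.limb.value for ev in bad]})"
            )


def _jittered_timestamps(
    rng: np.random.Generator, duration_s: float, rate: float, jitter: float
) -> np.ndarray:
    n = int(round(duration_s * rate))
    dt = 1.0 / rate
    if jitter <= 0:
        return np.arange(n) * dt
    steps = dt * (1 + jitter * rng.standard_normal(n - 1))
    steps = np.clip(steps, 0.2 * dt, 1.8 * dt)
    t = np.concatenate(([0.0], np.cumsum(steps)))
    # keep the nominal span so the epoch grid stays aligned
    t *= (n - 1) * dt / t[-1]
    return t


def _annotate(sc: InfantScenario) -> AnnotationTrack:
    n_epochs = int(sc.duration_s // 10.0)
    epochs: list[Epoch] = []
    for k in range(n_epochs):
        lo, hi = 10.0 * k, 10.0 * (k + 1)
        if sc.out_of_bed is not None:
            s, e = sc.out_of_bed
            if min(hi, e) - max(lo, s) > 0:
                epochs.append(Epoch(Category.OUT_OF_BED))
                continue
        limbs = frozenset(
            ev.limb
            for ev in sc.movement_events
            if min(hi, ev.end_s) - max(lo, ev.start_s) > 0
        )
        if not limbs:
            epochs.append(Epoch(Category.STILL))
        elif len(limbs) > 2:
            # simultaneous activity of most limbs reads as whole-body motion
            epochs.append(Epoch(Category.GROSS, limbs))
        else:
            epochs.append(Epoch(Category.FINE, limbs))
    return AnnotationTrack(epochs=epochs)


def simulate_infant(
    sc: InfantScenario,
) -> tuple[PressureRecording, AnnotationTrack]:
    """Generate a recording and its ground-truth annotation track."""
    _check_events(sc)
    rng = np.random.default_rng(sc.seed)
    g = sc.grid
    t = _jittered_timestamps(rng, sc.duration_s, sc.sample_rate, sc.timestamp_jitter)
    n = t.shape[0]

    signal = np.tile(footprint_map(sc), (n, 1, 1))

    regions = limb_regions(sc)
    for ev in sc.movement_events:
        m = (t >= ev.start_s) & (t < ev.end_s)
        burst = ev.amplitude * 0.5 * (
            1 - np.cos(2 * np.pi * ev.freq_hz * (t[m] - ev.start_s))
        )
        for r, c in regions[ev.limb]:
            signal[m, r - 1, c - 1] += burst

    if sc.out_of_bed is not None:
        s, e = sc.out_of_bed
        scale = np.ones(n)
        ramp = 1.0  # seconds taken to lift out / settle back
        scale = np.where(
            (t >= s) & (t < e), _OUT_OF_BED_RESIDUAL, scale
        )
        lift = (t >= s - ramp) & (t < s)
        scale[lift] = 1 - (1 - _OUT_OF_BED_RESIDUAL) * (t[lift] - (s - ramp)) / ramp
        settle = (t >= e) & (t < e + ramp)
        scale[settle] = _OUT_OF_BED_RESIDUAL + (1 - _OUT_OF_BED_RESIDUAL) * (
            t[settle] - e
        ) / ramp
        signal *= scale[:, None, None]

    if sc.drift is not None:
        amp, period = sc.drift
        drift = amp * 0.5 * (1 - np.cos(2 * np.pi * t / period))
        signal += drift[:, None, None]

    if sc.edge_artifact is not None:
        art_rows, art_cols, amp = sc.edge_artifact
        for r in art_rows:
            signal[:, r - 1, :] += amp
        for c in art_cols:
            signal[:, :, c - 1] += amp

    if sc.noise_sd > 0:
        signal += rng.normal(0.0, sc.noise_sd, size=signal.shape)
        np.clip(signal, 0.0, None, out=signal)

    rec = PressureRecording(
        grid=g,
        timestamps=t,
        values=signal,
        uniform=sc.timestamp_jitter <= 0,
    )
    return rec, _annotate(sc)


# ---------------------------------------------------------------------------
# Bench-test scenarios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Segment:
    """One schedule segment of a bench scenario.

    ``mass_kg`` is shared equally by ``sensors`` (``"all"`` spreads it over
    the whole grid). ``motion=(freq_hz, fraction)`` modulates each loaded
    sensor by ``1 + fraction * sin(2 pi f t + phase_i)`` with staggered phases,
    a stand-in for the robot's cyclic limb schedule. ``level_start/end`` set a
    linear common-mode output ramp (ambient-light drift of the empty mat).
    """

    start_s: float
    end_s: float
    mass_kg: float = 0.0
    sensors: Literal["all"] | tuple[tuple[int, int], ...] = "all"
    motion: tuple[float, float] | None = None
    level_start: float = 0.0
    level_end: float = 0.0

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ConfigurationError("segment must have positive duration")
        if self.sensors != "all":
            object.__setattr__(
                self, "sensors", tuple((int(r), int(c)) for r, c in self.sensors)
            )


BenchKind = Literal[
    "drift", "linearity", "reproducibility", "motion_sensitivity", "precision"
]


@dataclass(frozen=True)
class BenchScenario:
    kind: BenchKind
    schedule: tuple[Segment, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "schedule", tuple(self.schedule))
        if not self.schedule:
            raise ConfigurationError("schedule is empty")
        prev_end = None
        for seg in self.schedule:
            if prev_end is not None and not math.isclose(seg.start_s, prev_end):
                raise ConfigurationError(
                    "schedule segments must be consecutive and non-overlapping"
                )
            prev_end = seg.end_s
        _validate_kind(self.kind, self.schedule)


def _validate_kind(kind: str, schedule: tuple[Segment, ...]) -> None:
    loaded = [s for s in schedule if s.mass_kg > 0]
    if kind == "drift":
        if loaded:
            raise ConfigurationError("drift test runs on an empty mat")
    elif kind == "linearity":
        masses = [s.mass_kg for s in schedule]
        if any(np.diff(masses) < 0) or not loaded:
            raise ConfigurationError(
                "linearity schedule must apply cumulative increasing masses"
            )
    elif kind == "reproducibility":
        if len(loaded) < 1 or any(s.motion is not None for s in schedule):
            raise ConfigurationError(
                "reproducibility schedule needs static load placements"
            )
    elif kind == "motion_sensitivity":
        if not loaded or any(s.motion is None for s in loaded):
            raise ConfigurationError(
                "motion-sensitivity schedule needs moving load segments"
            )
    elif kind == "precision":
        if (
            len(schedule) < 3
            or schedule[0].mass_kg > 0
            or schedule[-1].mass_kg > 0
            or any(s.sensors == "all" or len(s.sensors) != 1 for s in loaded)
        ):
            raise ConfigurationError(
                "precision schedule is empty / single-node dwells / empty"
            )
    else:
        raise ConfigurationError(f"unknown bench kind {kind!r}")


@dataclass(frozen=True)
class DeviceModel:
    """Idealized sensor response used by the bench simulator.

    ``gain`` converts per-sensor applied mass (kg) to device units. The
    default puts the first 2.7 kg calibration plate (spread over 40 sensors)
    at about a quarter of a 1000-unit full scale, leaving headroom for the
    optional ``saturation`` ceiling. ``crosstalk`` is the fraction of each
    sensor's signal leaking to its 4-neighbors.
    """

    gain: float = 3700.0
    saturation: float | None = None
    crosstalk: float = 0.0
    noise_sd: float = 0.5
    grid: SensorGridSpec = field(default_factory=SensorGridSpec)


def simulate_bench(
    sc: BenchScenario,
    device: DeviceModel | None = None,
    sample_rate: float = 50.0,
) -> PressureRecording:
    """Simulate a bench-test recording: response proportional to applied mass
    per loaded sensor, with optional saturation ceiling and 4-neighbor
    crosstalk; deterministic given the scenario seed."""
    device = device or DeviceModel()
    g = device.grid
    rng = np.random.default_rng(sc.seed)
    t0 = sc.schedule[0].start_s
    t_end = sc.schedule[-1].end_s
    n = int(round((t_end - t0) * sample_rate))
    t = t0 + np.arange(n) / sample_rate

    load = np.zeros((n, g.n_rows, g.n_cols))
    level = np.zeros(n)
    for seg in sc.schedule:
        m = (t >= seg.start_s) & (t < seg.end_s)
        if not np.any(m):
            continue
        frac = (t[m] - seg.start_s) / (seg.end_s - seg.start_s)
        level[m] = seg.level_start + (seg.level_end - seg.level_start) * frac
        if seg.mass_kg > 0:
            if seg.sensors == "all":
                cells = [
                    (r, c)
                    for r in range(1, g.n_rows + 1)
                    for c in range(1, g.n_cols + 1)
                ]
            else:
                cells = list(seg.sensors)
            per_sensor = device.gain * seg.mass_kg / len(cells)
            for i, (r, c) in enumerate(cells):
                p = np.full(m.sum(), per_sensor)
                if seg.motion is not None:
                    freq, mfrac = seg.motion
                    # phases staggered over n+1 slots: the cyclic limb
                    # alternation never sums to zero across sensors
                    phase = 2 * np.pi * i / (len(cells) + 1)
                    p = p * (
                        1
                        + mfrac
                        * np.sin(2 * np.pi * freq * (t[m] - seg.start_s) + phase)
                    )
                load[m, r - 1, c - 1] += p

    if device.crosstalk > 0:
        leak = np.zeros_like(load)
        leak[:, 1:, :] += device.crosstalk * load[:, :-1, :]
        leak[:, :-1, :] += device.crosstalk * load[:, 1:, :]
        leak[:, :, 1:] += device.crosstalk * load[:, :, :-1]
        leak[:, :, :-1] += device.crosstalk * load[:, :, 1:]
        load = load + leak

    signal = load + level[:, None, None]
    if device.saturation is not None:
        np.clip(signal, None, device.saturation, out=signal)
    if device.noise_sd > 0:
        signal += rng.normal(0.0, device.noise_sd, size=signal.shape)
        np.clip(signal, 0.0, None, out=signal)

    grid = SensorGridSpec(
        n_rows=g.n_rows,
        n_cols=g.n_cols,
        sample_rate=sample_rate,
        excluded=g.excluded,
    )
    return PressureRecording(grid=grid, timestamps=t, values=signal, uniform=True)


# ---------------------------------------------------------------------------
# Canonical schedules for the five tests
# ---------------------------------------------------------------------------


def linearity_schedule(step_s: float = 60.0) -> tuple[Segment, ...]:
    """60 s empty baseline, then the cumulative plate steps at 60 s intervals."""
    segs = [Segment(0.0, step_s, 0.0)]
    masses = (0.0,) + LINEARITY_MASSES_KG
    for k, mass in enumerate(masses[1:], start=1):
        segs.append(Segment(k * step_s, (k + 1) * step_s, mass, "all"))
    return tuple(segs)


def _robot_cells(grid: SensorGridSpec) -> tuple[tuple[int, int], ...]:
    r = grid.n_rows // 2
    c = (grid.n_cols + 1) // 2
    return ((r, c), (r, c + 1), (r + 1, c), (r + 1, c + 1))


def reproducibility_schedule(
    cycles: int = 4,
    empty_s: float = 60.0,
    loaded_s: float = 60.0,
    grid: SensorGridSpec | None = None,
    amplitudes: Sequence[float] | None = None,
) -> tuple[Segment, ...]:
    """Alternating empty / robot-loaded segments. ``amplitudes`` optionally
    scales the robot's effective mass per placement (repositioning effects)."""
    grid = grid or SensorGridSpec()
    cells = _robot_cells(grid)
    if amplitudes is None:
        amplitudes = [1.0] * cycles
    segs = []
    t = 0.0
    for k in range(cycles):
        segs.append(Segment(t, t + empty_s, 0.0))
        t += empty_s
        segs.append(Segment(t, t + loaded_s, ROBOT_MASS_KG * amplitudes[k], cells))
        t += loaded_s
    segs.append(Segment(t, t + empty_s, 0.0))
    return tuple(segs)


def motion_schedule(
    cycles: int = 5,
    empty_s: float = 60.0,
    loaded_s: float = 60.0,
    freq_hz: float = 0.1,
    motion_frac: float = 0.5,
    grid: SensorGridSpec | None = None,
) -> tuple[Segment, ...]:
    """Alternating empty / active-robot segments (cyclic limb modulation)."""
    grid = grid or SensorGridSpec()
    cells = _robot_cells(grid)
    segs = []
    t = 0.0
    for _ in range(cycles):
        segs.append(Segment(t, t + empty_s, 0.0))
        t += empty_s
        segs.append(
            Segment(t, t + loaded_s, ROBOT_MASS_KG, cells, motion=(freq_hz, motion_frac))
        )
        t += loaded_s
    segs.append(Segment(t, t + empty_s, 0.0))
    return tuple(segs)


def precision_schedule(
    dwell_s: float = 10.0,
    empty_s: float = 60.0,
    grid: SensorGridSpec | None = None,
) -> tuple[Segment, ...]:
    """60 s empty, one dwell per node in row-major order, 60 s empty."""
    grid = grid or SensorGridSpec()
    segs = [Segment(0.0, empty_s, 0.0)]
    t = empty_s
    for r in range(1, grid.n_rows + 1):
        for c in range(1, grid.n_cols + 1):
            segs.append(Segment(t, t + dwell_s, PRECISION_WEIGHT_KG, ((r, c),)))
            t += dwell_s
    segs.append(Segment(t, t + empty_s, 0.0))
    return tuple(segs)


def drift_schedule(
    ramps: Sequence[tuple[float, float, float]],
) -> tuple[Segment, ...]:
    """Empty-mat drift schedule from ``(duration_s, level_start, level_end)``
    pieces (ambient-light level ramps)."""
    segs = []
    t = 0.0
    for dur, lo, hi in ramps:
        segs.append(Segment(t, t + dur, 0.0, level_start=lo, level_end=hi))
        t += dur
    return tuple(segs)
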