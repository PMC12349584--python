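"""Domain types for sensor-grid pressure recordings.

The device under study is a pressure-sensitive mattress built as a grid of
optical-fiber crossings: each crossing of a transmitting and a receiving fiber
is one pressure sensor. The clinical prototype uses 8 transmitting and
5 receiving fibers (40 sensors, nominally sampled at 50 Hz). Sensors are
addressed with 1-based ``(row, column)`` coordinates throughout: ``(1, 1)`` is
the first row and column, ``(8, 5)`` the last. Readings are nonnegative and in
arbitrary device units; the analysis never assumes a physical calibration.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FibermatError",
    "FormatError",
    "OrderingError",
    "AmbiguityError",
    "InsufficientDataError",
    "ConfigurationError",
    "CalibrationError",
    "EmptyGridError",
    "Limb",
    "Category",
    "Position",
    "SensorGridSpec",
    "PressureRecording",
    "Epoch",
    "AnnotationTrack",
    "CohortRecord",
    "resample_uniform",
    "apply_exclusions",
]


class FibermatError(Exception):
    """Base class for all package errors."""


class FormatError(FibermatError, ValueError):
    """A file or record does not conform to the expected layout."""


class OrderingError(FibermatError, ValueError):
    """Timestamps are not monotone nondecreasing."""


class AmbiguityError(FibermatError, ValueError):
    """Duplicate timestamps carry conflicting sensor values."""


class InsufficientDataError(FibermatError, ValueError):
    """The input is too short for the requested operation."""


class ConfigurationError(FibermatError, ValueError):
    """A scenario or schedule is internally inconsistent."""


class CalibrationError(FibermatError, ValueError):
    """A required noise/calibration reference is missing or degenerate."""


class EmptyGridError(FibermatError, ValueError):
    """No valid (non-excluded) sensors remain."""


class Limb(str, enum.Enum):
    """Limb labels: left/right leg and left/right arm."""

    LL = "LL"
    RL = "RL"
    LA = "LA"
    RA = "RA"


LIMBS: tuple[Limb, ...] = (Limb.LL, Limb.RL, Limb.LA, Limb.RA)


class Category(str, enum.Enum):
    """Annotation categories for 10 s epochs.

    ``still``, ``gross`` (torso/chest activity) and ``fine`` (isolated limb,
    head or facial movements) are the analysis categories; the remaining ones
    mark epochs that are removed before computing agreement statistics.
    """

    STILL = "still"
    GROSS = "gross"
    FINE = "fine"
    INTERVENTION = "intervention"
    CAMERA_MOVEMENT = "camera_movement"
    BAD_ANGLE = "bad_angle"
    OUT_OF_BED = "out_of_bed"


#: Categories excluded from movement-agreement analysis.
EXCLUDED_CATEGORIES = frozenset(
    {Category.INTERVENTION, Category.CAMERA_MOVEMENT, Category.BAD_ANGLE}
)


class Position(str, enum.Enum):
    SUPINE = "supine"
    PRONE = "prone"
    LATERAL = "lateral"


def _as_coord(rc: Sequence[int]) -> tuple[int, int]:
    r, c = rc
    return int(r), int(c)


@dataclass(frozen=True)
class SensorGridSpec:
    """Geometry and sampling of the sensor grid.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions (8 x 5 for the clinical prototype).
    sample_rate
        Nominal uniform sampling rate in Hz.
    excluded
        1-based ``(row, col)`` coordinates of sensors masked from analysis
        (e.g. a damaged sensor). Excluded sensors are masked, not zero-filled:
        denominators of medians, means and variances shrink accordingly.
    """

    n_rows: int = 8
    n_cols: int = 5
    sample_rate: float = 50.0
    excluded: frozenset[tuple[int, int]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ConfigurationError("grid must have at least one row and column")
        if self.sample_rate <= 0:
            raise ConfigurationError("sample_rate must be positive")
        excluded = frozenset(_as_coord(rc) for rc in self.excluded)
        object.__setattr__(self, "excluded", excluded)
        for r, c in excluded:
            if not (1 <= r <= self.n_rows and 1 <= c <= self.n_cols):
                raise ConfigurationError(
                    f"excluded sensor ({r},{c}) lies outside the "
                    f"{self.n_rows}x{self.n_cols} grid"
                )

    @property
    def n_sensors(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def n_valid(self) -> int:
        return self.n_sensors - len(self.excluded)

    def valid_mask(self) -> np.ndarray:
        """Boolean ``(n_rows, n_cols)`` mask, True where the sensor is valid."""
        mask = np.ones((self.n_rows, self.n_cols), dtype=bool)
        for r, c in self.excluded:
            mask[r - 1, c - 1] = False
        return mask

    def contains(self, rc: tuple[int, int]) -> bool:
        r, c = rc
        return 1 <= r <= self.n_rows and 1 <= c <= self.n_cols


@dataclass
class PressureRecording:
    """Time-stamped grid pressure frames.

    ``values[k, i, j]`` is the reading of sensor ``(i+1, j+1)`` at
    ``timestamps[k]`` (seconds). Readings are nonnegative device units.
    ``uniform`` is set once the recording has been resampled onto an exact
    uniform grid at ``grid.sample_rate``.
    """

    grid: SensorGridSpec
    timestamps: np.ndarray
    values: np.ndarray
    uniform: bool = False

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps.ndim != 1:
            raise FormatError("timestamps must be one-dimensional")
        if self.values.shape != (
            self.timestamps.shape[0],
            self.grid.n_rows,
            self.grid.n_cols,
        ):
            raise FormatError(
                f"values shape {self.values.shape} does not match "
                f"{self.timestamps.shape[0]} frames on a "
                f"{self.grid.n_rows}x{self.grid.n_cols} grid"
            )
        if np.any(np.diff(self.timestamps) < 0):
            raise OrderingError("timestamps are not monotone nondecreasing")
        if self.values.size and np.min(self.values) < 0:
            raise FormatError("pressure readings must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.timestamps.shape[0]

    @property
    def duration(self) -> float:
        if self.n_frames < 2:
            return 0.0
        return float(self.timestamps[-1] - self.timestamps[0])

    @property
    def rate(self) -> float:
        """Actual sampling rate inferred from the (uniform) time grid."""
        if self.n_frames < 2:
            raise InsufficientDataError("need at least 2 frames to infer a rate")
        return (self.n_frames - 1) / (self.timestamps[-1] - self.timestamps[0])

    def masked_values(self) -> np.ndarray:
        """Values with excluded sensors set to NaN (copy)."""
        out = self.values.copy()
        if self.grid.excluded:
            out[:, ~self.grid.valid_mask()] = np.nan
        return out


@dataclass(frozen=True)
class Epoch:
    """One annotated 10 s epoch."""

    category: Category
    limbs: frozenset[Limb] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "category", Category(self.category))
        object.__setattr__(self, "limbs", frozenset(Limb(l) for l in self.limbs))
        if self.category is Category.STILL and self.limbs:
            raise ConfigurationError("a still epoch cannot carry limb flags")


@dataclass
class AnnotationTrack:
    """Consecutive, non-overlapping annotation epochs on a fixed grid.

    Epoch ``k`` covers ``[k * epoch_length, (k + 1) * epoch_length)`` seconds,
    matching the 10 s windowing of the pressure pipeline.
    """

    epochs: list[Epoch]
    epoch_length: float = 10.0

    def __post_init__(self) -> None:
        if self.epoch_length <= 0:
            raise ConfigurationError("epoch_length must be positive")
        self.epochs = [
            e if isinstance(e, Epoch) else Epoch(*e) for e in self.epochs
        ]

    @property
    def n_epochs(self) -> int:
        return len(self.epochs)

    def start_times(self) -> np.ndarray:
        return np.arange(self.n_epochs) * self.epoch_length

    def categories(self) -> list[Category]:
        return [e.category for e in self.epochs]


@dataclass
class CohortRecord:
    """One infant's row of the cohort table.

    ``avg_active_sensors`` is the per-infant mean number of sensors passing
    the activity rule per 10 s window; ``limb_errors`` and ``still_error`` are
    average detected-movement percentage differences (device minus manual
    annotation) in percent.
    """

    infant_id: int
    ga_weeks: float
    weight_g: float
    position: Position
    avg_active_sensors: float
    limb_errors: dict[Limb, float] = field(default_factory=dict)
    still_error: float | None = None

    def __post_init__(self) -> None:
        self.position = Position(self.position)
        self.limb_errors = {Limb(k): float(v) for k, v in self.limb_errors.items()}
        if not 20 <= self.ga_weeks <= 44:
            raise FormatError(
                f"infant {self.infant_id}: gestational age {self.ga_weeks} weeks "
                "outside the plausible 20-44 range"
            )
        if self.weight_g <= 0:
            raise FormatError(f"infant {self.infant_id}: nonpositive weight")
        if not 0 <= self.avg_active_sensors <= 40:
            raise FormatError(
                f"infant {self.infant_id}: avg_active_sensors outside [0, 40]"
            )

    @property
    def is_lateral(self) -> bool:
        return self.position is Position.LATERAL


def resample_uniform(
    rec: PressureRecording, rate: float | None = None
) -> PressureRecording:
    """Linearly interpolate a recording onto an exact uniform time grid.

    The output grid is ``t0 + k / rate`` for ``k = 0 .. floor((tN - t0) * rate)``,
    spanning the original time range. Each sensor is interpolated
    independently (piecewise linear). Already-uniform input at the target rate
    is returned value-identical, so the operation is idempotent.
    """
    if rate is None:
        rate = rec.grid.sample_rate
    if rec.n_frames < 2:
        raise InsufficientDataError("resampling needs at least 2 timestamps")
    t = rec.timestamps
    v = rec.values
    dup = np.diff(t) == 0
    if np.any(dup):
        idx = np.nonzero(dup)[0]
        if not all(np.array_equal(v[i], v[i + 1]) for i in idx):
            raise AmbiguityError(
                "duplicate timestamps with conflicting values; cannot interpolate"
            )
        keep = np.concatenate(([True], ~dup))
        t, v = t[keep], v[keep]
    t0 = float(t[0])
    # small epsilon guards the exact-duration case against float round-off
    n_out = int(math.floor((float(t[-1]) - t0) * rate + 1e-9)) + 1
    new_t = t0 + np.arange(n_out) / rate
    flat = v.reshape(v.shape[0], -1)
    out = np.empty((n_out, flat.shape[1]))
    for j in range(flat.shape[1]):
        out[:, j] = np.interp(new_t, t, flat[:, j])
    new_grid = replace(rec.grid, sample_rate=float(rate))
    return PressureRecording(
        grid=new_grid,
        timestamps=new_t,
        values=out.reshape(n_out, rec.grid.n_rows, rec.grid.n_cols),
        uniform=True,
    )


def apply_exclusions(
    rec: PressureRecording, excluded: Iterable[tuple[int, int]]
) -> PressureRecording:
    """Mark sensors as excluded (masked) in a copy of the recording.

    Values are left untouched; downstream statistics skip masked sensors so
    that denominators count only valid sensors.
    """
    new_excluded = rec.grid.excluded | frozenset(_as_coord(rc) for rc in excluded)
    for rc in new_excluded:
        if not rec.grid.contains(rc):
            raise ConfigurationError(f"excluded sensor {rc} outside grid")
    grid = replace(rec.grid, excluded=new_excluded)
    return PressureRecording(
        grid=grid,
        timestamps=rec.timestamps.copy(),
        values=rec.values.copy(),
        uniform=rec.uniform,
    )
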