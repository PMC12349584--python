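"""Readers and writers for recordings, annotation tracks and cohort tables.

Two recording dialects are supported:

* ``csv_long`` — UTF-8 CSV with header ``time_s,row,col,pressure`` and one
  record per sensor per frame. Grid metadata travels in ``#``-prefixed header
  comments (``# n_rows=8``, ``# sample_rate=50``, ``# excluded=8,5|1,2``);
  missing metadata defaults to the 8 x 5 / 50 Hz clinical layout.
* ``hdf5`` — dataset ``/pressure`` of shape ``(frames, rows, cols)``, dataset
  ``/time_s`` with the per-frame timestamps, and root attributes
  ``sample_rate`` and ``excluded`` (list of ``"r,c"`` strings).

Annotation tracks are CSV with header ``epoch_start_s,category,limbs`` where
``limbs`` is a ``|``-separated subset of ``LL,RL,LA,RA``. The packaged cohort
table mirrors the published cohort summary column by column.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import (
    AnnotationTrack,
    Category,
    CohortRecord,
    Epoch,
    FormatError,
    Limb,
    OrderingError,
    PressureRecording,
    SensorGridSpec,
)

__all__ = [
    "read_recording",
    "write_recording",
    "read_annotations",
    "write_annotations",
    "read_cohort",
    "write_cohort",
    "load_cohort_table",
    "cohort_to_frame",
]

_COHORT_COLUMNS = [
    "infant_id",
    "ga_weeks",
    "weight_g",
    "position",
    "avg_active_sensors",
    "err_ll_pct",
    "err_rl_pct",
    "err_la_pct",
    "err_ra_pct",
    "err_still_pct",
]


def _parse_excluded(text: str) -> frozenset[tuple[int, int]]:
    text = text.strip()
    if not text:
        return frozenset()
    out = set()
    for part in text.split("|"):
        r, c = part.split(",")
        out.add((int(r), int(c)))
    return frozenset(out)


def _format_excluded(excluded) -> str:
    return "|".join(f"{r},{c}" for r, c in sorted(excluded))


def read_recording(path: str | Path, dialect: str = "csv_long") -> PressureRecording:
    """Read a pressure recording; values are preserved bit-exact."""
    path = Path(path)
    if dialect == "csv_long":
        return _read_csv_long(path)
    if dialect == "hdf5":
        return _read_hdf5(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_recording(
    rec: PressureRecording, path: str | Path, dialect: str = "csv_long"
) -> None:
    path = Path(path)
    if dialect == "csv_long":
        _write_csv_long(rec, path)
    elif dialect == "hdf5":
        _write_hdf5(rec, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _read_csv_long(path: Path) -> PressureRecording:
    meta = {"n_rows": 8, "n_cols": 5, "sample_rate": 50.0, "excluded": frozenset()}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                key = key.strip()
                if key in ("n_rows", "n_cols"):
                    meta[key] = int(val)
                elif key == "sample_rate":
                    meta[key] = float(val)
                elif key == "excluded":
                    meta[key] = _parse_excluded(val)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    expect = ["time_s", "row", "col", "pressure"]
    if list(df.columns) != expect:
        raise FormatError(f"{path}: expected columns {expect}, got {list(df.columns)}")
    grid = SensorGridSpec(
        n_rows=int(meta["n_rows"]),
        n_cols=int(meta["n_cols"]),
        sample_rate=float(meta["sample_rate"]),
        excluded=meta["excluded"],
    )
    bad = df[
        (df["row"] < 1)
        | (df["row"] > grid.n_rows)
        | (df["col"] < 1)
        | (df["col"] > grid.n_cols)
    ]
    if len(bad):
        rec0 = bad.iloc[0]
        raise FormatError(
            f"{path}: sensor ({int(rec0['row'])},{int(rec0['col'])}) at "
            f"time {rec0['time_s']} outside the {grid.n_rows}x{grid.n_cols} grid"
        )
    times = df["time_s"].to_numpy()
    frame_starts = np.nonzero(np.concatenate(([True], np.diff(times) != 0)))[0]
    t = times[frame_starts]
    if np.any(np.diff(t) < 0):
        raise OrderingError(f"{path}: frame timestamps are not monotone")
    n = len(frame_starts)
    values = np.zeros((n, grid.n_rows, grid.n_cols))
    frame_idx = np.cumsum(np.concatenate(([0], (np.diff(times) != 0).astype(int))))
    values[
        frame_idx, df["row"].to_numpy() - 1, df["col"].to_numpy() - 1
    ] = df["pressure"].to_numpy()
    return PressureRecording(grid=grid, timestamps=t, values=values)


def _write_csv_long(rec: PressureRecording, path: Path) -> None:
    g = rec.grid
    n, nr, nc = rec.n_frames, g.n_rows, g.n_cols
    df = pd.DataFrame(
        {
            "time_s": np.repeat(rec.timestamps, nr * nc),
            "row": np.tile(np.repeat(np.arange(1, nr + 1), nc), n),
            "col": np.tile(np.arange(1, nc + 1), n * nr),
            "pressure": rec.values.ravel(),
        }
    )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# n_rows={g.n_rows}\n# n_cols={g.n_cols}\n")
        fh.write(f"# sample_rate={float(g.sample_rate)!r}\n")
        if g.excluded:
            fh.write(f"# excluded={_format_excluded(g.excluded)}\n")
        # str() of a float is its shortest round-trippable representation
        df.to_csv(fh, index=False)


def _read_hdf5(path: Path) -> PressureRecording:
    with h5py.File(path, "r") as f:
        if "pressure" not in f:
            raise FormatError(f"{path}: missing /pressure dataset")
        values = f["pressure"][()]
        t = f["time_s"][()]
        sample_rate = float(f.attrs.get("sample_rate", 50.0))
        raw_excl = f.attrs.get("excluded", [])
        excluded = frozenset(
            tuple(int(x) for x in str(s).split(",")) for s in raw_excl
        )
        uniform = bool(f.attrs.get("uniform", False))
    if values.ndim != 3:
        raise FormatError(f"{path}: /pressure must be (frames, rows, cols)")
    grid = SensorGridSpec(
        n_rows=values.shape[1],
        n_cols=values.shape[2],
        sample_rate=sample_rate,
        excluded=excluded,
    )
    return PressureRecording(grid=grid, timestamps=t, values=values, uniform=uniform)


def _write_hdf5(rec: PressureRecording, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("pressure", data=rec.values)
        f.create_dataset("time_s", data=rec.timestamps)
        f.attrs["sample_rate"] = rec.grid.sample_rate
        f.attrs["excluded"] = [f"{r},{c}" for r, c in sorted(rec.grid.excluded)]
        f.attrs["uniform"] = rec.uniform


def read_annotations(path: str | Path, epoch_length: float = 10.0) -> AnnotationTrack:
    df = pd.read_csv(path, keep_default_na=False)
    expect = ["epoch_start_s", "category", "limbs"]
    if list(df.columns) != expect:
        raise FormatError(f"{path}: expected columns {expect}, got {list(df.columns)}")
    starts = df["epoch_start_s"].to_numpy(dtype=float)
    expected = np.arange(len(df)) * epoch_length
    if not np.allclose(starts, expected):
        raise FormatError(
            f"{path}: epochs must be consecutive multiples of {epoch_length} s"
        )
    epochs = []
    for _, row in df.iterrows():
        limbs = frozenset(
            Limb(tok) for tok in str(row["limbs"]).split("|") if tok
        )
        epochs.append(Epoch(category=Category(row["category"]), limbs=limbs))
    return AnnotationTrack(epochs=epochs, epoch_length=epoch_length)


def write_annotations(track: AnnotationTrack, path: str | Path) -> None:
    rows = []
    for k, e in enumerate(track.epochs):
        rows.append(
            {
                "epoch_start_s": k * track.epoch_length,
                "category": e.category.value,
                "limbs": "|".join(sorted(l.value for l in e.limbs)),
            }
        )
    pd.DataFrame(rows, columns=["epoch_start_s", "category", "limbs"]).to_csv(
        path, index=False
    )


def _records_from_frame(df: pd.DataFrame) -> list[CohortRecord]:
    missing = [c for c in _COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"cohort table missing columns {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(
            CohortRecord(
                infant_id=int(row["infant_id"]),
                ga_weeks=float(row["ga_weeks"]),
                weight_g=float(row["weight_g"]),
                position=str(row["position"]).lower(),
                avg_active_sensors=float(row["avg_active_sensors"]),
                limb_errors={
                    Limb.LL: float(row["err_ll_pct"]),
                    Limb.RL: float(row["err_rl_pct"]),
                    Limb.LA: float(row["err_la_pct"]),
                    Limb.RA: float(row["err_ra_pct"]),
                },
                still_error=float(row["err_still_pct"]),
            )
        )
    return records


def read_cohort(path: str | Path) -> list[CohortRecord]:
    return _records_from_frame(pd.read_csv(path))


def write_cohort(records: list[CohortRecord], path: str | Path) -> None:
    cohort_to_frame(records).to_csv(path, index=False)


def cohort_to_frame(records: list[CohortRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "infant_id": r.infant_id,
                "ga_weeks": r.ga_weeks,
                "weight_g": r.weight_g,
                "position": r.position.value,
                "avg_active_sensors": r.avg_active_sensors,
                "err_ll_pct": r.limb_errors.get(Limb.LL),
                "err_rl_pct": r.limb_errors.get(Limb.RL),
                "err_la_pct": r.limb_errors.get(Limb.LA),
                "err_ra_pct": r.limb_errors.get(Limb.RA),
                "err_still_pct": r.still_error,
            }
        )
    return pd.DataFrame(rows, columns=_COHORT_COLUMNS)


def load_cohort_table() -> list[CohortRecord]:
    """Load the packaged 17-infant cohort table (annotated infants only)."""
    ref = importlib.resources.files("fibermat.data").joinpath("cohort_table.csv")
    with importlib.resources.as_file(ref) as p:
        return read_cohort(p)
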