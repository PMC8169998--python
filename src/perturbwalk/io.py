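"""Session containers and CSV ingest/export.

A trial is held as a :class:`MarkerSession`: the six landmark trajectories
(C7, sacrum, left/right trochanter, left/right hallux) on a common 100 Hz
time grid, plus the left/right belt-speed commands sampled at the force-plate
rate (1000 Hz by default).  Belt speeds live on the force grid because
perturbation ramps contain kinks at arbitrary instants that a 100 Hz grid
would misplace.

Lab frame: right-handed, +x = walking direction (anterior), +y = left,
+z = up, fixed to the treadmill.

On-disk layout (one directory per trial):

    markers.csv   time,C7_x,C7_y,C7_z,SACR_x,...   (100 Hz)
    forces.csv    time,fz_left,fz_right,belt_left,belt_right  (1000 Hz)
    truth.json    optional synthetic ground truth sidecar
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_MARKERS",
    "MarkerSession",
    "ForceRecord",
    "ParticipantRecord",
    "read_session",
    "write_session",
    "read_forces",
    "write_forces",
    "assign_groups",
]

REQUIRED_MARKERS = ("C7", "SACR", "LTRO", "RTRO", "LHLX", "RHLX")
_AXES = ("x", "y", "z")


@dataclass
class MarkerSession:
    """Time-indexed marker trajectories and belt-speed commands for one trial."""

    time: np.ndarray  # seconds, marker grid
    markers: dict  # label -> (n, 3) array, metres, lab frame
    belt_speed_left: np.ndarray  # m/s on the force grid
    belt_speed_right: np.ndarray
    sampling_rate_markers: float = 100.0
    sampling_rate_forces: float = 1000.0
    trial_label: str = ""

    def __post_init__(self) -> None:
        n = len(self.time)
        for label, arr in self.markers.items():
            if arr.shape != (n, 3):
                raise ValueError(
                    f"marker {label} has shape {arr.shape}, expected ({n}, 3)"
                )
        missing = [m for m in REQUIRED_MARKERS if m not in self.markers]
        if missing:
            raise ValueError(f"missing required markers: {', '.join(missing)}")

    @property
    def n_frames(self) -> int:
        return len(self.time)

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0]) + 1.0 / self.sampling_rate_markers

    @property
    def belt_time(self) -> np.ndarray:
        return self.time[0] + np.arange(len(self.belt_speed_left)) / self.sampling_rate_forces

    def belt_at(self, t, side: str) -> np.ndarray:
        """Belt speed of one side ('L'/'R') linearly interpolated at time(s) t."""
        series = self.belt_speed_left if side == "L" else self.belt_speed_right
        return np.interp(t, self.belt_time, series)

    def copy(self) -> "MarkerSession":
        return replace(
            self,
            time=self.time.copy(),
            markers={k: v.copy() for k, v in self.markers.items()},
            belt_speed_left=self.belt_speed_left.copy(),
            belt_speed_right=self.belt_speed_right.copy(),
        )


@dataclass
class ForceRecord:
    """Dual-belt vertical ground-reaction forces (N) on the 1000 Hz grid."""

    time: np.ndarray
    left: np.ndarray
    right: np.ndarray
    rate: float = 1000.0

    def as_dict(self) -> dict:
        return {"L": self.left, "R": self.right}


@dataclass(frozen=True)
class ParticipantRecord:
    """Demographics plus retrospective (12-month) falls count.

    A participant belongs to the Falls group iff they reported at least one
    fall in the past year.
    """

    id: str
    sex: str = ""
    age: float = float("nan")
    height: float = float("nan")  # cm
    weight: float = float("nan")  # kg
    falls_last_year: int = 0

    def __post_init__(self) -> None:
        if self.falls_last_year < 0:
            raise ValueError(
                f"falls_last_year must be >= 0, got {self.falls_last_year}"
            )

    @property
    def group(self) -> str:
        return "Falls" if self.falls_last_year >= 1 else "NoFalls"


def assign_groups(records) -> tuple[list, list]:
    """Partition participants into (Falls, NoFalls) by 12-month falls history."""
    records = list(records)
    for r in records:
        if r.falls_last_year < 0:
            raise ValueError(f"negative falls count for participant {r.id}")
    falls = [r for r in records if r.falls_last_year >= 1]
    nofalls = [r for r in records if r.falls_last_year == 0]
    return falls, nofalls


# ---------------------------------------------------------------------------
# CSV ingest


def _interpolate_gaps(values: np.ndarray, max_gap: int, column: str) -> np.ndarray:
    """Linearly fill NaN runs of at most ``max_gap`` samples; longer runs error."""
    isnan = np.isnan(values)
    if not isnan.any():
        return values
    if isnan[0] or isnan[-1]:
        raise ValueError(f"column {column}: gap at series edge cannot be interpolated")
    idx = np.flatnonzero(np.diff(isnan.astype(int)))
    starts = idx[::2] + 1
    ends = idx[1::2] + 1  # exclusive
    lengths = ends - starts
    if (lengths > max_gap).any():
        worst = int(lengths.max())
        raise ValueError(
            f"column {column}: marker gap of {worst} frames exceeds the "
            f"{max_gap}-frame interpolation limit"
        )
    good = ~isnan
    out = values.copy()
    out[isnan] = np.interp(
        np.flatnonzero(isnan), np.flatnonzero(good), values[good]
    )
    return out


def read_session(
    path,
    fmt: str = "csv",
    alias_map: Mapping[str, str] | None = None,
    max_gap_frames: int = 10,
) -> MarkerSession:
    """Read a trial from ``path`` (a trial directory or a markers CSV file).

    Marker gaps (NaNs) of at most ``max_gap_frames`` are linearly
    interpolated; longer gaps raise.  ``alias_map`` maps file column prefixes
    to the canonical labels (e.g. ``{"SACRUM": "SACR"}``).
    """
    if fmt != "csv":
        raise ValueError(f"unsupported session format: {fmt!r} (CSV only)")
    path = Path(path)
    markers_path = path / "markers.csv" if path.is_dir() else path
    if not markers_path.exists():
        raise FileNotFoundError(markers_path)
    df = pd.read_csv(markers_path)
    if "time" not in df.columns:
        raise ValueError("markers CSV must contain a 'time' column")
    if alias_map:
        renames = {}
        for col in df.columns:
            for src, dst in alias_map.items():
                if col.startswith(src + "_"):
                    renames[col] = dst + col[len(src):]
        df = df.rename(columns=renames)

    time = df["time"].to_numpy(dtype=float)
    if len(time) < 2:
        raise ValueError("markers CSV must contain at least 2 frames")
    dts = np.diff(time)
    if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
        raise ValueError("irregular marker time base")
    rate = 1.0 / dts[0]

    missing = [
        m
        for m in REQUIRED_MARKERS
        if not all(f"{m}_{ax}" in df.columns for ax in _AXES)
    ]
    if missing:
        raise ValueError(f"missing required markers: {', '.join(missing)}")

    markers = {}
    for m in REQUIRED_MARKERS:
        cols = []
        for ax in _AXES:
            col = f"{m}_{ax}"
            cols.append(
                _interpolate_gaps(df[col].to_numpy(dtype=float), max_gap_frames, col)
            )
        markers[m] = np.column_stack(cols)

    belt_l = belt_r = None
    force_rate = 1000.0
    forces_path = path / "forces.csv" if path.is_dir() else None
    if forces_path is not None and forces_path.exists():
        rec = read_forces(forces_path)
        force_rate = rec.rate
        fdf = pd.read_csv(forces_path)
        if "belt_left" in fdf.columns:
            belt_l = fdf["belt_left"].to_numpy(dtype=float)
            belt_r = fdf["belt_right"].to_numpy(dtype=float)
    if belt_l is None:
        # fall back to belt columns on the marker grid, else zeros
        if "belt_left" in df.columns:
            belt_l = df["belt_left"].to_numpy(dtype=float)
            belt_r = df["belt_right"].to_numpy(dtype=float)
            force_rate = rate
        else:
            belt_l = np.zeros(len(time))
            belt_r = np.zeros(len(time))
            force_rate = rate

    return MarkerSession(
        time=time,
        markers=markers,
        belt_speed_left=belt_l,
        belt_speed_right=belt_r,
        sampling_rate_markers=rate,
        sampling_rate_forces=force_rate,
        trial_label=str(path.name),
    )


def write_session(
    session: MarkerSession,
    path,
    forces: ForceRecord | None = None,
    truth: dict | None = None,
) -> Path:
    """Write a trial directory (markers.csv, optional forces.csv / truth.json)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    data = {"time": session.time}
    for m in REQUIRED_MARKERS:
        for j, ax in enumerate(_AXES):
            data[f"{m}_{ax}"] = session.markers[m][:, j]
    pd.DataFrame(data).to_csv(path / "markers.csv", index=False, float_format="%.6f")
    if forces is not None:
        write_forces(forces, path / "forces.csv", session)
    if truth is not None:
        with open(path / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1)
    return path


def read_forces(path) -> ForceRecord:
    df = pd.read_csv(path)
    time = df["time"].to_numpy(dtype=float)
    rate = 1.0 / float(np.median(np.diff(time))) if len(time) > 1 else 1000.0
    return ForceRecord(
        time=time,
        left=df["fz_left"].to_numpy(dtype=float),
        right=df["fz_right"].to_numpy(dtype=float),
        rate=round(rate, 6),
    )


def write_forces(forces: ForceRecord, path, session: MarkerSession | None = None) -> None:
    data = {
        "time": forces.time,
        "fz_left": forces.left,
        "fz_right": forces.right,
    }
    if session is not None and len(session.belt_speed_left) == len(forces.time):
        data["belt_left"] = session.belt_speed_left
        data["belt_right"] = session.belt_speed_right
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.4f")
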