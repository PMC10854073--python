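"""Telemetry track I/O and step geometry.

A track is a time-ordered sequence of fixes (timestamp + projected x/y in
meters) for a single animal.  Steps are the displacement between successive
fixes; everything downstream (motility estimation, availability sampling,
conditional-likelihood fitting) operates on steps.  Time is kept internally
in hours so that sampling intervals match how telemetry schedules are
usually reported; irregular intervals are represented simply as larger
Δt — no imputation or interpolation is done.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

TWO_PI = 2.0 * np.pi

DEFAULT_COLUMNS = {"id": "id", "timestamp": "timestamp", "x": "x", "y": "y"}


class TrackValidationError(ValueError):
    """Raised when a track violates a structural invariant."""


@dataclass
class Track:
    """Time-stamped positions of one animal.

    Attributes
    ----------
    animal_id : str
        Identifier of the animal.
    times : ndarray, shape (n,)
        Fix times in hours (strictly increasing).
    positions : ndarray, shape (n, 2)
        Fix coordinates in meters, projected CRS.
    """

    animal_id: str
    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise TrackValidationError("positions must be an (n, 2) array")
        if len(self.times) != len(self.positions):
            raise TrackValidationError("times and positions must have equal length")
        if not np.all(np.isfinite(self.times)) or not np.all(np.isfinite(self.positions)):
            raise TrackValidationError("times and positions must be finite")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            bad = int(np.argmax(dt <= 0)) + 1
            raise TrackValidationError(
                f"times must be strictly increasing; violation at fix index {bad}"
            )

    def __len__(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> np.ndarray:
        """Sampling intervals Δt_i in hours, one per step."""
        return np.diff(self.times)


@dataclass
class StepSeries:
    """Per-step geometry derived from a track.

    Step i joins fix i-1 to fix i.  Bearings are absolute directions in
    [0, 2π); turning angles are successive bearing differences wrapped to
    [0, 2π), NaN where undefined (first step, or a zero-length neighbour).
    """

    animal_id: str
    t0: np.ndarray
    t1: np.ndarray
    dt: np.ndarray
    origin: np.ndarray       # (n, 2) step start
    endpoint: np.ndarray     # (n, 2) step end
    length: np.ndarray
    bearing: np.ndarray      # NaN when length == 0
    turn: np.ndarray         # NaN when undefined

    def __len__(self) -> int:
        return len(self.length)

    @property
    def midpoint_time(self) -> np.ndarray:
        return 0.5 * (self.t0 + self.t1)

    def subset(self, index: np.ndarray) -> "StepSeries":
        """Select steps by boolean mask or integer index (turns recomputed not)."""
        return StepSeries(
            animal_id=self.animal_id,
            t0=self.t0[index],
            t1=self.t1[index],
            dt=self.dt[index],
            origin=self.origin[index],
            endpoint=self.endpoint[index],
            length=self.length[index],
            bearing=self.bearing[index],
            turn=self.turn[index],
        )


def _looks_geographic(x: np.ndarray, y: np.ndarray) -> bool:
    return bool(np.all(np.abs(x) <= 360.0) and np.all(np.abs(y) <= 90.0))


def _times_to_hours(raw: pd.Series) -> np.ndarray:
    """Parse a timestamp column to hours.

    Numeric values are taken as hours directly; strings are parsed as
    ISO-8601 and converted to hours since the Unix epoch.
    """
    if pd.api.types.is_numeric_dtype(raw):
        return raw.to_numpy(dtype=float)
    try:
        parsed = pd.to_datetime(raw, utc=True, format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise TrackValidationError(f"unparseable timestamp column: {exc}") from exc
    return parsed.astype("int64").to_numpy() / 3.6e12  # ns -> hours


def read_track(
    path,
    column_map: dict | None = None,
    animal_id: str | None = None,
    allow_geographic: bool = False,
) -> Track:
    """Read one animal's telemetry from CSV.

    Parameters
    ----------
    path : path-like
        CSV with id, timestamp, x, y columns (names remappable via
        ``column_map``).  Timestamps are ISO-8601 strings or numeric hours.
    column_map : dict, optional
        Mapping from canonical names (``id``, ``timestamp``, ``x``, ``y``)
        to the file's column names.
    animal_id : str, optional
        Select one animal if the file contains several; required in that
        case, otherwise inferred.
    allow_geographic : bool
        Coordinates that look like lon/lat degrees are rejected unless this
        is set; the library works in projected meters only.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, float_precision="round_trip")
    for key in ("id", "timestamp", "x", "y"):
        if cols[key] not in df.columns:
            raise TrackValidationError(f"missing column {cols[key]!r} in {path}")
    ids = df[cols["id"]].astype(str)
    if animal_id is None:
        unique = ids.unique()
        if len(unique) > 1:
            raise TrackValidationError(
                f"file contains {len(unique)} animals; pass animal_id"
            )
        animal_id = str(unique[0])
    else:
        df = df[ids == str(animal_id)]
        if df.empty:
            raise TrackValidationError(f"animal_id {animal_id!r} not found")

    times = _times_to_hours(df[cols["timestamp"]])
    x = df[cols["x"]].to_numpy(dtype=float)
    y = df[cols["y"]].to_numpy(dtype=float)
    if not allow_geographic and _looks_geographic(x, y):
        raise TrackValidationError(
            "coordinates look like lon/lat degrees; project to a metric CRS "
            "first, or pass allow_geographic=True to override"
        )
    order = np.argsort(times, kind="stable")
    times, x, y = times[order], x[order], y[order]
    dup = np.flatnonzero(np.diff(times) == 0)
    if dup.size:
        raise TrackValidationError(
            f"duplicate timestamp at sorted row {int(dup[0]) + 1}"
        )
    return Track(animal_id=animal_id, times=times, positions=np.column_stack([x, y]))


def write_track(track: Track, path) -> None:
    """Write a track as CSV (numeric hour timestamps, full precision)."""
    df = pd.DataFrame(
        {
            "id": track.animal_id,
            "timestamp": track.times,
            "x": track.positions[:, 0],
            "y": track.positions[:, 1],
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def derive_steps(track: Track) -> StepSeries:
    """Derive step lengths, bearings and turning angles from a track.

    Bearings come from atan2 of the displacement, wrapped to [0, 2π).  The
    turning angle of step i is bearing_i − bearing_{i−1} wrapped to
    [0, 2π); it is NaN for the first step and wherever either bearing is
    undefined (zero-length step).
    """
    if len(track) < 2:
        raise TrackValidationError("need at least 2 fixes to derive steps")
    disp = np.diff(track.positions, axis=0)
    length = np.hypot(disp[:, 0], disp[:, 1])
    bearing = np.mod(np.arctan2(disp[:, 1], disp[:, 0]), TWO_PI)
    bearing = np.where(length > 0, bearing, np.nan)
    turn = np.full_like(length, np.nan)
    if len(length) > 1:
        turn[1:] = np.mod(bearing[1:] - bearing[:-1], TWO_PI)
    return StepSeries(
        animal_id=track.animal_id,
        t0=track.times[:-1],
        t1=track.times[1:],
        dt=np.diff(track.times),
        origin=track.positions[:-1].copy(),
        endpoint=track.positions[1:].copy(),
        length=length,
        bearing=bearing,
        turn=turn,
    )


def steps_to_frame(steps: StepSeries) -> pd.DataFrame:
    """Step table in the export layout."""
    return pd.DataFrame(
        {
            "step_id": np.arange(len(steps)),
            "t0": steps.t0,
            "t1": steps.t1,
            "dt_h": steps.dt,
            "x0": steps.origin[:, 0],
            "y0": steps.origin[:, 1],
            "x1": steps.endpoint[:, 0],
            "y1": steps.endpoint[:, 1],
            "length_m": steps.length,
            "bearing_rad": steps.bearing,
            "turn_rad": steps.turn,
        }
    )


def write_steps(steps: StepSeries, path) -> None:
    steps_to_frame(steps).to_csv(path, index=False, float_format="%.17g")
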