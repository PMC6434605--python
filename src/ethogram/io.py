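"""Domain containers and biologger CSV input/output.

The two raw-data containers are :class:`AccelTrace` (tri-axial
acceleration at the accelerometer rate, with optional depth and
temperature channels carried on the same time base) and
:class:`GpsTrack` (planar nest-centered fixes in meters, or lon/lat
degrees for real exports).  Files are plain comma-separated CSV with a
header row and time expressed as seconds since the start of the
deployment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .config import SpeciesConfig

__all__ = [
    "AccelTrace", "GpsTrack", "FormatError", "DataError",
    "read_accel_csv", "write_accel_csv", "read_gps_csv", "write_gps_csv",
    "subsample", "ground_speed",
]


class FormatError(ValueError):
    """A file does not conform to the expected CSV dialect."""


class DataError(ValueError):
    """File contents violate a data invariant (e.g. non-monotone time)."""


@dataclass
class AccelTrace:
    """Raw tri-axial acceleration for one deployment.

    ``t`` is seconds since deployment start on a nominally regular grid;
    ``X`` (surge), ``Y`` (sway) and ``Z`` (heave) are in units of g.
    ``depth`` is meters, negative below the sea surface; step-filled to
    the accelerometer grid when it was logged at 1 Hz.
    """

    bird_id: str
    t: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    Z: np.ndarray
    depth: Optional[np.ndarray] = None
    temperature: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for ax in ("X", "Y", "Z"):
            arr = np.asarray(getattr(self, ax), dtype=float)
            if arr.shape != self.t.shape:
                raise DataError(f"axis {ax} length does not match time base")
            if not np.all(np.isfinite(arr)):
                raise DataError(f"axis {ax} contains non-finite values")
            setattr(self, ax, arr)
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise DataError("time base is not strictly increasing")
        for name in ("depth", "temperature"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != self.t.shape:
                    raise DataError(f"{name} length does not match time base")
                setattr(self, name, arr)

    def __len__(self) -> int:
        return self.t.size

    @property
    def sampling_rate(self) -> float:
        """Median sampling rate in Hz."""
        if self.t.size < 2:
            return float("nan")
        return 1.0 / float(np.median(np.diff(self.t)))

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.t.size else 0.0

    def to_frame(self) -> pd.DataFrame:
        cols = {"time": self.t, "X": self.X, "Y": self.Y, "Z": self.Z}
        if self.depth is not None:
            cols["depth"] = self.depth
        if self.temperature is not None:
            cols["temperature"] = self.temperature
        return pd.DataFrame(cols)


@dataclass
class GpsTrack:
    """GPS fixes for one deployment.

    ``x``/``y`` are planar meters in a nest-centered frame for synthetic
    tracks, or lon/lat degrees for real data (``lonlat=True``).
    """

    bird_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    fix_interval: float
    lonlat: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.t.shape or self.y.shape != self.t.shape:
            raise DataError("coordinate arrays must match time base")
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise DataError("GPS time base is not strictly increasing")

    def __len__(self) -> int:
        return self.t.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.t, "x": self.x, "y": self.y})


def _step_fill(values: np.ndarray) -> np.ndarray:
    """Forward-fill NaN runs with the previous value (step interpolation)."""
    ser = pd.Series(values)
    return ser.ffill().bfill().to_numpy()


def read_accel_csv(path, config: Optional[SpeciesConfig] = None,
                   bird_id: Optional[str] = None) -> AccelTrace:
    """Read a per-bird accelerometer CSV.

    Required columns: ``time, X, Y, Z``; optional ``depth`` and
    ``temperature``.  Channels logged at 1 Hz may be left blank between
    samples; they are carried forward to the accelerometer grid by
    previous-value (step) fill so that dive onsets are not smeared.
    """
    df = pd.read_csv(path)
    required = {"time", "X", "Y", "Z"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"missing required column(s): {sorted(missing)}")
    t = df["time"].to_numpy(dtype=float)
    if t.size >= 2 and not np.all(np.diff(t) > 0):
        raise DataError("time column is not strictly increasing")
    kwargs = {}
    for name in ("depth", "temperature"):
        if name in df.columns:
            kwargs[name] = _step_fill(df[name].to_numpy(dtype=float))
    if bird_id is None:
        bird_id = str(getattr(path, "stem", path))
    return AccelTrace(bird_id=bird_id, t=t,
                      X=df["X"].to_numpy(dtype=float),
                      Y=df["Y"].to_numpy(dtype=float),
                      Z=df["Z"].to_numpy(dtype=float), **kwargs)


def write_accel_csv(trace: AccelTrace, path, float_format: str = "%.6g") -> None:
    trace.to_frame().to_csv(path, index=False, float_format=float_format)


def read_gps_csv(path, fix_interval: float, bird_id: Optional[str] = None,
                 lonlat: bool = False) -> GpsTrack:
    df = pd.read_csv(path)
    missing = {"time", "x", "y"} - set(df.columns)
    if missing:
        raise FormatError(f"missing required column(s): {sorted(missing)}")
    if bird_id is None:
        bird_id = str(getattr(path, "stem", path))
    return GpsTrack(bird_id=bird_id, t=df["time"].to_numpy(dtype=float),
                    x=df["x"].to_numpy(dtype=float),
                    y=df["y"].to_numpy(dtype=float),
                    fix_interval=fix_interval, lonlat=lonlat)


def write_gps_csv(track: GpsTrack, path, float_format: str = "%.6g") -> None:
    track.to_frame().to_csv(path, index=False, float_format=float_format)


def subsample(obj, interval: float):
    """Keep the record nearest each grid point ``t = 0, interval, 2*interval...``

    Works on an :class:`AccelTrace` or on any DataFrame with a ``t`` (or
    ``time``) column; returns the same type.  Output length is
    ``floor(duration / interval) + 1``.
    """
    if isinstance(obj, AccelTrace):
        t = obj.t
    elif isinstance(obj, pd.DataFrame):
        col = "t" if "t" in obj.columns else "time"
        t = obj[col].to_numpy(dtype=float)
    else:
        raise TypeError(f"cannot subsample {type(obj).__name__}")
    if t.size < 2:
        return obj
    native = float(np.median(np.diff(t)))
    if interval < native - 1e-9:
        raise ValueError(
            f"subsample interval {interval} s is finer than the native "
            f"step {native} s")
    t0 = t[0]
    duration = t[-1] - t0
    grid = t0 + interval * np.arange(int(np.floor(duration / interval)) + 1)
    idx = np.searchsorted(t, grid)
    idx = np.clip(idx, 0, t.size - 1)
    left = np.clip(idx - 1, 0, t.size - 1)
    idx = np.where(np.abs(t[left] - grid) < np.abs(t[idx] - grid), left, idx)
    if isinstance(obj, AccelTrace):
        return AccelTrace(
            bird_id=obj.bird_id, t=t[idx], X=obj.X[idx], Y=obj.Y[idx],
            Z=obj.Z[idx],
            depth=None if obj.depth is None else obj.depth[idx],
            temperature=(None if obj.temperature is None
                         else obj.temperature[idx]))
    return obj.iloc[idx].reset_index(drop=True)


_EARTH_RADIUS = 6_371_000.0  # m


def _haversine(lon1, lat1, lon2, lat2) -> np.ndarray:
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    a = (np.sin((lat2 - lat1) / 2) ** 2
         + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2)
    return 2 * _EARTH_RADIUS * np.arcsin(np.sqrt(a))


def ground_speed(track: GpsTrack) -> np.ndarray:
    """Per-fix ground speed in m/s.

    Speed at fix ``i`` is the distance from fix ``i-1`` divided by the
    elapsed time; the first fix is assigned the speed of the second.
    Planar Euclidean distance for nest-centered tracks, great-circle
    distance for lon/lat tracks.
    """
    if len(track) < 2:
        raise DataError("ground speed needs at least two fixes")
    dt = np.diff(track.t)
    if np.any(dt <= 0):
        raise DataError("duplicate or non-increasing GPS timestamps")
    if track.lonlat:
        dist = _haversine(track.x[:-1], track.y[:-1],
                          track.x[1:], track.y[1:])
    else:
        dist = np.hypot(np.diff(track.x), np.diff(track.y))
    speed = np.empty(len(track))
    speed[1:] = dist / dt
    speed[0] = speed[1]
    return speed
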