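"""Core signal and series containers plus delimited-text I/O and resampling.

Everything downstream of the raw recordings is expressed in terms of five
containers: uniformly sampled waveforms (PPG, ECG, accelerometer-derived
envelopes), triaxial accelerometer traces, beat event trains, unevenly
time-stamped inter-beat interval series, and uniformly resampled
variability series.  Time is in seconds everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

__all__ = [
    "UniformSignal",
    "TriaxialSignal",
    "BeatTrain",
    "IntervalSeries",
    "UniformVariability",
    "read_signal",
    "write_signal",
    "read_beats",
    "write_beats",
    "read_intervals",
    "write_intervals",
    "resample_cubic",
]


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class UniformSignal:
    """A uniformly sampled waveform; sample k lives at time ``t0 + k/fs``."""

    values: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "values", _as_float_array(self.values, "values"))
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.values.size < 1:
            raise ValueError("signal must contain at least one sample")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    @property
    def duration(self) -> float:
        return (self.n - 1) / self.fs


@dataclass(frozen=True)
class TriaxialSignal:
    """Three-axis accelerometer trace sharing one sampling rate."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    fs: float

    def __post_init__(self):
        for name in ("x", "y", "z"):
            object.__setattr__(self, name, _as_float_array(getattr(self, name), name))
        if not (self.x.size == self.y.size == self.z.size):
            raise ValueError("the three axes must have equal lengths")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")

    @property
    def n(self) -> int:
        return self.x.size


@dataclass(frozen=True)
class BeatTrain:
    """Strictly increasing event times (R-peaks or systolic peaks), seconds."""

    times: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "times", _as_float_array(self.times, "times"))
        if self.times.size and np.any(self.times < 0):
            raise ValueError("beat times must be non-negative")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("beat times must be strictly increasing")

    @property
    def n(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class IntervalSeries:
    """Unevenly stamped inter-beat durations.

    ``anchor_times[k]`` is the time of the beat *ending* interval k, so a
    series built from a beat train satisfies
    ``anchor_times[k] - anchor_times[k-1] == durations[k]``.
    ``log`` records correction events (merges/splits) applied by
    post-processing stages.
    """

    anchor_times: np.ndarray
    durations: np.ndarray
    log: tuple = field(default_factory=tuple)

    def __post_init__(self):
        object.__setattr__(
            self, "anchor_times", _as_float_array(self.anchor_times, "anchor_times")
        )
        object.__setattr__(
            self, "durations", _as_float_array(self.durations, "durations")
        )
        object.__setattr__(self, "log", tuple(self.log))
        if self.anchor_times.size != self.durations.size:
            raise ValueError("anchor_times and durations must have equal lengths")
        if np.any(self.durations <= 0):
            raise ValueError("durations must be positive")
        if self.anchor_times.size > 1 and np.any(np.diff(self.anchor_times) <= 0):
            raise ValueError("anchor_times must be strictly increasing")

    @property
    def n(self) -> int:
        return self.durations.size

    @property
    def total_duration(self) -> float:
        return float(np.sum(self.durations))


@dataclass(frozen=True)
class UniformVariability:
    """Evenly resampled variability series (interval durations in s)."""

    values: np.ndarray
    fs_v: float
    t0: float = 0.0
    log: tuple = field(default_factory=tuple)

    def __post_init__(self):
        object.__setattr__(self, "values", _as_float_array(self.values, "values"))
        object.__setattr__(self, "log", tuple(self.log))
        if not self.fs_v > 0:
            raise ValueError(f"fs_v must be positive, got {self.fs_v}")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs_v


# ---------------------------------------------------------------------------
# Delimited-text I/O.  Dialect: comma-separated, optional single header line
# (auto-detected by a non-numeric first row), times in seconds.
# ---------------------------------------------------------------------------


def _read_table(path) -> np.ndarray:
    try:
        first = pd.read_csv(path, header=None, nrows=1)
    except FileNotFoundError:
        raise FileNotFoundError(f"no such file: {path}")
    has_header = not np.all(
        [np.issubdtype(first.dtypes[c], np.number) for c in first.columns]
    )
    df = pd.read_csv(path, header=0 if has_header else None)
    try:
        arr = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric rows in {path}: {exc}") from None
    if not np.all(np.isfinite(arr)):
        bad = int(np.argwhere(~np.isfinite(arr))[0, 0])
        raise ValueError(f"non-finite value at data row {bad} of {path}")
    return arr


def read_signal(path, fs: float | None = None, time_scale: float = 1.0) -> UniformSignal:
    """Read a one- or two-column (time,value) CSV into a :class:`UniformSignal`.

    With a time column, spacing must be uniform to within 10% of ``1/fs``;
    ``fs`` is derived from the median spacing when not given.  ``time_scale``
    converts the on-disk time unit to seconds (e.g. 1e-3 for ms stamps).
    """
    arr = _read_table(path)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.shape[1] == 1:
        if fs is None:
            raise ValueError("fs is required for a single-column file")
        return UniformSignal(arr[:, 0], fs=fs)
    if arr.shape[1] != 2:
        raise ValueError(f"expected 1 or 2 columns, got {arr.shape[1]} in {path}")
    t = arr[:, 0] * time_scale
    v = arr[:, 1]
    if t.size < 2:
        if fs is None:
            raise ValueError("fs is required for a single-row file")
        return UniformSignal(v, fs=fs, t0=float(t[0]))
    dt = np.diff(t)
    if fs is None:
        fs = 1.0 / float(np.median(dt))
    dev = np.abs(dt - 1.0 / fs)
    bad = np.nonzero(dev >= 0.1 / fs)[0]
    if bad.size:
        k = int(bad[0])
        raise ValueError(
            f"non-uniform time column in {path}: spacing {dt[k]:.6g} s at row "
            f"{k + 1} deviates >=10% from expected {1.0 / fs:.6g} s"
        )
    return UniformSignal(v, fs=fs, t0=float(t[0]))


def write_signal(signal: UniformSignal, path) -> str:
    """Write ``time,value`` CSV; round-trips through :func:`read_signal`."""
    df = pd.DataFrame({"time": signal.times, "value": signal.values})
    df.to_csv(path, index=False, float_format="%.17g")
    return str(path)


def read_beats(path) -> BeatTrain:
    arr = _read_table(path)
    if arr.ndim > 1:
        arr = arr[:, 0]
    return BeatTrain(arr)


def write_beats(beats: BeatTrain, path) -> str:
    pd.DataFrame({"time": beats.times}).to_csv(path, index=False, float_format="%.17g")
    return str(path)


def read_intervals(path) -> IntervalSeries:
    arr = _read_table(path)
    if arr.ndim == 1 or arr.shape[1] < 2:
        raise ValueError(f"interval file {path} needs anchor_time,duration columns")
    return IntervalSeries(arr[:, 0], arr[:, 1])


def write_intervals(iv: IntervalSeries, path) -> str:
    pd.DataFrame({"anchor_time": iv.anchor_times, "duration": iv.durations}).to_csv(
        path, index=False, float_format="%.17g"
    )
    return str(path)


def resample_cubic(signal: UniformSignal, target_fs: float) -> UniformSignal:
    """Resample onto a ``target_fs`` grid with a cubic spline through all samples.

    The output covers the same time span (no extrapolation); the interpolant
    passes exactly through the original samples, so resampling at the native
    rate is the identity.
    """
    if signal.n < 4:
        raise ValueError("cubic resampling needs at least 4 samples")
    if not target_fs > 0:
        raise ValueError(f"target_fs must be positive, got {target_fs}")
    spline = CubicSpline(signal.times, signal.values)
    n_out = int(np.floor(signal.duration * target_fs + 1e-9)) + 1
    t_new = signal.t0 + np.arange(n_out) / target_fs
    return UniformSignal(spline(t_new), fs=target_fs, t0=signal.t0)
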