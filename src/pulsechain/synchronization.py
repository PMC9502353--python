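"""Accelerometer tap-envelope computation and offset application.

Recording sessions start and end with the participant tapping the
devices together; the taps show up as short high-energy bursts in the
accelerometer and anchor the cross-device time alignment.  The envelope
computed here makes them easy to locate; the alignment offset itself is
confirmed by the user and applied with :func:`apply_offset`.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import hilbert

from .signal_model import TriaxialSignal, UniformSignal

__all__ = ["tap_envelope", "apply_offset", "report_peaks"]

#: moving-average window presets (samples) per device accelerometer
DEVICE_SMOOTH_WINDOWS = {"smartwatch": 20, "chest": 34, "wristband": 16}


def tap_envelope(acc: TriaxialSignal, smooth_window: int = 20) -> UniformSignal:
    """Normalised energy envelope of a triaxial accelerometer trace.

    Sum of squared axes -> mean subtraction -> centred moving average of
    ``smooth_window`` samples -> magnitude of the analytic extension ->
    min-max normalisation to [0, 1].  Constant traces (zero energy after
    mean removal) are rejected.
    """
    if smooth_window < 1:
        raise ValueError("smooth_window must be >= 1")
    energy = acc.x ** 2 + acc.y ** 2 + acc.z ** 2
    energy = energy - energy.mean()
    smoothed = (
        np.convolve(energy, np.ones(smooth_window) / smooth_window, mode="same")
        if smooth_window > 1
        else energy
    )
    env = np.abs(hilbert(smoothed))
    lo, hi = float(env.min()), float(env.max())
    if hi - lo <= 1e-15 * max(1.0, hi):
        raise ValueError("constant accelerometer energy: envelope undefined")
    return UniformSignal((env - lo) / (hi - lo), fs=acc.fs)


def apply_offset(signal: UniformSignal, offset: float) -> UniformSignal:
    """Shift a signal's start time by ``offset`` seconds (values untouched)."""
    return UniformSignal(signal.values, fs=signal.fs, t0=signal.t0 + offset)


def report_peaks(
    envelope: UniformSignal, k: int = 4, min_separation: float = 1.0
) -> np.ndarray:
    """Times of the ``k`` largest well-separated envelope peaks.

    Helper for locating synchronisation taps; the user confirms which
    peaks are taps and derives the offset from them.
    """
    order = np.argsort(envelope.values)[::-1]
    chosen: list[int] = []
    min_sep = int(round(min_separation * envelope.fs))
    for i in order:
        if len(chosen) >= k:
            break
        if all(abs(i - j) >= min_sep for j in chosen):
            chosen.append(int(i))
    return envelope.t0 + np.sort(np.asarray(chosen, dtype=float)) / envelope.fs
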