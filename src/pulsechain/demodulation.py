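"""Amplitude demodulation of the band-filtered PPG.

Wrist PPG amplitude is modulated by perfusion, contact pressure and
motion; pulse *timing* is not.  Dividing the waveform by a positive
estimate of its local amplitude flattens the envelope while preserving
signs and zero-crossing positions, which is what makes demodulation safe
ahead of beat detection.  Three estimators are provided:

* :func:`adaptive_standardize` — sliding-window standard deviation;
* :func:`online_demodulate` — sliding-window mean of gated local extrema;
* :func:`hilbert_demodulate` — magnitude of the analytic extension
  (parameter-free; the default used by the processing chain).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .signal_model import UniformSignal

__all__ = [
    "DemodulationParams",
    "adaptive_standardize",
    "online_demodulate",
    "hilbert_demodulate",
    "demodulate",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DemodulationParams:
    """Parameters of the windowed algorithms.

    ``window_len`` is an odd sample count; ``p`` gates local extrema at
    ``p`` times the window's max-min span in the online algorithm.
    """

    window_len: int = 125
    p: float = 0.3

    def __post_init__(self):
        if self.window_len < 3 or self.window_len % 2 == 0:
            raise ValueError(f"window_len must be odd and >= 3, got {self.window_len}")
        if not 0 < self.p < 1:
            raise ValueError(f"p must lie in (0, 1), got {self.p}")


def _check_window(window_len: int, n: int) -> None:
    if window_len < 3 or window_len % 2 == 0:
        raise ValueError(f"window_len must be odd and >= 3, got {window_len}")
    if window_len > n:
        raise ValueError(f"window_len {window_len} exceeds signal length {n}")


def adaptive_standardize(signal: UniformSignal, window_len: int = 125) -> UniformSignal:
    """Divide each sample by the SD over the window centred on it.

    Edge samples use truncated windows.  Windows with zero SD fall back to
    an epsilon of ``1e-12`` times the global SD (logged).
    """
    _check_window(window_len, signal.n)
    x = signal.values
    sd = (
        pd.Series(x)
        .rolling(window_len, center=True, min_periods=1)
        .std(ddof=0)
        .to_numpy()
    )
    global_sd = float(np.std(x))
    eps = 1e-12 * global_sd if global_sd > 0 else 1e-12
    degenerate = sd <= eps
    if degenerate.any():
        logger.info(
            "adaptive_standardize: %d zero-SD windows guarded with epsilon",
            int(degenerate.sum()),
        )
        sd = np.where(degenerate, eps, sd)
    return UniformSignal(x / sd, fs=signal.fs, t0=signal.t0)


def online_demodulate(
    signal: UniformSignal, params: DemodulationParams | None = None
) -> UniformSignal:
    """Sliding-window demodulation by the mean magnitude of gated extrema.

    Per window (odd length, truncated at the edges, sliding by one
    sample): subtract the window mean; let Delta be the window's
    max-minus-min; collect interior local maxima above ``p*Delta`` and
    minima below ``-p*Delta``; divide the centre sample by the mean
    absolute value of the qualifying extrema.  Windows without qualifying
    extrema fall back to ``Delta/2`` as the divisor (logged).
    """
    if params is None:
        params = DemodulationParams()
    _check_window(params.window_len, signal.n)
    x = signal.values
    n = signal.n
    hw = params.window_len // 2
    out = np.empty(n)
    global_sd = float(np.std(x))
    eps = 1e-12 * global_sd if global_sd > 0 else 1e-12
    n_fallback = 0
    for c in range(n):
        w = x[max(0, c - hw): min(n, c + hw + 1)]
        w = w - w.mean()
        delta = float(w.max() - w.min())
        if delta <= eps:
            out[c] = x[c] / eps
            n_fallback += 1
            continue
        interior = w[1:-1]
        is_max = (interior > w[:-2]) & (interior > w[2:]) & (interior > params.p * delta)
        is_min = (interior < w[:-2]) & (interior < w[2:]) & (interior < -params.p * delta)
        ext = np.abs(interior[is_max | is_min])
        if ext.size == 0:
            divisor = delta / 2.0
            n_fallback += 1
        else:
            divisor = float(ext.mean())
        out[c] = x[c] / divisor
    if n_fallback:
        logger.info(
            "online_demodulate: fallback divisor used in %d/%d windows", n_fallback, n
        )
    return UniformSignal(out, fs=signal.fs, t0=signal.t0)


def hilbert_demodulate(signal: UniformSignal) -> UniformSignal:
    """Divide by the magnitude of the analytic extension (unit envelope out).

    Parameter-free; samples where the envelope collapses below ``1e-12``
    times the global RMS are guarded with that epsilon (logged).
    """
    x = signal.values
    rms = float(np.sqrt(np.mean(x ** 2)))
    if rms == 0.0:
        raise ValueError("cannot demodulate an all-zero signal")
    env = np.abs(hilbert(x))
    eps = 1e-12 * rms
    degenerate = env < eps
    if degenerate.any():
        logger.info(
            "hilbert_demodulate: %d near-zero envelope samples guarded",
            int(degenerate.sum()),
        )
        env = np.where(degenerate, eps, env)
    return UniformSignal(x / env, fs=signal.fs, t0=signal.t0)


_METHODS = {
    "hilbert": lambda s, params: hilbert_demodulate(s),
    "standardize": lambda s, params: adaptive_standardize(
        s, (params or DemodulationParams()).window_len
    ),
    "online": online_demodulate,
}


def demodulate(
    signal: UniformSignal,
    method: str = "hilbert",
    params: DemodulationParams | None = None,
) -> UniformSignal:
    """Dispatch to one of the three demodulation algorithms by name."""
    try:
        fn = _METHODS[method]
    except KeyError:
        raise ValueError(
            f"unknown demodulation method {method!r}; choose from {sorted(_METHODS)}"
        ) from None
    return fn(signal, params)
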