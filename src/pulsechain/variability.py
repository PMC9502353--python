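"""Inter-beat interval post-processing and uniform resampling.

The raw HRV/PRV series is a sequence of beat-to-beat durations stamped
at the beat ending each interval.  Post-processing repairs detection
errors while conserving total elapsed time:

1. physiological screening — durations outside 0.3-1.5 s (200-40 bpm)
   are merged into their neighbour (too short: a spurious extra beat) or
   split in half (too long: a missed beat);
2. local-statistics correction — durations outside mean +/- 3 SD of a
   centred 25-sample moving window are repaired the same way;
3. uniform resampling — cubic-spline interpolation to 10 Hz, zero-phase
   low-pass filtering at 0.5 Hz (the physiological variability bound),
   decimation to 1 Hz;
4. autoregressive correction — a 25-sample window slides over the
   uniform series, a Burg AR(8) model predicts the next sample, and the
   sample is replaced by the prediction when it deviates by more than
   one innovation SD.

Merging and splitting conserve the summed duration exactly, so the
screened series still spans the same stretch of time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import filtfilt, firwin, kaiserord
from statsmodels.regression.linear_model import burg

from .signal_model import BeatTrain, IntervalSeries, UniformVariability

__all__ = [
    "ScreeningBounds",
    "ArParams",
    "beats_to_intervals",
    "screen_physiological",
    "correct_outliers_local",
    "to_uniform",
    "ar_correct",
]


@dataclass(frozen=True)
class ScreeningBounds:
    """Physiological interval limits in seconds (defaults 0.3-1.5 s,
    i.e. 200 down to 40 bpm)."""

    lo: float = 0.3
    hi: float = 1.5

    def __post_init__(self):
        if not 0 < self.lo < self.hi:
            raise ValueError(f"require 0 < lo < hi, got {self.lo}, {self.hi}")


@dataclass(frozen=True)
class ArParams:
    """AR-correction settings: sliding ``window`` of past samples, Burg
    model ``order``, replacement gate ``replace_k`` innovation SDs."""

    window: int = 25
    order: int = 8
    replace_k: float = 1.0

    def __post_init__(self):
        if not self.order < self.window:
            raise ValueError("order must be smaller than window")
        if not self.replace_k > 0:
            raise ValueError("replace_k must be positive")


def beats_to_intervals(beats: BeatTrain) -> IntervalSeries:
    """Durations between consecutive beats, anchored at the ending beat."""
    if beats.n < 2:
        raise ValueError("need at least 2 beats to form an interval")
    return IntervalSeries(beats.times[1:], np.diff(beats.times))


def _rebuild(first_start: float, durations: list[float], log: list[str]) -> IntervalSeries:
    durations = np.asarray(durations, dtype=float)
    anchors = first_start + np.cumsum(durations)
    return IntervalSeries(anchors, durations, log=tuple(log))


def screen_physiological(
    iv: IntervalSeries, bounds: ScreeningBounds | None = None
) -> IntervalSeries:
    """One left-to-right screening pass against the physiological limits.

    A duration below ``bounds.lo`` marks its ending beat as spurious: the
    interval is removed and its duration added to the following one (to
    the preceding one if it is last).  A duration above ``bounds.hi``
    suggests a skipped beat and is split into two halves.  Total summed
    duration is conserved; intervals still out of bounds after the single
    pass are reported in the result's log rather than re-processed.
    """
    if bounds is None:
        bounds = ScreeningBounds()
    start = float(iv.anchor_times[0] - iv.durations[0])
    src = list(iv.durations)
    out: list[float] = []
    log = list(iv.log)
    carry = 0.0
    for k, d in enumerate(src):
        d = d + carry
        carry = 0.0
        if d < bounds.lo:
            if k < len(src) - 1:
                carry = d
                log.append(f"screen: merged short interval {k} ({d:.3f} s) forward")
            elif out:
                out[-1] += d
                log.append(f"screen: merged trailing short interval {k} ({d:.3f} s) backward")
            else:
                out.append(d)
                log.append(f"screen: short interval {k} ({d:.3f} s) kept (nothing to merge)")
        elif d > bounds.hi:
            out.extend([d / 2.0, d / 2.0])
            log.append(f"screen: split long interval {k} ({d:.3f} s) in half")
        else:
            out.append(d)
    residual = sum(1 for d in out if d < bounds.lo or d > bounds.hi)
    if residual:
        log.append(f"screen: {residual} intervals remain out of bounds after one pass")
    return _rebuild(start, out, log)


def correct_outliers_local(
    iv: IntervalSeries, window: int = 25, k: float = 3.0
) -> IntervalSeries:
    """Repair durations outside mean +/- k*SD of a centred moving window.

    Moving statistics are computed once on the input (truncated windows
    at the edges).  A duration above the band is split in half; one below
    is merged into its successor (predecessor if last) — the same repairs
    as physiological screening, so total duration is conserved.  Windows
    with zero SD treat every sample as inside the band.
    """
    if window < 3:
        raise ValueError("window must be >= 3")
    d = iv.durations
    s = pd.Series(d)
    mean = s.rolling(window, center=True, min_periods=1).mean().to_numpy()
    sd = s.rolling(window, center=True, min_periods=1).std(ddof=0).to_numpy()
    start = float(iv.anchor_times[0] - iv.durations[0])
    out: list[float] = []
    log = list(iv.log)
    carry = 0.0
    for j in range(d.size):
        val = d[j] + carry
        carry = 0.0
        if sd[j] <= 0:
            out.append(val)
            continue
        hi = mean[j] + k * sd[j]
        lo = mean[j] - k * sd[j]
        if val > hi:
            out.extend([val / 2.0, val / 2.0])
            log.append(f"local-stats: split interval {j} ({val:.3f} s > {hi:.3f})")
        elif val < lo:
            if j < d.size - 1:
                carry = val
                log.append(f"local-stats: merged interval {j} ({val:.3f} s < {lo:.3f}) forward")
            elif out:
                out[-1] += val
                log.append(f"local-stats: merged trailing interval {j} backward")
            else:
                out.append(val)
        else:
            out.append(val)
    return _rebuild(start, out, log)


def _design_lowpass(cutoff: float, fs: float, n_samples: int) -> np.ndarray:
    """Zero-phase FIR low-pass with a 0.1 Hz transition centred on
    ``cutoff`` (60 dB stopband from cutoff+0.05 Hz); taps capped so short
    series remain filterable."""
    nyq = fs / 2.0
    width = min(0.1, 2.0 * (nyq - cutoff) * 0.9) / nyq
    ntaps, beta = kaiserord(60.0, width)
    ntaps = min(ntaps, max(3, (n_samples - 1) // 3))
    if ntaps % 2 == 0:
        ntaps += 1
    return firwin(ntaps, cutoff / nyq, window=("kaiser", beta))


def to_uniform(
    iv: IntervalSeries,
    mid_fs: float = 10.0,
    cutoff: float = 0.5,
    out_fs: float = 1.0,
    t_start: float | None = None,
    t_end: float | None = None,
) -> UniformVariability:
    """Resample an interval series onto a uniform grid.

    Cubic-spline interpolation of (anchor time, duration) onto a
    ``mid_fs`` grid, zero-phase low-pass at ``cutoff``, then decimation
    to ``out_fs``.  The output never extrapolates beyond the anchor span;
    ``t_start``/``t_end`` may restrict it further (e.g. to a span shared
    with a reference series).
    """
    if iv.n < 4:
        raise ValueError("need at least 4 intervals to resample")
    if mid_fs % out_fs > 1e-9:
        raise ValueError("mid_fs must be an integer multiple of out_fs")
    a0, a1 = float(iv.anchor_times[0]), float(iv.anchor_times[-1])
    t_start = a0 if t_start is None else max(t_start, a0)
    t_end = a1 if t_end is None else min(t_end, a1)
    if t_end - t_start < 4.0 / out_fs:
        raise ValueError(
            f"anchor span {t_end - t_start:.2f} s too short for {out_fs} Hz output"
        )
    spline = CubicSpline(iv.anchor_times, iv.durations)
    n_mid = int(np.floor((t_end - t_start) * mid_fs + 1e-9)) + 1
    t_mid = t_start + np.arange(n_mid) / mid_fs
    y = spline(t_mid)
    taps = _design_lowpass(cutoff, mid_fs, n_mid)
    if taps.size >= 3 and n_mid > 3 * taps.size:
        y = filtfilt(taps, [1.0], y)
    elif taps.size >= 3:
        y = filtfilt(taps, [1.0], y, padlen=max(1, min(n_mid - 2, 3 * taps.size)))
    step = int(round(mid_fs / out_fs))
    return UniformVariability(y[::step], fs_v=out_fs, t0=t_start, log=iv.log)


def ar_correct(series: UniformVariability, params: ArParams | None = None) -> UniformVariability:
    """Replace samples that defy a local autoregressive prediction.

    A window of ``params.window`` past *observed* samples is mean-removed
    and fitted with a Burg AR model of order ``params.order``; the next
    sample is replaced by the one-step prediction when it deviates by
    more than ``replace_k`` innovation SDs.  The innovation SD carries a
    ``sqrt(window / (window - order))`` small-sample correction so the
    gate refers to out-of-sample prediction error rather than the
    in-sample fit.  Fitting on the observed rather than the corrected
    series keeps the filter open-loop: replacements cannot compound into
    model drift, so on clean data the correction is nearly neutral.  The
    first ``window`` samples pass through unchanged; constant (singular)
    windows skip correction for that step.
    """
    if params is None:
        params = ArParams()
    if series.n <= params.window:
        raise ValueError(
            f"series length {series.n} must exceed the AR window {params.window}"
        )
    observed = series.values
    y = series.values.copy()
    log = list(series.log)
    w, order = params.window, params.order
    dof_scale = np.sqrt(w / (w - order))
    for i in range(w, y.size):
        win = observed[i - w: i]
        mu = float(win.mean())
        centred = win - mu
        if float(np.max(np.abs(centred))) < 1e-12 * max(1.0, abs(mu)):
            log.append(f"ar: constant window before sample {i}, correction skipped")
            continue
        try:
            rho, sigma2 = burg(centred, order=order, demean=False)
        except (np.linalg.LinAlgError, ValueError):
            log.append(f"ar: singular fit before sample {i}, correction skipped")
            continue
        pred = mu + float(np.dot(rho, centred[::-1][: order]))
        sd = float(np.sqrt(max(sigma2, 0.0))) * dof_scale
        if sd > 0 and abs(observed[i] - pred) > params.replace_k * sd:
            log.append(
                f"ar: sample {i} ({y[i]:.4f}) replaced by prediction {pred:.4f} "
                f"(|dev| > {params.replace_k:g} SD = {params.replace_k * sd:.4f})"
            )
            y[i] = pred
    return UniformVariability(y, fs_v=series.fs_v, t0=series.t0, log=tuple(log))
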