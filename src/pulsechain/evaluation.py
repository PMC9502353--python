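"""Metrics comparing a PRV series against the reference HRV.

Raw interval series from the two chains generally have different
lengths (missed or spurious beats), so they are compared with dynamic
time warping (DTW) and with the Pearson correlation of the aligned
pairs.  The uniformly resampled series are compared with the relative
root-mean-square error

    RRMSE = 100 * ||PRV - HRV||_2 / ||HRV||_2   [%]

and pooled across participants as the root mean square of individual
RRMSEs (mRRMSE).  Spectral content is checked with a Welch PSD
(30 s window, 25-sample overlap at 1 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import welch

from .signal_model import IntervalSeries, UniformVariability

__all__ = [
    "ComparisonReport",
    "PsdEstimate",
    "dtw_align",
    "aligned_pearson",
    "rrmse",
    "mrrmse",
    "welch_psd",
    "compare",
]


@dataclass(frozen=True)
class ComparisonReport:
    """Summary of one PRV-vs-HRV comparison."""

    rrmse: float          # percent, on the uniform series
    dtw_distance: float   # s, sum of matched absolute differences
    pearson_r: float      # correlation of DTW-aligned pairs (nan if undefined)
    n_ref: int            # raw HRV length
    n_test: int           # raw PRV length


@dataclass(frozen=True)
class PsdEstimate:
    """One-sided power spectral density of a variability series."""

    freqs: np.ndarray   # Hz
    power: np.ndarray   # s^2/Hz

    @property
    def peak_freq(self) -> float:
        return float(self.freqs[int(np.argmax(self.power))])


def dtw_align(a, b) -> tuple[float, list[tuple[int, int]]]:
    """Classic DTW with |a_i - b_j| cost and unit-weight symmetric steps.

    Returns the accumulated cost of the optimal boundary-to-boundary
    path and the path itself as monotone, contiguous (i, j) index pairs.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("DTW inputs must be non-empty")
    n, m = a.size, b.size
    cost = np.abs(a[:, None] - b[None, :])
    acc = np.full((n, m), np.inf)
    acc[0, 0] = cost[0, 0]
    acc[0, 1:] = cost[0, 1:].cumsum() + cost[0, 0]
    acc[1:, 0] = cost[1:, 0].cumsum() + cost[0, 0]
    for i in range(1, n):
        row_prev = acc[i - 1]
        row = acc[i]
        c = cost[i]
        for j in range(1, m):
            row[j] = c[j] + min(row_prev[j], row[j - 1], row_prev[j - 1])
    # backtrack, preferring the diagonal on ties
    path = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while (i, j) != (0, 0):
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            options = ((acc[i - 1, j - 1], i - 1, j - 1),
                       (acc[i - 1, j], i - 1, j),
                       (acc[i, j - 1], i, j - 1))
            _, i, j = min(options, key=lambda o: o[0])
        path.append((i, j))
    path.reverse()
    return float(acc[n - 1, m - 1]), path


def aligned_pearson(a, b, path) -> float:
    """Pearson correlation over the DTW-matched pairs.

    Every path pair contributes once (many-to-one matches repeat the
    shared sample).  Returns ``nan`` when either side has zero variance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ai = np.array([a[i] for i, _ in path])
    bj = np.array([b[j] for _, j in path])
    if np.std(ai) == 0 or np.std(bj) == 0:
        return float("nan")
    return float(np.corrcoef(ai, bj)[0, 1])


def rrmse(prv: UniformVariability, hrv: UniformVariability) -> float:
    """Relative RMSE in percent: ``100 * ||PRV-HRV|| / ||HRV||``."""
    if prv.n != hrv.n:
        raise ValueError(f"length mismatch: {prv.n} vs {hrv.n}")
    if prv.fs_v != hrv.fs_v:
        raise ValueError(f"rate mismatch: {prv.fs_v} vs {hrv.fs_v}")
    denom = float(np.linalg.norm(hrv.values))
    if denom == 0:
        raise ValueError("all-zero reference series")
    return 100.0 * float(np.linalg.norm(prv.values - hrv.values)) / denom


def mrrmse(per_participant) -> float:
    """Root mean square of per-participant RRMSEs, in percent."""
    vals = np.asarray(list(per_participant), dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one participant RRMSE")
    return float(np.sqrt(np.mean(vals ** 2)))


def welch_psd(
    series: UniformVariability,
    window_s: float = 30.0,
    overlap_samples: int = 25,
) -> PsdEstimate:
    """Welch PSD with a Hamming taper and per-segment mean removal."""
    nperseg = int(round(window_s * series.fs_v))
    if series.n < nperseg:
        raise ValueError(
            f"series ({series.n} samples) shorter than one {window_s} s segment"
        )
    freqs, power = welch(
        series.values,
        fs=series.fs_v,
        window="hamming",
        nperseg=nperseg,
        noverlap=overlap_samples,
        detrend="constant",
    )
    return PsdEstimate(freqs, power)


def compare(
    prv_raw: IntervalSeries,
    hrv_raw: IntervalSeries,
    prv_u: UniformVariability,
    hrv_u: UniformVariability,
) -> ComparisonReport:
    """Assemble DTW, aligned correlation and RRMSE into one report."""
    distance, path = dtw_align(prv_raw.durations, hrv_raw.durations)
    r = aligned_pearson(prv_raw.durations, hrv_raw.durations, path)
    return ComparisonReport(
        rrmse=rrmse(prv_u, hrv_u),
        dtw_distance=distance,
        pearson_r=r,
        n_ref=hrv_raw.n,
        n_test=prv_raw.n,
    )
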