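"""Beat detection: R-peaks in ECG and systolic peaks in PPG.

The ECG reference chain uses the Pan-Tompkins algorithm (derivative,
squaring, moving-window integration, dual adaptive thresholds with
search-back and a T-wave slope test).  The band-pass front end of the
original algorithm is omitted because the wavelet band filter has already
done that job.

Three PPG detectors emit comparable systolic-peak fiducials:

* :func:`pda` — neighbour comparison with a relative amplitude gate;
* :func:`ampd` — automatic multiscale peak detection via the
  local-maxima scalogram, applied segment-wise;
* :func:`ssf_detect` — slope-sum-function onset detection with an
  adaptive threshold, refined to the nearby signal maximum.

All detectors assume the input has been band filtered (and, for PPG,
amplitude demodulated so the envelope is near unity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .signal_model import BeatTrain, UniformSignal

__all__ = [
    "SsfParams",
    "pan_tompkins",
    "pda",
    "ampd",
    "ssf_transform",
    "ssf_detect",
    "detect_beats",
]

ECG_REFRACTORY_S = 0.2
PPG_REFRACTORY_S = 0.3


@dataclass(frozen=True)
class SsfParams:
    """Slope-sum-function settings: ``w`` is the analysis window in ms
    (default 128), ``init_seconds`` the stretch used for the initial
    threshold, ``update_fraction`` the per-pulse threshold update."""

    w: float = 128.0
    init_seconds: float = 10.0
    update_fraction: float = 0.40

    def __post_init__(self):
        if not self.w > 0:
            raise ValueError(f"w must be positive, got {self.w}")
        if not 0 < self.update_fraction < 1:
            raise ValueError(
                f"update_fraction must lie in (0, 1), got {self.update_fraction}"
            )
        if not self.init_seconds > 0:
            raise ValueError(f"init_seconds must be positive, got {self.init_seconds}")


# ---------------------------------------------------------------------------
# ECG: Pan-Tompkins
# ---------------------------------------------------------------------------


def pan_tompkins(ecg: UniformSignal) -> BeatTrain:
    """Detect R-peaks in a wavelet-filtered ECG.

    Derivative -> squaring -> 150 ms moving-window integration (centred,
    so the fiducial has no group delay) -> dual adaptive thresholds with
    search-back at 1.66 times the running RR average, a 200 ms refractory
    period, and a T-wave slope test for candidates within 360 ms of the
    previous beat.  Reported times are the filtered-ECG maxima within
    +/-50 ms of each integrator fiducial.
    """
    fs = ecg.fs
    if fs < 100:
        raise ValueError(f"Pan-Tompkins needs fs >= 100 Hz, got {fs}")
    if ecg.duration < 2.0:
        raise ValueError("signal shorter than 2 s: cannot initialise thresholds")
    x = ecg.values
    n = ecg.n

    # five-point derivative, squaring, centred 150 ms integration
    dkernel = np.array([2.0, 1.0, 0.0, -1.0, -2.0]) * fs / 8.0
    deriv = np.convolve(x, dkernel, mode="same")
    squared = deriv ** 2
    n_int = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(squared, np.ones(n_int) / n_int, mode="same")

    refr = int(round(ECG_REFRACTORY_S * fs))
    cand, _ = find_peaks(mwi, distance=max(1, refr // 2))
    if cand.size == 0:
        return BeatTrain(np.empty(0))

    n_init = int(round(2.0 * fs))
    spki = 0.5 * float(mwi[:n_init].max())
    npki = 0.5 * float(mwi[:n_init].mean())

    accepted: list[int] = []
    noise_peaks: list[int] = []
    rr_history: list[float] = []

    def slope_at(i: int) -> float:
        lo, hi = max(0, i - n_int), min(n, i + n_int)
        return float(np.max(np.abs(deriv[lo:hi])))

    for i in cand:
        thr1 = npki + 0.25 * (spki - npki)
        accept = False
        if mwi[i] > thr1:
            if accepted and (i - accepted[-1]) < refr:
                pass  # inside refractory period: ignore
            elif accepted and (i - accepted[-1]) / fs < 0.360:
                # T-wave test: genuine QRS has comparable max slope
                if slope_at(i) < 0.5 * slope_at(accepted[-1]):
                    npki = 0.125 * mwi[i] + 0.875 * npki
                    noise_peaks.append(i)
                else:
                    accept = True
            else:
                accept = True
        else:
            npki = 0.125 * mwi[i] + 0.875 * npki
            noise_peaks.append(i)

        if accept:
            if accepted:
                rr_history.append((i - accepted[-1]) / fs)
                if len(rr_history) > 8:
                    rr_history.pop(0)
            accepted.append(i)
            spki = 0.125 * mwi[i] + 0.875 * spki
        elif rr_history and accepted:
            # search-back when a beat seems missed
            rr_avg = float(np.mean(rr_history))
            if (i - accepted[-1]) / fs > 1.66 * rr_avg:
                thr2 = 0.5 * thr1
                window = [
                    j for j in noise_peaks
                    if accepted[-1] + refr <= j < i - refr and mwi[j] > thr2
                ]
                if window:
                    j = max(window, key=lambda k: mwi[k])
                    rr_history.append((j - accepted[-1]) / fs)
                    if len(rr_history) > 8:
                        rr_history.pop(0)
                    accepted.append(j)
                    spki = 0.25 * mwi[j] + 0.75 * spki
                    noise_peaks = [k for k in noise_peaks if k > j]

    # refine each integrator fiducial to the R maximum within +/-50 ms
    half = max(1, int(round(0.050 * fs)))
    times = []
    for i in sorted(accepted):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        r = lo + int(np.argmax(x[lo:hi]))
        t = ecg.t0 + r / fs
        if not times or t - times[-1] >= ECG_REFRACTORY_S:
            times.append(t)
    return BeatTrain(np.asarray(times))


# ---------------------------------------------------------------------------
# PPG: PDA
# ---------------------------------------------------------------------------


def pda(ppg: UniformSignal, threshold: float = 0.8) -> BeatTrain:
    """Peak detection by neighbour comparison with a relative gate.

    Local maxima are kept when their amplitude reaches ``threshold``
    times the maximum over the surrounding 2 s (+/-1 s), with a minimum
    separation of 0.3 s resolved in favour of the larger peak.
    """
    x = ppg.values
    fs = ppg.fs
    peaks, _ = find_peaks(x)
    if peaks.size == 0:
        return BeatTrain(np.empty(0))
    half = int(round(1.0 * fs))
    gated = [
        i for i in peaks
        if x[i] >= threshold * x[max(0, i - half): min(ppg.n, i + half + 1)].max()
    ]
    min_sep = int(round(PPG_REFRACTORY_S * fs))
    kept: list[int] = []
    for i in sorted(gated, key=lambda k: -x[k]):  # larger peaks claim first
        if all(abs(i - j) >= min_sep for j in kept):
            kept.append(i)
    kept.sort()
    return BeatTrain(ppg.t0 + np.asarray(kept, dtype=float) / fs)


# ---------------------------------------------------------------------------
# PPG: AMPD
# ---------------------------------------------------------------------------


def _ampd_segment(x: np.ndarray) -> np.ndarray:
    """Peak indices of one segment via the local-maxima scalogram."""
    n = x.size
    # remove linear trend so slow drift does not mask periodicity
    t = np.arange(n)
    x = x - np.polyval(np.polyfit(t, x, 1), t)
    max_scale = int(np.ceil(n / 2.0)) - 1
    if max_scale < 1:
        return np.empty(0, dtype=int)
    not_max_counts = np.zeros(max_scale, dtype=int)
    masks = []
    for k in range(1, max_scale + 1):
        is_max = np.zeros(n, dtype=bool)
        is_max[k:n - k] = (x[k:n - k] > x[:n - 2 * k]) & (x[k:n - k] > x[2 * k:])
        masks.append(is_max)
        not_max_counts[k - 1] = n - int(is_max.sum())
    lam = int(np.argmin(not_max_counts)) + 1
    all_scales = np.logical_and.reduce(masks[:lam])
    return np.nonzero(all_scales)[0]


def ampd(ppg: UniformSignal, expected_peaks_per_segment: int = 30) -> BeatTrain:
    """Automatic multiscale peak detection, applied segment-wise.

    The scalogram is quadratic in segment length, so the signal is cut
    into segments expected to hold about ``expected_peaks_per_segment``
    pulses (using a spectral pulse-rate estimate), overlapping by 50%;
    duplicate detections within 0.1 s keep the earlier segment's index.
    """
    x = ppg.values
    fs = ppg.fs
    n = ppg.n
    if n < 4:
        raise ValueError("AMPD needs at least 4 samples")

    # crude pulse-rate estimate from the dominant spectral line in 0.5-3.5 Hz
    spec = np.abs(np.fft.rfft(x - x.mean()))
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    band = (freqs >= 0.5) & (freqs <= 3.5)
    rate_hz = float(freqs[band][np.argmax(spec[band])]) if band.any() else 1.0
    if rate_hz <= 0:
        rate_hz = 1.0
    seg_len = int(round(expected_peaks_per_segment / rate_hz * fs))
    seg_len = max(4, min(seg_len, n))
    hop = max(1, seg_len // 2)

    detections: list[int] = []
    start = 0
    while True:
        stop = min(start + seg_len, n)
        seg_peaks = _ampd_segment(x[start:stop]) + start
        tol = max(1, int(round(0.1 * fs)))
        for i in seg_peaks:
            if not any(abs(i - j) <= tol for j in detections[-6:]):
                detections.append(int(i))
        if stop >= n:
            break
        start += hop
    detections = sorted(set(detections))
    return BeatTrain(ppg.t0 + np.asarray(detections, dtype=float) / fs)


# ---------------------------------------------------------------------------
# PPG: slope sum function
# ---------------------------------------------------------------------------


def ssf_transform(ppg: UniformSignal, params: SsfParams | None = None) -> UniformSignal:
    """Windowed sum of positive first differences (upstroke accentuator).

    At each sample the positive slopes over the trailing window of
    ``params.w`` milliseconds are summed; negative slopes contribute
    nothing, so the output is non-negative and identically zero on
    non-increasing signals.
    """
    if params is None:
        params = SsfParams()
    x = ppg.values
    n_w = max(1, int(round(params.w / 1000.0 * ppg.fs)))
    d = np.zeros_like(x)
    d[1:] = np.maximum(np.diff(x), 0.0)
    c = np.concatenate(([0.0], np.cumsum(d)))
    ssf = np.empty_like(x)
    for i in range(x.size):
        ssf[i] = c[i + 1] - c[max(0, i - n_w + 1)]
    return UniformSignal(ssf, fs=ppg.fs, t0=ppg.t0)


def ssf_detect(ppg: UniformSignal, params: SsfParams | None = None) -> BeatTrain:
    """Systolic-peak detection via SSF onsets on the reflected signal.

    The signal is reflected upside-down so that the SSF upstroke onset
    lands at the systolic peak rather than the pulse foot.  The initial
    threshold is the mean SSF over the first ``init_seconds``; after each
    detected pulse it becomes ``update_fraction`` times that pulse's SSF
    maximum.  A 0.3 s refractory period applies, and the reported beat
    time is the maximum of the original signal in a window from one SSF
    window before the onset to 0.3 s after it.
    """
    if params is None:
        params = SsfParams()
    fs = ppg.fs
    if ppg.duration < params.init_seconds:
        raise ValueError(
            f"signal shorter than init_seconds ({params.init_seconds} s)"
        )
    reflected = UniformSignal(-ppg.values, fs=fs, t0=ppg.t0)
    ssf = ssf_transform(reflected, params).values
    n = ssf.size
    n_init = int(round(params.init_seconds * fs))
    thr = float(ssf[:n_init].mean())
    refr = int(round(PPG_REFRACTORY_S * fs))
    n_w = max(1, int(round(params.w / 1000.0 * fs)))
    search = int(round(PPG_REFRACTORY_S * fs))

    onsets: list[int] = []
    times: list[float] = []
    i = 1
    while i < n:
        if ssf[i] >= thr > ssf[i - 1] and (not onsets or i - onsets[-1] >= refr):
            onsets.append(i)
            pulse_max = float(ssf[i: min(n, i + search)].max())
            thr = params.update_fraction * pulse_max
            lo = max(0, i - n_w)
            hi = min(n, i + search + 1)
            r = lo + int(np.argmax(ppg.values[lo:hi]))
            t = ppg.t0 + r / fs
            if not times or t - times[-1] >= PPG_REFRACTORY_S:
                times.append(t)
            i += refr
        else:
            i += 1
    return BeatTrain(np.asarray(times))


def refine_peaks(
    signal: UniformSignal,
    beats: BeatTrain,
    target_fs: float = 1000.0,
    half_window_s: float = 0.12,
) -> BeatTrain:
    """Refine beat times to sub-sample precision by local spline upsampling.

    Around each detected beat, the waveform is interpolated with a cubic
    spline evaluated on a ``target_fs`` grid (default 1 kHz) and the beat
    moved to the local maximum.  This recovers the quantisation headroom
    that a 25 Hz PPG otherwise loses, without upsampling the whole record.
    """
    from scipy.interpolate import CubicSpline

    x = signal.values
    fs = signal.fs
    n = signal.n
    hw = max(2, int(round(half_window_s * fs)))
    refined = []
    for t in beats.times:
        k = int(round((t - signal.t0) * fs))
        lo, hi = max(0, k - hw), min(n, k + hw + 1)
        if hi - lo < 4:
            refined.append(t)
            continue
        tt = signal.t0 + np.arange(lo, hi) / fs
        spline = CubicSpline(tt, x[lo:hi])
        fine = np.arange(tt[0], tt[-1], 1.0 / target_fs)
        refined.append(float(fine[int(np.argmax(spline(fine)))]))
    refined = np.asarray(refined)
    keep = np.ones(refined.size, dtype=bool)
    for k in range(1, refined.size):  # guard monotonicity after refinement
        if refined[k] <= refined[k - 1]:
            keep[k] = False
    return BeatTrain(refined[keep])


_DETECTORS = {
    "pantompkins": lambda s, **kw: pan_tompkins(s),
    "pda": lambda s, **kw: pda(s, **kw),
    "ampd": lambda s, **kw: ampd(s, **kw),
    "ssf": lambda s, **kw: ssf_detect(s, **kw),
}


def detect_beats(signal: UniformSignal, method: str, **kwargs) -> BeatTrain:
    """Dispatch to a beat detector by name."""
    try:
        fn = _DETECTORS[method]
    except KeyError:
        raise ValueError(
            f"unknown detector {method!r}; choose from {sorted(_DETECTORS)}"
        ) from None
    return fn(signal, **kwargs)
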