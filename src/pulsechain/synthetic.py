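"""Synthetic paired PPG/ECG recordings with known ground truth.

Real wrist recordings of this kind are rarely shareable, so every stage
of the chain is exercised against generated signals instead.  The beat
process is an integral pulse frequency modulation (IPFM) model: an
instantaneous heart rate with low-frequency (~0.1 Hz, baroreflex) and
high-frequency (~0.25 Hz, respiratory) sinusoidal modulation is
integrated and a beat is emitted at each integer crossing.  ECG and PPG
waveforms are then synthesised by placing pulse templates at the beat
times (the PPG systolic peak trails the R-peak by a constant
pulse-transit offset), and five laboratory artifact regimes can be
injected into the PPG: none, 10 s lighting steps, finger taps (1 s
periods for the first half, 2 s for the second), rhythmic arm swings
(amplitude modulation plus slow baseline wander), and paced-breathing
baseline at 5 or 30 breaths/min.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .signal_model import BeatTrain, UniformSignal

__all__ = [
    "BeatProcessParams",
    "ArtifactSpec",
    "simulate_beats",
    "synth_ppg",
    "synth_ecg",
    "inject_artifacts",
    "ppg_template",
    "ecg_template",
]

ARTIFACT_REGIMES = ("none", "light", "tap", "arm", "breath")

#: constant pulse-transit delay between R-peak and systolic peak, seconds
DEFAULT_TRANSIT_S = 0.25


@dataclass(frozen=True)
class BeatProcessParams:
    """IPFM beat-process settings (rates in bpm, frequencies in Hz)."""

    duration: float = 300.0
    mean_hr: float = 70.0
    lf_freq: float = 0.1
    lf_amp: float = 3.0
    hf_freq: float = 0.25
    hf_amp: float = 2.0
    jitter_sd: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if self.mean_hr - self.lf_amp - self.hf_amp <= 40.0:
            raise ValueError(
                "instantaneous rate may fall below the 40 bpm guard: "
                f"mean_hr - lf_amp - hf_amp = "
                f"{self.mean_hr - self.lf_amp - self.hf_amp:g} bpm"
            )


@dataclass(frozen=True)
class ArtifactSpec:
    """Artifact regime and a scalar severity multiplying its nominal level."""

    regime: str = "none"
    severity: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.regime not in ARTIFACT_REGIMES:
            raise ValueError(
                f"unknown regime {self.regime!r}; choose from {ARTIFACT_REGIMES}"
            )
        if self.severity < 0:
            raise ValueError("severity must be >= 0")


def simulate_beats(
    params: BeatProcessParams,
) -> tuple[BeatTrain, Callable[[np.ndarray], np.ndarray]]:
    """Generate a beat train from the IPFM model.

    Returns the beat times and the ground-truth instantaneous-rate
    function ``r(t)`` in bpm.  Beats occur where the integral of
    ``r(t)/60`` crosses successive integers; optional Gaussian timing
    jitter (``jitter_sd`` seconds) is added afterwards.
    """

    def rate(t):
        t = np.asarray(t, dtype=float)
        return (
            params.mean_hr
            + params.lf_amp * np.sin(2 * np.pi * params.lf_freq * t)
            + params.hf_amp * np.sin(2 * np.pi * params.hf_freq * t)
        )

    def integral(t):
        # closed-form integral of rate(t)/60 from 0 to t
        t = np.asarray(t, dtype=float)
        out = params.mean_hr * t / 60.0
        if params.lf_amp and params.lf_freq:
            w = 2 * np.pi * params.lf_freq
            out = out + params.lf_amp / 60.0 * (1 - np.cos(w * t)) / w
        if params.hf_amp and params.hf_freq:
            w = 2 * np.pi * params.hf_freq
            out = out + params.hf_amp / 60.0 * (1 - np.cos(w * t)) / w
        return out

    grid = np.arange(0.0, params.duration + 1e-9, 1e-3)
    cum = integral(grid)
    n_beats = int(np.floor(cum[-1]))
    targets = np.arange(1, n_beats + 1, dtype=float)
    times = np.interp(targets, cum, grid)
    if params.jitter_sd > 0:
        rng = np.random.default_rng(params.seed)
        times = times + rng.normal(0.0, params.jitter_sd, size=times.size)
        times = np.sort(times)
        # enforce strict monotonicity after jitter
        for k in range(1, times.size):
            if times[k] <= times[k - 1]:
                times[k] = times[k - 1] + 1e-6
    return BeatTrain(times), rate


def ppg_template(tau: np.ndarray) -> np.ndarray:
    """PPG pulse shape: systolic lobe with a diastolic bump at 0.35 amplitude.

    ``tau`` is time relative to the systolic peak; support is about
    [-0.2, 0.5] s.
    """
    tau = np.asarray(tau, dtype=float)
    systolic = np.exp(-(tau ** 2) / (2 * 0.06 ** 2))
    diastolic = 0.35 * np.exp(-((tau - 0.22) ** 2) / (2 * 0.08 ** 2))
    return systolic + diastolic


def ecg_template(tau: np.ndarray) -> np.ndarray:
    """ECG beat shape: narrow biphasic QRS with small P and T lobes."""
    tau = np.asarray(tau, dtype=float)
    r = np.exp(-(tau ** 2) / (2 * 0.012 ** 2))
    q = -0.20 * np.exp(-((tau + 0.028) ** 2) / (2 * 0.010 ** 2))
    s = -0.28 * np.exp(-((tau - 0.028) ** 2) / (2 * 0.010 ** 2))
    p = 0.12 * np.exp(-((tau + 0.18) ** 2) / (2 * 0.025 ** 2))
    t_wave = 0.30 * np.exp(-((tau - 0.26) ** 2) / (2 * 0.045 ** 2))
    return r + q + s + p + t_wave


def _superpose(
    beats: BeatTrain,
    fs: float,
    template: Callable[[np.ndarray], np.ndarray],
    support: tuple[float, float],
    offsets: np.ndarray | float,
    duration: float | None,
) -> UniformSignal:
    if duration is None:
        duration = (beats.times[-1] if beats.n else 0.0) + max(1.0, support[1] + 0.5)
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs
    out = np.zeros(n)
    centers = beats.times + offsets
    for c in np.atleast_1d(centers):
        lo = max(0, int(np.floor((c + support[0]) * fs)))
        hi = min(n, int(np.ceil((c + support[1]) * fs)) + 1)
        if hi > lo:
            out[lo:hi] += template(t[lo:hi] - c)
    return UniformSignal(out, fs=fs)


def synth_ppg(
    beats: BeatTrain,
    fs: float = 25.0,
    transit: float = DEFAULT_TRANSIT_S,
    duration: float | None = None,
    template: Callable[[np.ndarray], np.ndarray] = ppg_template,
) -> UniformSignal:
    """Superpose PPG pulse templates, systolic peak at beat + ``transit``."""
    if beats.n == 0:
        n = int(round((duration or 1.0) * fs)) + 1
        return UniformSignal(np.zeros(n), fs=fs)
    med = float(np.median(np.diff(beats.times))) if beats.n > 1 else np.inf
    if med < 0.7:  # template support exceeds the beat interval
        import warnings

        warnings.warn("beat intervals shorter than the pulse template; overlap likely")
    return _superpose(beats, fs, template, (-0.25, 0.55), transit, duration)


def synth_ecg(
    beats: BeatTrain,
    fs: float = 130.0,
    duration: float | None = None,
    template: Callable[[np.ndarray], np.ndarray] = ecg_template,
) -> UniformSignal:
    """Superpose ECG beat templates centred exactly at the beat times."""
    if beats.n == 0:
        n = int(round((duration or 1.0) * fs)) + 1
        return UniformSignal(np.zeros(n), fs=fs)
    return _superpose(beats, fs, template, (-0.28, 0.45), 0.0, duration)


def inject_artifacts(signal: UniformSignal, spec: ArtifactSpec) -> UniformSignal:
    """Corrupt a waveform with one laboratory artifact regime.

    Severity 0 returns the input unchanged.  All regimes add Gaussian
    sensor noise with SD ``0.05 * severity`` times the signal RMS on top
    of their specific disturbance.
    """
    if spec.severity == 0.0:
        return signal
    t = signal.times
    x = signal.values.copy()
    rms = float(np.sqrt(np.mean(x ** 2)))
    sev = spec.severity
    rng = np.random.default_rng(spec.seed)

    if spec.regime == "none":
        pass
    elif spec.regime == "light":
        # lighting switched every 10 s: additive square wave, 20 s period
        square = np.where((t % 20.0) < 10.0, 1.0, -1.0)
        x = x + sev * 1.5 * rms * square
    elif spec.regime == "tap":
        # finger taps: 1 s periods in the first half of the record, 2 s
        # periods in the second half.  Each tap is a sharp biphasic spike
        # followed by a short damped in-band ring -- the mechanical
        # transient disturbs the optical coupling for ~0.3 s, which is
        # what makes taps harmful to pulse detection.
        half = t[-1] / 2.0
        spikes = np.concatenate(
            [np.arange(0.5, half, 1.0), np.arange(half + 0.5, t[-1], 2.0)]
        )
        amp = sev * 3.0 * rms
        tau = np.arange(0.0, 0.35, 1.0 / signal.fs)
        kernel = amp * np.exp(-tau / 0.08) * np.cos(2 * np.pi * 2.5 * tau)
        for ts in spikes:
            k = int(round((ts - signal.t0) * signal.fs))
            hi = min(x.size, k + kernel.size)
            if 0 <= k < x.size:
                x[k:hi] += kernel[: hi - k]
    elif spec.regime == "arm":
        # hydrostatic amplitude modulation (20 s swing cycle) + slow wander
        x = x * (1.0 + sev * np.sin(2 * np.pi * t / 20.0))
        x = x + sev * 2.0 * rms * np.sin(2 * np.pi * 0.05 * t + 0.7)
    elif spec.regime == "breath":
        # mild respiratory baseline: 5 breaths/min first half, 30 second half
        half = t[-1] / 2.0
        baseline = np.where(
            t < half,
            np.sin(2 * np.pi * (5.0 / 60.0) * t),
            np.sin(2 * np.pi * 0.5 * t),
        )
        x = x + sev * 0.5 * rms * baseline
    x = x + rng.normal(0.0, 0.05 * sev * rms, size=x.size)
    return UniformSignal(x, fs=signal.fs, t0=signal.t0)
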