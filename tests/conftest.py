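import numpy as np
import pytest

from pulsechain.demodulation import hilbert_demodulate
from pulsechain.signal_model import UniformSignal
from pulsechain.synthetic import BeatProcessParams, simulate_beats, synth_ecg, synth_ppg
from pulsechain.wavelet import filter_ppg


@pytest.fixture(scope="session")
def clean_beats():
    """Deterministic 300 s beat train with LF+HF modulation (no jitter,
    so detector accuracy can be asserted at sample resolution)."""
    params = BeatProcessParams(duration=300.0, mean_hr=70.0, jitter_sd=0.0, seed=7)
    beats, rate = simulate_beats(params)
    return beats, rate


@pytest.fixture(scope="session")
def clean_ppg(clean_beats):
    beats, _ = clean_beats
    return synth_ppg(beats, fs=25.0, duration=300.0)


@pytest.fixture(scope="session")
def clean_ecg(clean_beats):
    beats, _ = clean_beats
    return synth_ecg(beats, fs=130.0, duration=300.0)


@pytest.fixture(scope="session")
def demodulated_ppg(clean_ppg):
    """Band-filtered and Hilbert-demodulated clean PPG, ready for detection."""
    return hilbert_demodulate(filter_ppg(clean_ppg))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def match_fraction(times_a, times_b, tol):
    """Fraction of beats in a that have a match in b within tol seconds."""
    times_a = np.asarray(times_a)
    times_b = np.asarray(times_b)
    if times_a.size == 0:
        return 0.0
    hits = 0
    for t in times_a:
        if np.min(np.abs(times_b - t)) <= tol:
            hits += 1
    return hits / times_a.size


@pytest.fixture(scope="session")
def tone_25hz():
    t = np.arange(0, 60, 1 / 25.0)
    return UniformSignal(np.sin(2 * np.pi * 1.2 * t), fs=25.0)
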