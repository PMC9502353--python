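import numpy as np
import pytest

from pulsechain.beat_detection import (
    SsfParams,
    ampd,
    pan_tompkins,
    pda,
    refine_peaks,
    ssf_detect,
    ssf_transform,
)
from pulsechain.signal_model import BeatTrain, UniformSignal
from pulsechain.synthetic import synth_ecg, synth_ppg
from pulsechain.wavelet import filter_ecg

from conftest import match_fraction


def _regular_ecg(duration=60.0, fs=130.0, snr_db=None, seed=0):
    beats = BeatTrain(np.arange(1.0, duration - 1.0, 1.0))
    ecg = synth_ecg(beats, fs=fs, duration=duration)
    x = ecg.values
    if snr_db is not None:
        rng = np.random.default_rng(seed)
        noise_sd = np.sqrt(np.mean(x ** 2) / 10 ** (snr_db / 10))
        x = x + rng.normal(0, noise_sd, x.size)
    return beats, UniformSignal(x, fs=fs)


class TestPanTompkins:
    def test_recovers_regular_train_exactly(self):
        truth, ecg = _regular_ecg(snr_db=20)
        detected = pan_tompkins(filter_ecg(ecg))
        assert detected.n == truth.n
        assert np.abs(detected.times - truth.times).max() <= 1.0 / ecg.fs + 1e-9

    def test_searchback_recovers_attenuated_beat(self):
        truth = BeatTrain(np.arange(1.0, 59.0, 1.0))
        ecg = synth_ecg(truth, fs=130.0, duration=60.0)
        x = ecg.values.copy()
        k = int(round(30.0 * 130))  # halve the QRS at t=30 s
        x[k - 20: k + 20] *= 0.5
        detected = pan_tompkins(filter_ecg(UniformSignal(x, fs=130.0)))
        assert match_fraction([30.0], detected.times, tol=0.05) == 1.0

    def test_noise_bounded_by_refractory_period(self, rng):
        noise = UniformSignal(rng.normal(size=int(2.5 * 130)), fs=130.0)
        detected = pan_tompkins(noise)
        assert detected.n <= int(np.ceil(2.5 / 0.2))

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            pan_tompkins(UniformSignal(np.ones(130), fs=130.0))


class TestPda:
    def test_clean_pulse_train(self, demodulated_ppg, clean_beats):
        truth, _ = clean_beats
        detected = pda(demodulated_ppg)
        # systolic peaks trail R times by the pulse-transit offset
        frac = match_fraction(truth.times + 0.25, detected.times, tol=1.5 / 25.0)
        assert frac > 0.99
        assert abs(detected.n - truth.n) <= 2

    def test_small_bump_rejected_by_gate(self):
        t = np.arange(0, 60, 1 / 25.0)
        x = np.sin(2 * np.pi * 1.0 * t)
        k = int(12.6 * 25)
        x[k] = 0.5 * 1.0  # interpolated bump at half the local maximum
        detected = pda(UniformSignal(x, fs=25.0), threshold=0.8)
        assert match_fraction([t[k]], detected.times, tol=0.02) == 0.0

    def test_monotone_signal_gives_no_peaks(self):
        detected = pda(UniformSignal(np.linspace(0, 1, 200), fs=25.0))
        assert detected.n == 0

    def test_constant_signal_gives_no_peaks(self):
        assert pda(UniformSignal(np.ones(100), fs=25.0)).n == 0


class TestAmpd:
    def test_clean_pulse_train(self, demodulated_ppg, clean_beats):
        truth, _ = clean_beats
        detected = ampd(demodulated_ppg)
        frac = match_fraction(truth.times + 0.25, detected.times, tol=1.5 / 25.0)
        assert frac > 0.99

    def test_single_triangular_pulse(self):
        x = np.zeros(200)
        x[95:106] = np.concatenate([np.linspace(0, 1, 6), np.linspace(1, 0, 6)[1:]])
        detected = ampd(UniformSignal(x, fs=25.0))
        assert detected.n == 1
        assert abs(detected.times[0] - 100 / 25.0) <= 1 / 25.0

    def test_no_adjacent_detections_on_noise(self, rng):
        x = rng.normal(size=500)
        detected = ampd(UniformSignal(x, fs=25.0))
        if detected.n > 1:
            assert np.min(np.diff(detected.times)) >= 2 / 25.0 - 1e-9


class TestSsfTransform:
    def test_decreasing_signal_is_zero(self):
        sig = UniformSignal(np.linspace(5, 0, 100), fs=25.0)
        assert np.abs(ssf_transform(sig).values).max() == 0.0

    def test_unit_step_response(self):
        x = np.zeros(50)
        x[20:] = 1.0
        out = ssf_transform(UniformSignal(x, fs=25.0), SsfParams(w=128.0)).values
        n_w = int(round(0.128 * 25))  # 3 samples
        expected = np.zeros(50)
        expected[20: 20 + n_w] = 1.0
        np.testing.assert_allclose(out, expected)

    def test_ramp_steady_state(self):
        slope = 0.4
        sig = UniformSignal(slope * np.arange(100, dtype=float), fs=25.0)
        out = ssf_transform(sig, SsfParams(w=128.0)).values
        n_w = int(round(0.128 * 25))
        np.testing.assert_allclose(out[n_w:], slope * n_w, atol=1e-12)

    def test_output_non_negative(self, rng):
        sig = UniformSignal(rng.normal(size=300), fs=25.0)
        assert ssf_transform(sig).values.min() >= 0.0


class TestSsfDetect:
    def test_clean_pulse_train(self, demodulated_ppg, clean_beats):
        truth, _ = clean_beats
        detected = ssf_detect(demodulated_ppg)
        frac = match_fraction(truth.times + 0.25, detected.times, tol=1.5 / 25.0)
        assert frac > 0.98

    def test_threshold_adapts_to_growing_amplitude(self, clean_beats):
        truth, _ = clean_beats
        ppg = synth_ppg(truth, fs=25.0, duration=300.0)
        growth = np.linspace(1.0, 2.0, ppg.n)  # amplitudes double over time
        detected = ssf_detect(UniformSignal(ppg.values * growth, fs=25.0))
        frac = match_fraction(truth.times + 0.25, detected.times, tol=1.5 / 25.0)
        assert frac > 0.98

    def test_constant_signal_gives_no_detections(self):
        sig = UniformSignal(np.ones(500), fs=25.0)
        assert ssf_detect(sig).n == 0

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            ssf_detect(UniformSignal(np.ones(50), fs=25.0))


class TestDetectorProperties:
    @pytest.mark.parametrize("detector", [pda, ampd, ssf_detect])
    def test_times_increasing_and_inside_span(self, detector, demodulated_ppg):
        beats = detector(demodulated_ppg)
        assert np.all(np.diff(beats.times) > 0)
        assert beats.times[0] >= demodulated_ppg.t0
        assert beats.times[-1] <= demodulated_ppg.times[-1] + 1e-9

    @pytest.mark.parametrize("detector", [pda, ampd, ssf_detect])
    def test_ppg_refractory_bound(self, detector, demodulated_ppg):
        beats = detector(demodulated_ppg)
        assert np.min(np.diff(beats.times)) >= 0.3 - 1e-9

    def test_ecg_refractory_bound(self):
        _, ecg = _regular_ecg(snr_db=15)
        beats = pan_tompkins(filter_ecg(ecg))
        assert np.min(np.diff(beats.times)) >= 0.2 - 1e-9

    def test_cross_detector_agreement_on_clean_data(self, demodulated_ppg):
        """On artifact-free PPG the three detectors are interchangeable."""
        sets = {d.__name__: d(demodulated_ppg).times for d in (pda, ampd, ssf_detect)}
        tol = 1.5 / 25.0  # +/- one sample
        for a in sets:
            for b in sets:
                if a < b:
                    assert match_fraction(sets[a], sets[b], tol) >= 0.99, (a, b)


class TestRefinePeaks:
    def test_reduces_quantisation_error(self, clean_beats):
        truth, _ = clean_beats
        ppg = synth_ppg(truth, fs=25.0, duration=300.0)
        coarse = pda(ppg)
        fine = refine_peaks(ppg, coarse, target_fs=1000.0)
        err_c = [np.min(np.abs(truth.times + 0.25 - t)) for t in coarse.times]
        err_f = [np.min(np.abs(truth.times + 0.25 - t)) for t in fine.times]
        assert np.mean(err_f) < np.mean(err_c)
        assert np.mean(err_f) < 0.01  # sub-sample accuracy
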