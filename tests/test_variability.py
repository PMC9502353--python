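import numpy as np
import pytest

from pulsechain.signal_model import BeatTrain, IntervalSeries, UniformVariability
from pulsechain.variability import (
    ArParams,
    ScreeningBounds,
    ar_correct,
    beats_to_intervals,
    correct_outliers_local,
    screen_physiological,
    to_uniform,
)


def _series(durations, start=0.0):
    durations = np.asarray(durations, dtype=float)
    return IntervalSeries(start + np.cumsum(durations), durations)


class TestBeatsToIntervals:
    def test_regular_beats(self):
        iv = beats_to_intervals(BeatTrain([0.0, 1.0, 2.0, 3.0]))
        np.testing.assert_allclose(iv.durations, [1, 1, 1])
        np.testing.assert_allclose(iv.anchor_times, [1, 2, 3])

    def test_irregular_beats(self):
        iv = beats_to_intervals(BeatTrain([0.0, 0.8, 1.9]))
        np.testing.assert_allclose(iv.durations, [0.8, 1.1])

    def test_single_beat_rejected(self):
        with pytest.raises(ValueError):
            beats_to_intervals(BeatTrain([1.0]))


class TestScreening:
    def test_short_interval_merged_forward(self):
        out = screen_physiological(_series([0.8, 0.1, 0.7]))
        np.testing.assert_allclose(out.durations, [0.8, 0.8])

    def test_long_interval_split_in_half(self):
        out = screen_physiological(_series([1.6]))
        np.testing.assert_allclose(out.durations, [0.8, 0.8])

    def test_valid_series_unchanged(self):
        durations = [0.8, 0.9, 1.1, 0.75]
        out = screen_physiological(_series(durations))
        np.testing.assert_allclose(out.durations, durations)
        assert not any("screen" in e for e in out.log)

    def test_trailing_short_interval_merged_backward(self):
        out = screen_physiological(_series([0.8, 0.2]))
        np.testing.assert_allclose(out.durations, [1.0])

    def test_total_duration_conserved(self, rng):
        durations = rng.uniform(0.5, 1.0, size=200)
        durations[::17] = 0.1   # spurious beats
        durations[5::31] = 2.0  # missed beats
        iv = _series(durations)
        out = screen_physiological(iv)
        assert out.total_duration == pytest.approx(iv.total_duration, abs=1e-9)

    def test_residual_out_of_bounds_logged_not_reprocessed(self):
        # a 3.4 s gap splits once into 1.7 + 1.7, both still above the
        # 1.5 s bound: the single pass leaves them and logs the residue
        out = screen_physiological(_series([0.8, 3.4, 0.8]))
        np.testing.assert_allclose(out.durations, [0.8, 1.7, 1.7, 0.8])
        assert out.total_duration == pytest.approx(5.0, abs=1e-9)
        assert any("remain out of bounds" in e for e in out.log)


class TestLocalOutlierCorrection:
    def test_isolated_spike_split(self):
        durations = np.full(50, 0.8)
        durations[25] = 2.0
        out = correct_outliers_local(_series(durations), window=25, k=3.0)
        assert out.n == 51
        np.testing.assert_allclose(out.durations[25:27], [1.0, 1.0])
        assert out.total_duration == pytest.approx(0.8 * 49 + 2.0, abs=1e-9)

    def test_clean_gaussian_series_rarely_touched(self):
        rng = np.random.default_rng(42)
        durations = rng.normal(0.8, 0.02, size=10_000)
        out = correct_outliers_local(_series(durations), window=25, k=3.0)
        corrected = sum("local-stats" in e for e in out.log)
        assert corrected / durations.size < 0.005

    def test_constant_series_unchanged(self):
        out = correct_outliers_local(_series(np.full(40, 0.8)))
        np.testing.assert_allclose(out.durations, 0.8)
        assert out.n == 40

    def test_total_duration_conserved(self, rng):
        durations = rng.uniform(0.7, 0.9, size=300)
        durations[50] = 3.0
        durations[200] = 0.05
        iv = _series(durations)
        out = correct_outliers_local(iv)
        assert out.total_duration == pytest.approx(iv.total_duration, abs=1e-9)


class TestToUniform:
    def test_constant_series_stays_constant(self):
        iv = _series(np.full(380, 0.8))  # ~300 s
        u = to_uniform(iv)
        assert u.fs_v == 1.0
        np.testing.assert_allclose(u.values, 0.8, atol=1e-6)

    def test_passband_modulation_preserved(self):
        # 0.1 Hz modulation of the durations, amplitude 0.05 s
        n = 400
        anchors = np.cumsum(np.full(n, 0.8))
        durations = 0.8 + 0.05 * np.sin(2 * np.pi * 0.1 * anchors)
        u = to_uniform(IntervalSeries(anchors, durations))
        mid = u.values[20:-20]
        amp = (mid.max() - mid.min()) / 2
        assert abs(amp - 0.05) < 0.005

    def test_cutoff_attenuation_ordering(self):
        # components straddling the 0.5 Hz cutoff: 0.45 Hz passes,
        # 0.55 Hz is attenuated at least 10x more
        n = 3000
        anchors = np.cumsum(np.full(n, 0.1))  # dense anchors, 10 Hz
        base = 1.0

        def gain(f):
            durations = base + 0.05 * np.sin(2 * np.pi * f * anchors)
            u = to_uniform(IntervalSeries(anchors, durations), out_fs=10.0)
            mid = u.values[200:-200] - base
            # amplitude of the f-component via quadrature projection
            t = u.times[200:-200]
            c = 2 * np.mean(mid * np.cos(2 * np.pi * f * t))
            s = 2 * np.mean(mid * np.sin(2 * np.pi * f * t))
            return np.hypot(c, s) / 0.05

        assert gain(0.55) < gain(0.45) / 10.0

    def test_short_span_rejected(self):
        with pytest.raises(ValueError):
            to_uniform(_series([0.5, 0.5, 0.5, 0.5]))


class TestArCorrect:
    @staticmethod
    def _ar2(n, sd, seed, mean=0.9):
        rng = np.random.default_rng(seed)
        x = np.zeros(n)
        for t in range(2, n):
            x[t] = 0.6 * x[t - 1] - 0.3 * x[t - 2] + rng.normal(0, sd)
        return mean + x

    def test_clean_ar_process_replacement_fraction(self):
        y = self._ar2(400, 0.01, seed=3)
        series = UniformVariability(y, fs_v=1.0)
        out = ar_correct(series, ArParams())
        replaced = np.count_nonzero(out.values != y)
        assert replaced / (y.size - 25) < 0.40

    def test_spikes_replaced_with_sane_predictions(self):
        sd = 0.01
        y = self._ar2(400, sd, seed=5)
        clean = y.copy()
        spike_at = [60, 130, 200, 270, 340]
        y[spike_at] += 10 * sd
        out = ar_correct(UniformVariability(y, fs_v=1.0), ArParams())
        # the one-step out-of-sample prediction error of the order-8-on-25
        # Burg fit has SD ~1.4x the innovation SD, so individual
        # replacements can land a few SD out while the ensemble stays close
        errors = []
        for i in spike_at:
            assert out.values[i] != y[i], f"spike at {i} not replaced"
            errors.append(abs(out.values[i] - clean[i]))
            assert errors[-1] < 4 * sd
        assert np.mean(errors) < 2 * sd

    def test_constant_series_passes_through(self):
        series = UniformVariability(np.full(60, 0.8), fs_v=1.0)
        out = ar_correct(series)
        np.testing.assert_array_equal(out.values, series.values)
        assert any("skipped" in e for e in out.log)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            ar_correct(UniformVariability(np.full(20, 0.8), fs_v=1.0))

    def test_order_must_fit_window(self):
        with pytest.raises(ValueError):
            ArParams(window=10, order=12)
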