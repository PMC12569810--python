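"""Evoked-potential analysis: filtering, CM/SP extraction, thresholds, DPOAE."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cochleametrics.evoked import (
    EpochSet,
    ToneResponse,
    abr_peak_latency,
    cm_component,
    dpoae_extract,
    io_function_and_threshold,
    preprocess_epochs,
    summating_potential,
    tuning_curve,
)

RATE = 100_000.0


class TestPreprocess:
    def _epochs(self, wave, n):
        return EpochSet(epochs=np.tile(wave, (n, 1)), rate=RATE,
                        stimulus_frequency=1000.0, level=80.0)

    def test_identical_epochs_average_to_filtered_single(self):
        t = np.arange(2000) / RATE
        wave = np.sin(2 * np.pi * 1000 * t)
        es = self._epochs(wave, 10)
        avg = preprocess_epochs(es)
        single = preprocess_epochs(self._epochs(wave, 1))
        np.testing.assert_allclose(avg, single, atol=1e-12)

    def test_averaging_reduces_noise_sqrt_n(self, rng):
        n, n_avg = 2000, 400
        noise = rng.normal(0, 1.0, (n_avg, n))
        es = EpochSet(epochs=noise, rate=RATE, stimulus_frequency=1000.0, level=80)
        avg = preprocess_epochs(es)
        single = preprocess_epochs(EpochSet(epochs=noise[:1], rate=RATE,
                                            stimulus_frequency=1000.0, level=80))
        # residual RMS ~ single-epoch RMS / sqrt(n_avg)
        ratio = np.std(single) / np.std(avg)
        assert ratio == pytest.approx(np.sqrt(n_avg), rel=0.3)

    def test_band_edges(self):
        t = np.arange(10000) / RATE
        in_band = np.sin(2 * np.pi * 1000 * t)
        drift = np.sin(2 * np.pi * 50 * t)
        es = self._epochs(in_band + drift, 4)
        avg = preprocess_epochs(es)
        amp_in, _ = cm_component(avg, RATE, 1000)
        amp_drift, _ = cm_component(avg, RATE, 50)
        assert amp_in > 0.95  # passband ~unity
        assert amp_drift < 0.05  # 50 Hz removed

    def test_band_outside_nyquist_rejected(self):
        es = self._epochs(np.zeros(100), 2)
        with pytest.raises(ValueError, match="Nyquist"):
            preprocess_epochs(es, band=(300.0, 60_000.0))

    def test_gain_bookkeeping(self):
        t = np.arange(2000) / RATE
        es = self._epochs(1e4 * np.sin(2 * np.pi * 1000 * t), 3)
        avg = preprocess_epochs(es, gain=1e4)
        amp, _ = cm_component(avg, RATE, 1000)
        assert amp == pytest.approx(1.0, rel=0.01)

    def test_n_average_beyond_repetitions_rejected(self):
        es = self._epochs(np.zeros(100), 5)
        with pytest.raises(ValueError, match="exceeds"):
            preprocess_epochs(es, n_average=6)


class TestThreshold:
    LEVELS = np.array([85.0, 75.0, 65.0, 55.0, 45.0, 35.0, 25.0])

    def test_interpolated_between_bracketing_levels(self):
        amps = np.array([10.0, 5.0, 2.0, 0.8, 0.4, 0.2, 0.1])
        io = io_function_and_threshold(self.LEVELS, amps, criterion=1.0)
        # crossing between 55 (0.8) and 65 (2.0): 55 + 10*(1-0.8)/1.2
        assert io.threshold == pytest.approx(55 + 10 * 0.2 / 1.2)
        assert io.threshold_reached

    def test_all_below_criterion_not_reached(self):
        io = io_function_and_threshold(self.LEVELS, np.full(7, 0.01), criterion=1.0)
        assert not io.threshold_reached and np.isnan(io.threshold)

    def test_zero_criterion_returns_lowest_level(self):
        io = io_function_and_threshold(self.LEVELS, np.linspace(10, 1, 7), criterion=0.0)
        assert io.threshold == 25.0

    def test_levels_stored_descending_as_presented(self):
        io = io_function_and_threshold(self.LEVELS[::-1], np.linspace(1, 10, 7), 0.5)
        assert np.all(np.diff(io.levels) < 0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 100), min_size=7, max_size=7),
           st.floats(0.1, 50), st.floats(0.1, 50))
    def test_threshold_monotone_in_criterion(self, amps, c1, c2):
        lo_c, hi_c = sorted((c1, c2))
        io_lo = io_function_and_threshold(self.LEVELS, np.array(amps), lo_c)
        io_hi = io_function_and_threshold(self.LEVELS, np.array(amps), hi_c)
        if io_hi.threshold_reached:
            assert io_lo.threshold_reached
            assert io_hi.threshold >= io_lo.threshold - 1e-9

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            io_function_and_threshold(np.array([]), np.array([]), 1.0)


class TestCmComponent:
    def test_pure_sine_exact(self):
        t = np.arange(5000) / RATE
        w = 50.0 * np.sin(2 * np.pi * 200 * t + 0.4)
        amp, phase = cm_component(w, RATE, 200)
        assert amp == pytest.approx(50.0, rel=1e-9)
        assert phase == pytest.approx(0.4, abs=1e-9)

    def test_phase_relative_to_drive(self):
        t = np.arange(5000) / RATE
        drive = np.sin(2 * np.pi * 200 * t)
        w = 20 * np.sin(2 * np.pi * 200 * t + 0.7)
        _, phase = cm_component(w, RATE, 200, drive_reference=drive)
        assert phase == pytest.approx(0.7, abs=1e-9)

    def test_window_shift_invariance_and_linear_phase(self):
        t = np.arange(20000) / RATE
        w = 5 * np.sin(2 * np.pi * 200 * t)
        cycle = int(RATE / 200)
        amp0, ph0 = cm_component(w, RATE, 200)
        amp1, ph1 = cm_component(w[cycle:], RATE, 200)
        assert amp1 == pytest.approx(amp0, rel=1e-9)
        assert ph1 == pytest.approx(ph0, abs=1e-9)
        # a 1/4-cycle offset shifts phase by pi/2
        _, ph2 = cm_component(w[cycle // 4:], RATE, 200)
        assert (ph2 - ph0 + np.pi) % (2 * np.pi) - np.pi == pytest.approx(np.pi / 2, abs=1e-6)

    def test_noise_bias_small(self, rng):
        t = np.arange(50000) / RATE
        sigma = 5.0
        amps = []
        for _ in range(30):
            w = 10 + 20 * np.sin(2 * np.pi * 200 * t) + rng.normal(0, sigma, t.size)
            amps.append(cm_component(w, RATE, 200)[0])
        bias = abs(np.mean(amps) - 20.0)
        assert bias < 3 * sigma / np.sqrt(t.size) * 3

    def test_exclusion_rule(self):
        t = np.arange(5000) / RATE
        w = 5.0 * np.sin(2 * np.pi * 200 * t)
        amp, phase = cm_component(w, RATE, 200, exclusion_criterion=10.0)
        assert amp == pytest.approx(5.0)
        assert np.isnan(phase)

    def test_unresolvable_frequency_rejected(self):
        with pytest.raises(ValueError, match="resolvable"):
            cm_component(np.zeros(10), RATE, 200)


class TestSummatingPotential:
    def _wave(self, dc, n_pre=1000, n_on=5000):
        t = np.arange(n_on) / RATE
        on = dc + 8 * np.sin(2 * np.pi * 200 * t)
        return np.concatenate([np.zeros(n_pre), on]), n_pre / RATE

    def test_positive_and_negative_dc(self):
        for dc in (10.0, -10.0):
            w, onset = self._wave(dc)
            sp, sp_abs = summating_potential(w, RATE, 200, (onset, len(w) / RATE))
            assert sp == pytest.approx(dc, abs=1e-9)
            assert sp_abs == pytest.approx(abs(dc))

    def test_zero_mean_periodic_is_zero(self):
        w, onset = self._wave(0.0)
        sp, _ = summating_potential(w, RATE, 200, (onset, len(w) / RATE))
        assert sp == pytest.approx(0.0, abs=1e-9)

    def test_missing_baseline_rejected(self):
        t = np.arange(5000) / RATE
        w = np.sin(2 * np.pi * 200 * t)
        with pytest.raises(ValueError, match="baseline"):
            summating_potential(w, RATE, 200, (0.0, 0.05))


class TestTuningCurve:
    def _resp(self, f, a):
        return ToneResponse(frequency=f, level=80, cm_amplitude=a, cm_phase=0.0)

    def test_programmed_peak_at_200(self):
        freqs = np.arange(60, 821, 20.0)
        amps = np.exp(-((freqs - 200) / 80.0) ** 2)
        curve, best, tie = tuning_curve([self._resp(f, a) for f, a in zip(freqs, amps)])
        assert best == 200.0 and not tie

    def test_monotone_curve_best_is_highest(self):
        rs = [self._resp(f, f) for f in (100, 200, 400, 800)]
        _, best, _ = tuning_curve(rs)
        assert best == 800

    def test_tie_resolves_to_lowest_and_flags(self):
        rs = [self._resp(100, 5), self._resp(300, 5), self._resp(200, 1)]
        _, best, tie = tuning_curve(rs)
        assert best == 100 and tie


class TestDpoae:
    F1, F2 = 1000.0, 1200.0

    def _two_tone(self, eps, n=50000):
        t = np.arange(n) / RATE
        x = np.sin(2 * np.pi * self.F1 * t) + np.sin(2 * np.pi * self.F2 * t)
        return x + eps * x**3

    def test_no_distortion_at_noise_floor(self):
        out = dpoae_extract(self._two_tone(0.0), RATE, self.F1, self.F2)
        assert out["2f1-f2"] < 1e-9
        assert out["f1"] == pytest.approx(1.0, rel=1e-9)

    def test_cubic_distortion_grows_linearly(self):
        # analytic small-eps intermodulation: amplitude(2f1-f2) = 3*eps/4
        outs = [dpoae_extract(self._two_tone(e), RATE, self.F1, self.F2)["2f1-f2"]
                for e in (0.005, 0.01, 0.02)]
        assert outs[0] == pytest.approx(3 * 0.005 / 4, rel=1e-6)
        assert outs[1] / outs[0] == pytest.approx(2.0, rel=1e-6)
        assert outs[2] / outs[1] == pytest.approx(2.0, rel=1e-6)

    def test_wrong_ratio_rejected(self):
        with pytest.raises(ValueError, match="1.2"):
            dpoae_extract(self._two_tone(0.01), RATE, 1000.0, 1500.0)


class TestLatency:
    def test_largest_peak_after_onset(self):
        w = np.zeros(1000)
        w[300] = 1.0
        w[700] = -2.0
        assert abr_peak_latency(w, 1000.0, onset=0.1) == pytest.approx(0.6)
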