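"""ROI-level steady-state analysis: detrend, transient rule, spectra, trials."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from boldwave import steady_state as ss


def _roits(data, tr=0.5, onsets=(0.0, 10.0), name="M1"):
    return ss.RoiTimeseries(np.atleast_2d(data), tr, np.asarray(onsets), name)


class TestPercentSignalChange:
    def test_constant_maps_to_zero(self):
        out = ss.percent_signal_change(np.full((3, 100), 900.0))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_linear_ramp_removed(self):
        t = np.arange(200.0)
        out = ss.percent_signal_change(1000 + 0.5 * t[None, :])
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_sinusoid_amplitude_in_percent(self):
        t = np.arange(400) * 0.5
        raw = 1000 + 10 * np.sin(2 * np.pi * 0.1 * t)
        pct = ss.percent_signal_change(raw)
        from boldwave.spectral import fundamental_amplitude
        # the slope fit absorbs a sliver of the fundamental (~0.15% here)
        assert fundamental_amplitude(pct[0], 0.5, 0.1) == pytest.approx(1.0, rel=5e-3)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ss.InputError):
            ss.percent_signal_change(np.full((1, 50), -5.0))


class TestDiscardTransient:
    def test_cut_at_trial_closest_to_65s(self):
        # 0.05 Hz: onsets 0,20,...; |60-65| < |80-65| -> cut at 60 s
        x = np.arange(480.0)
        onsets = np.arange(12) * 20.0
        trunc, kept, start = ss.discard_transient(x, 0.5, onsets, 20.0)
        assert start == 120 and kept[0] == 60.0

    def test_tie_broken_toward_earlier_onset(self):
        # 0.10 Hz: onsets ...,60,70,...; both 5 s from the mark -> keep 60 s
        x = np.arange(480.0)
        onsets = np.arange(24) * 10.0
        _, kept, start = ss.discard_transient(x, 0.5, onsets, 10.0)
        assert kept[0] == 60.0 and start == 120

    def test_lead_in_shifts_the_rule(self):
        # 20-s lead-in, 0.05 Hz: onsets 20,40,60,... -> cut at 60 s
        x = np.arange(520.0)
        onsets = 20.0 + np.arange(12) * 20.0
        _, kept, _ = ss.discard_transient(x, 0.5, onsets, 20.0)
        assert kept[0] == 60.0

    def test_integer_number_of_periods_retained(self):
        x = np.arange(487.0)  # 3.5 s of trailing partial trial
        onsets = np.arange(12) * 20.0
        trunc, _, _ = ss.discard_transient(x, 0.5, onsets, 20.0)
        assert trunc.shape[-1] % 40 == 0

    def test_too_few_trials_rejected(self):
        with pytest.raises(ss.InputError):
            ss.discard_transient(np.arange(200.0), 0.5, np.array([0.0, 80.0]), 80.0)


class TestAmplitudeSpectrum:
    def test_on_grid_sinusoid_calibration(self):
        t = np.arange(200) * 0.5
        A, f = 0.7, 0.2
        spec = ss.amplitude_spectrum(_roits(A * np.sin(2 * np.pi * f * t)))
        assert spec.value_at(f) == pytest.approx(A, rel=1e-12)
        others = spec.amplitude[np.abs(spec.freq_hz - f) > 1e-6]
        assert np.max(others) < 1e-10

    def test_two_sinusoids_recovered_independently(self):
        t = np.arange(400) * 0.5
        y = 0.4 * np.sin(2 * np.pi * 0.1 * t) + 0.15 * np.sin(2 * np.pi * 0.25 * t)
        spec = ss.amplitude_spectrum(_roits(y))
        assert spec.value_at(0.1) == pytest.approx(0.4, rel=1e-12)
        assert spec.value_at(0.25) == pytest.approx(0.15, rel=1e-12)

    def test_magnitude_average_resists_phase_cancellation(self):
        t = np.arange(200) * 0.5
        A, f = 1.0, 0.2
        v1 = A * np.sin(2 * np.pi * f * t)
        data = np.vstack([v1, -v1])  # opposite phase
        mag = ss.amplitude_spectrum(_roits(data), average="magnitude")
        cplx = ss.amplitude_spectrum(_roits(data), average="complex")
        assert mag.value_at(f) == pytest.approx(A, rel=1e-12)
        assert cplx.value_at(f) < 1e-12

    @given(st.integers(1, 9))
    def test_on_grid_bin_calibration_property(self, k):
        n, tr = 120, 0.5
        f = k / (n * tr)
        t = np.arange(n) * tr
        spec = ss.amplitude_spectrum(_roits(0.3 * np.cos(2 * np.pi * f * t)))
        assert spec.value_at(f) == pytest.approx(0.3, rel=1e-9)


class TestNormalizeSpectrum:
    def _specs(self):
        t = np.arange(400) * 0.5
        ref = ss.amplitude_spectrum(
            _roits(0.5 * np.sin(2 * np.pi * 0.05 * t), name="M1"))
        tgt = ss.amplitude_spectrum(
            _roits(0.05 * np.sin(2 * np.pi * 0.5 * t), name="M1"))
        return ref, tgt

    def test_self_normalization_is_unity(self):
        ref, _ = self._specs()
        norm = ss.normalize_spectrum(ref, ref)
        assert norm.value_at(0.05) == pytest.approx(1.0, rel=1e-12)

    def test_ratio_arithmetic(self):
        ref, tgt = self._specs()
        norm = ss.normalize_spectrum(tgt, ref)
        assert norm.value_at(0.5) == pytest.approx(0.1, rel=1e-12)
        assert norm.normalized_to == "M1 @ 0.05 Hz"

    def test_normalization_idempotent_under_unit_reference(self):
        ref, tgt = self._specs()
        norm = ss.normalize_spectrum(tgt, ref)
        unit = ss.AmplitudeSpectrum(ref.freq_hz,
                                    np.ones_like(ref.amplitude), "unit")
        again = ss.normalize_spectrum(norm, unit)
        np.testing.assert_allclose(again.amplitude, norm.amplitude, rtol=1e-12)

    def test_zero_reference_rejected(self):
        ref, tgt = self._specs()
        zero = ss.AmplitudeSpectrum(ref.freq_hz, np.zeros_like(ref.amplitude))
        with pytest.raises(ss.InputError):
            ss.normalize_spectrum(tgt, zero)


class TestNoiseFloor:
    def test_sqrt_n_rule_exact(self):
        rng = np.random.default_rng(0)
        runs = [_roits(rng.standard_normal((8, 200)))]
        floor = ss.estimate_noise_floor(runs, run_counts=(1, 4))
        np.testing.assert_allclose(floor.scaled[4], floor.single_run / 2.0,
                                   rtol=1e-15)

    def test_white_noise_closed_form(self):
        # E[per-bin amplitude] of white noise = sigma * sqrt(pi/N)
        rng = np.random.default_rng(1)
        sigma, n = 0.8, 256
        runs = [_roits(sigma * rng.standard_normal((256, n))) for _ in range(2)]
        floor = ss.estimate_noise_floor(runs)
        expected = sigma * np.sqrt(np.pi / n)
        interior = floor.single_run[1:-1]  # DC and Nyquist have other stats
        assert np.all(np.abs(interior - expected) / expected < 0.10)

    def test_record_length_scaling(self):
        # doubling the record lowers the per-bin floor by sqrt(2) (within 10%)
        rng = np.random.default_rng(2)
        f1 = ss.estimate_noise_floor([_roits(rng.standard_normal((400, 128)))])
        f2 = ss.estimate_noise_floor([_roits(rng.standard_normal((400, 256)))])
        r = f1.single_run[1:-1].mean() / f2.single_run[1:-1].mean()
        assert r == pytest.approx(np.sqrt(2), rel=0.10)

    def test_zero_noise_floor_is_zero(self):
        floor = ss.estimate_noise_floor([_roits(np.zeros((4, 100)) + 0.0)])
        assert np.max(floor.single_run[1:]) < 1e-14

    def test_empty_input_rejected(self):
        with pytest.raises(ss.InputError):
            ss.estimate_noise_floor([])


class TestTrialAverage:
    def test_noiseless_sinusoid_reproduces_one_period(self):
        t = np.arange(200) * 0.5
        f = 0.1
        y = np.sin(2 * np.pi * f * t)
        ta = ss.trial_average(_roits(y, onsets=np.arange(10) * 10.0), 10.0)
        np.testing.assert_allclose(ta.mean, y[:20], atol=1e-12)

    def test_identical_voxels_zero_ci(self):
        t = np.arange(200) * 0.5
        y = np.sin(2 * np.pi * 0.1 * t)
        data = np.tile(y, (5, 1))
        ta = ss.trial_average(_roits(data, onsets=np.arange(10) * 10.0), 10.0)
        np.testing.assert_allclose(ta.ci95, 0.0, atol=1e-12)
        assert ta.n_voxels == 5

    def test_noise_reduction_with_averaging(self):
        # trial-average RMSE shrinks roughly as 1/sqrt(n_trials * n_runs)
        rng = np.random.default_rng(3)
        t = np.arange(400) * 0.5
        truth = np.sin(2 * np.pi * 0.1 * t[:20])

        def rmse(n_runs):
            runs = []
            for _ in range(n_runs):
                y = np.tile(truth, 20) + rng.standard_normal(400)
                runs.append(_roits(y, onsets=np.arange(20) * 10.0))
            ta = ss.trial_average(runs, 10.0)
            return np.sqrt(np.mean((ta.mean - truth) ** 2))

        r1 = np.mean([rmse(1) for _ in range(20)])
        r16 = np.mean([rmse(16) for _ in range(20)])
        assert r1 / r16 == pytest.approx(4.0, rel=0.35)

    def test_non_integer_period_rejected(self):
        with pytest.raises(ss.InputError):
            ss.trial_average(_roits(np.zeros(100), onsets=(0.0, 3.3)), 3.3)


class TestPeakToPeak:
    def test_sinusoid_gives_twice_amplitude(self):
        t = np.arange(20) * 0.5
        ta = ss.TrialAverage(t, 0.3 * np.sin(2 * np.pi * 0.1 * t),
                             np.zeros(20), 1, 1)
        assert ss.peak_to_peak(ta) == pytest.approx(0.6, rel=1e-6)

    def test_constant_gives_zero(self):
        ta = ss.TrialAverage(np.arange(4.0), np.ones(4), np.zeros(4), 1, 1)
        assert ss.peak_to_peak(ta) == 0.0
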