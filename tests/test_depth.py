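"""Depth-resolved fitting, delay referencing and the cancellation statistic."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from boldwave import depth
from boldwave.steady_state import InputError


def _sinusoid_set(amps, phases, freq=0.5, tr=0.5, name="M1"):
    """DepthTrialSet of pure sinusoids over one trial period."""
    per = int(round(1.0 / freq / tr))
    t = np.arange(per) * tr
    amps = np.asarray(amps, float)
    phases = np.asarray(phases, float)
    resp = amps[:, None] * np.sin(2 * np.pi * freq * t[None, :] + phases[:, None])
    return depth.DepthTrialSet(
        time_s=t, responses=resp, n_voxels=np.ones(len(amps), int),
        stim_freq_hz=freq, roi_name=name)


class TestDepthTrialSet:
    def _pct(self, per_depth, n_trials=4, tr=0.5, period=2.0):
        per = int(period / tr)
        t = np.arange(n_trials * per) * tr
        data = np.vstack([
            a * np.sin(2 * np.pi * 0.5 * t) for a in per_depth])
        onsets = np.arange(n_trials) * period
        return data, onsets

    def test_uniform_truth_gives_identical_bins(self):
        data, onsets = self._pct([1.0, 1.0, 1.0])
        ds = depth.depth_trial_set(data, np.array([0, 1, 2]), 3, 0.5, onsets,
                                   2.0, 0.5)
        np.testing.assert_allclose(ds.responses[0], ds.responses[1], atol=1e-12)
        np.testing.assert_allclose(ds.responses[0], ds.responses[2], atol=1e-12)

    def test_single_voxel_bin_is_identity(self):
        data, onsets = self._pct([0.7, 1.3])
        ds = depth.depth_trial_set(data, np.array([0, 1]), 2, 0.5, onsets,
                                   2.0, 0.5)
        per = 4
        np.testing.assert_allclose(ds.responses[1],
                                   data[1][:per], atol=1e-12)

    def test_empty_bin_flagged_not_dropped(self):
        data, onsets = self._pct([1.0, 1.0])
        with pytest.warns(UserWarning, match="empty"):
            ds = depth.depth_trial_set(data, np.array([0, 2]), 3, 0.5, onsets,
                                       2.0, 0.5)
        assert ds.n_voxels.tolist() == [1, 0, 1]
        assert np.all(np.isnan(ds.responses[1]))

    def test_default_bin_counts(self):
        from boldwave.synth import DepthSignalSpec
        d = DepthSignalSpec()
        assert d.n_depths_s1 == 7 and d.n_depths_m1 == 15


class TestUpsample:
    def test_band_limited_sinusoid_reproduced(self):
        t4 = np.arange(4) * 0.5
        y = 0.3 * np.sin(2 * np.pi * 0.5 * t4 + 0.7)
        up = depth.upsample_trial(y, 50)
        tt = np.arange(200) * 0.01
        np.testing.assert_allclose(up, 0.3 * np.sin(2 * np.pi * 0.5 * tt + 0.7),
                                   atol=1e-9)
        np.testing.assert_allclose(up[::50], y, atol=1e-12)

    def test_factor_one_identity(self):
        y = np.array([0.0, 1.0, 0.0, -1.0])
        np.testing.assert_array_equal(depth.upsample_trial(y, 1), y)

    def test_four_sample_trial_reaches_10ms_steps(self):
        # 0.5-Hz paradigm at TR 0.5 s has 4 samples/trial; x50 -> 200 @10 ms
        assert depth.upsample_trial(np.zeros(4), 50).shape == (200,)

    def test_factor_validation(self):
        with pytest.raises(ValueError):
            depth.upsample_trial(np.zeros(4), 0)
        with pytest.raises(InputError):
            depth.upsample_trial(np.zeros(2), 50)


class TestFitSine:
    def test_exactly_determined_four_point_fit(self):
        t = np.arange(4) * 0.5
        y = 0.3 * np.sin(2 * np.pi * 0.5 * t + 1.0)
        fit = depth.fit_sine(y, t, 0.5)
        assert fit.amplitude == pytest.approx(0.3, abs=1e-9)
        # delay-signed convention: a +1.0 rad *lead* is a -1.0 rad phase
        assert fit.phase == pytest.approx(-1.0, abs=1e-9)

    def test_delayed_response_has_positive_phase_and_delay(self):
        t = np.arange(20) * 0.5
        tau = 0.8
        y = np.sin(2 * np.pi * 0.1 * (t - tau))
        fit = depth.fit_sine(y, t, 0.1)
        assert fit.phase > 0
        assert fit.delay_s == pytest.approx(tau, abs=1e-9)

    def test_constant_input_degenerate(self):
        fit = depth.fit_sine(np.full(8, 2.5), np.arange(8) * 0.5, 0.25)
        assert fit.degenerate and fit.amplitude == 0.0

    def test_phase_error_small_at_snr_10(self):
        # Monte-Carlo: phase error < 0.05 rad in >= 95% of seeded draws
        rng = np.random.default_rng(0)
        t = np.arange(40) * 0.5
        f, A, sigma = 0.1, 1.0, 0.1  # SNR 10
        ok = 0
        n_draws = 500
        for _ in range(n_draws):
            phi = rng.uniform(-np.pi, np.pi)
            y = A * np.sin(2 * np.pi * f * t + phi) + sigma * rng.standard_normal(40)
            fit = depth.fit_sine(y, t, f)
            err = abs((-phi) - fit.phase)
            err = min(err, 2 * np.pi - err)
            ok += err < 0.05
        assert ok / n_draws >= 0.95

    def test_undersampled_trial_rejected(self):
        with pytest.raises(InputError):
            depth.fit_sine(np.zeros(4), np.arange(4) * 1.0, 0.5)


class TestDelayProfile:
    def test_equal_phases_zero_delays(self):
        fits = [depth.SineFit(1.0, 0.3, 0.0, 0.0, 0.5) for _ in range(5)]
        csf = depth.SineFit(1.0, 0.3, 0.0, 0.0, 0.5)
        prof = depth.delay_profile(fits, csf, 0.5)
        np.testing.assert_allclose(prof.delay_s, 0.0, atol=1e-12)

    def test_quarter_cycle_at_half_hz_is_half_second(self):
        csf = depth.SineFit(1.0, 0.0, 0.0, 0.0, 0.5)
        fits = [depth.SineFit(1.0, np.pi / 2, 0.0, 0.0, 0.5)]
        prof = depth.delay_profile(fits, csf, 0.5)
        assert prof.delay_s[0] == pytest.approx(0.5, abs=1e-12)

    def test_unwrapping_across_the_branch_cut(self):
        # phases near +/- pi: unwrap from the CSF reference keeps the
        # profile continuous instead of jumping a full period
        truth = np.array([2.9, 3.05, 3.18, 3.38])  # WM -> pial, rad
        csf_truth = 3.48
        wrap = lambda p: (p + np.pi) % (2 * np.pi) - np.pi
        fits = [depth.SineFit(1.0, wrap(p), 0.0, 0.0, 0.5) for p in truth]
        csf = depth.SineFit(1.0, wrap(csf_truth), 0.0, 0.0, 0.5)
        prof = depth.delay_profile(fits, csf, 0.5)
        np.testing.assert_allclose(prof.phase_rad, truth - csf_truth, atol=1e-9)

    def test_degenerate_csf_rejected(self):
        csf = depth.SineFit(0.0, np.nan, 0.0, 0.0, 0.5, degenerate=True)
        with pytest.raises(InputError):
            depth.delay_profile([depth.SineFit(1.0, 0.0, 0.0, 0.0, 0.5)], csf, 0.5)


class TestCancellation:
    def test_perfect_destructive_interference(self):
        res = depth.cancellation(_sinusoid_set([1.0, 1.0], [0.0, np.pi]))
        assert res.cancellation == pytest.approx(1.0, abs=1e-12)

    def test_in_phase_no_cancellation(self):
        res = depth.cancellation(_sinusoid_set([0.5, 1.5, 2.0], [0.2, 0.2, 0.2]))
        assert res.cancellation == pytest.approx(0.0, abs=1e-12)

    def test_quarter_cycle_pair_closed_form(self):
        res = depth.cancellation(_sinusoid_set([1.0, 1.0], [0.0, np.pi / 2]))
        assert res.cancellation == pytest.approx(1 - np.cos(np.pi / 4), abs=1e-9)

    def test_two_depth_closed_form_monotone_on_grid(self):
        gaps = np.linspace(0.0, np.pi, 50)
        vals = [depth.cancellation(_sinusoid_set([1.0, 1.0], [0.0, g])).cancellation
                for g in gaps]
        np.testing.assert_allclose(vals, 1 - np.cos(gaps / 2), atol=1e-9)
        assert np.all(np.diff(vals) >= -1e-12)

    def test_frequency_monotonicity_under_fixed_delays(self):
        # fixed time-delay profile: cancellation is non-decreasing in the
        # stimulus frequency while the phase span stays below pi
        delays = np.linspace(0.0, 0.5, 15)
        amps = np.linspace(1.0, 3.0, 15)
        vals = []
        for f in (0.05, 0.10, 0.20, 1 / 3, 0.50):
            phases = 2 * np.pi * f * delays
            vals.append(depth.phasor_oracle(amps, phases).cancellation)
        assert np.all(np.diff(vals) >= 0)

    def test_zero_amplitudes_degenerate(self):
        res = depth.cancellation(_sinusoid_set([0.0, 0.0], [0.0, 1.0]))
        assert res.degenerate

    def test_ptp_convention_agrees_for_pure_sinusoids(self):
        ds = _sinusoid_set([1.0, 2.0], [0.3, 1.1])
        a = depth.cancellation(ds, f_convention="fundamental").cancellation
        b = depth.cancellation(ds, f_convention="ptp").cancellation
        # ptp reads the discrete max of the 50x-upsampled grid, so agreement
        # is limited by the 10-ms sampling of the peak, not machine precision
        assert a == pytest.approx(b, abs=1e-5)


class TestPhasorOracle:
    def test_uniform_phase_spread_approaches_full_cancellation(self):
        prev = 0.0
        for D in (4, 16, 64):
            phases = 2 * np.pi * np.arange(D) / D
            c = depth.phasor_oracle(np.ones(D), phases).cancellation
            assert c >= prev
            prev = c
        assert prev > 1 - 1e-9

    def test_single_nonzero_depth_no_interference(self):
        a = np.array([0.8, 0.0, 0.0, 0.0])
        res = depth.phasor_oracle(a, np.array([1.0, 0.0, 0.0, 0.0]))
        assert res.cancellation == pytest.approx(0.0, abs=1e-12)

    @given(st.integers(2, 12), st.integers(0, 10_000))
    def test_oracle_matches_pipeline_on_sinusoids(self, D, seed):
        rng = np.random.default_rng(seed)
        amps = rng.uniform(0.1, 3.0, D)
        phases = rng.uniform(-np.pi, np.pi, D)
        ds = _sinusoid_set(amps, phases, freq=0.2, tr=0.5)
        a = depth.cancellation(ds).cancellation
        b = depth.phasor_oracle(amps, phases).cancellation
        assert a == pytest.approx(b, abs=1e-9)
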