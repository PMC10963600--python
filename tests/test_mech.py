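"""Kinematic filtering, power/work integration, cadence, profiles."""

import numpy as np
import pytest

import exoassist as ea
from exoassist import mech

from conftest import FS


def _phase_of(x, t, freq):
    """Phase (rad) of the `freq` component of x via quadrature projection."""
    c = np.mean(x * np.cos(2 * np.pi * freq * t))
    s = np.mean(x * np.sin(2 * np.pi * freq * t))
    return np.arctan2(-s, c)


class TestZeroLagLowpass:
    def test_constant_series_unchanged(self):
        y = ea.zero_lag_lowpass(np.full(1000, 4.2), 6.0, FS)
        np.testing.assert_allclose(y, 4.2, atol=1e-9)

    def test_no_phase_shift_in_passband(self):
        t = np.arange(int(10 * FS)) / FS
        x = np.sin(2 * np.pi * 1.0 * t)
        y = ea.zero_lag_lowpass(x, 6.0, FS)
        i = slice(int(2 * FS), int(8 * FS))
        dphi = _phase_of(y[i], t[i], 1.0) - _phase_of(x[i], t[i], 1.0)
        assert abs(np.degrees(dphi)) < 0.1

    def test_stopband_attenuation(self):
        t = np.arange(int(4 * FS)) / FS
        x = np.sin(2 * np.pi * 50.0 * t)
        y = ea.zero_lag_lowpass(x, 6.0, FS)
        i = slice(int(FS), int(3 * FS))
        atten_db = 20 * np.log10(np.ptp(y[i]) / np.ptp(x[i]))
        assert atten_db < -40.0

    def test_combined_minus_3db_at_cutoff(self):
        t = np.arange(int(20 * FS)) / FS
        x = np.sin(2 * np.pi * 6.0 * t)
        y = ea.zero_lag_lowpass(x, 6.0, FS)
        i = slice(int(5 * FS), int(15 * FS))
        assert np.ptp(y[i]) / np.ptp(x[i]) == pytest.approx(2 ** -0.5, abs=0.02)

    def test_short_series_rejected(self):
        with pytest.raises(ea.DataLengthError):
            ea.zero_lag_lowpass(np.ones(20), 6.0, FS)

    def test_odd_order_rejected(self):
        with pytest.raises(ea.ParameterError):
            ea.zero_lag_lowpass(np.ones(1000), 6.0, FS, order=5)

    def test_idempotent_on_band_limited_signal(self):
        t = np.arange(int(10 * FS)) / FS
        x = np.sin(2 * np.pi * 1.5 * t)  # well inside the passband
        once = ea.zero_lag_lowpass(x, 6.0, FS)
        twice = ea.zero_lag_lowpass(once, 6.0, FS)
        i = slice(int(2 * FS), int(8 * FS))
        assert np.max(np.abs(twice[i] - once[i])) < 0.01 * np.ptp(once[i])


class TestInstantaneousPower:
    def test_sign_algebra(self):
        # extension torque during extension motion -> positive power
        p = ea.instantaneous_power(np.array([-0.135]), np.array([-1.0]),
                                   omega_unit="rad/s")
        assert p[0] == pytest.approx(0.135)

    def test_degrees_converted(self):
        p = ea.instantaneous_power(np.array([2.0]), np.array([90.0]))
        assert p[0] == pytest.approx(2.0 * np.pi / 2)

    def test_elementwise_oracle_on_gait(self, gait, src_params):
        signals, _ = gait
        cmd = ea.run_src(signals, src_params)
        p = ea.instantaneous_power(cmd.T_L, signals.omega_hip_L)
        oracle = cmd.T_L * signals.omega_hip_L * np.pi / 180.0
        np.testing.assert_allclose(p, oracle, rtol=1e-12, atol=1e-15)

    def test_unit_heuristic_warns(self):
        with pytest.warns(UserWarning, match="rad"):
            ea.instantaneous_power(np.ones(100), np.full(100, 120.0),
                                   omega_unit="rad/s")


class TestStrideWork:
    def test_rectangle(self):
        strides = [mech.StrideSegment(0.0, 1.0, 0, int(FS) + 1)]
        summary = ea.stride_work(np.ones(int(FS) + 1), FS, strides)
        assert summary.work_pos[0] == pytest.approx(1.0)
        assert summary.work_neg[0] == 0.0
        assert summary.work_net[0] == pytest.approx(1.0)

    def test_sine_over_full_period_cancels(self):
        n = int(FS) + 1
        t = np.arange(n) / FS
        power = np.sin(2 * np.pi * t)
        summary = ea.stride_work(power, FS, [mech.StrideSegment(0, 1, 0, n)])
        assert summary.work_net[0] == pytest.approx(0.0, abs=1e-6)
        assert summary.work_pos[0] == pytest.approx(summary.work_neg[0],
                                                    rel=1e-6)

    def test_decomposition_identity_per_stride(self, gait, src_params):
        signals, events = gait
        cmd = ea.run_src(signals, src_params)
        power = ea.instantaneous_power(cmd.T_L, signals.omega_hip_L)
        strides = ea.segment_strides(events.heelstrikes_L, FS, len(signals))
        summary = ea.stride_work(power, FS, strides)
        np.testing.assert_allclose(summary.work_net,
                                   summary.work_pos - summary.work_neg,
                                   rtol=1e-9, atol=1e-12)

    def test_empty_stride_list(self):
        summary = ea.stride_work(np.ones(100), FS, [])
        assert summary.n_strides == 0 and np.isnan(summary.mean_pos)

    def test_segmentation_conserves_integral(self, gait):
        signals, events = gait
        strides = ea.segment_strides(events.heelstrikes_L, FS, len(signals))
        x = signals.theta_hip_L
        dt = 1.0 / FS
        per_stride = sum(np.sum(x[s.i0:s.i1]) * dt for s in strides)
        whole = np.sum(x[strides[0].i0:strides[-1].i1]) * dt
        assert per_stride == pytest.approx(whole, rel=1e-12)


class TestCadence:
    def test_generator_ground_truth(self):
        params = ea.sinusoid_preset(stride_period=1.2)
        signals, _ = ea.generate_gait(params, 12.0)
        cadence = ea.cadence_from_grf(signals.W_l, signals.W_r, FS,
                                      params.weight)
        assert cadence == pytest.approx(100.0, abs=1.0)

    def test_doubling_stride_period_halves_cadence(self):
        c = {}
        for T in (1.0, 2.0):
            params = ea.sinusoid_preset(stride_period=T)
            signals, _ = ea.generate_gait(params, 10 * T)
            c[T] = ea.cadence_from_grf(signals.W_l, signals.W_r, FS,
                                       params.weight)
        assert c[2.0] == pytest.approx(c[1.0] / 2, rel=0.01)

    def test_zero_loads_insufficient(self):
        with pytest.raises(ea.InsufficientDataError):
            ea.cadence_from_grf(np.zeros(1000), np.zeros(1000), FS, 700.0)


class TestProfiles:
    def test_constant_profile_zero_sd(self):
        rows = mech.resample_strides(np.full(1000, 2.0),
                                     [mech.StrideSegment(0, 1, 0, 500),
                                      mech.StrideSegment(1, 2, 500, 1000)])
        mean, sd = mech.average_profile(rows)
        np.testing.assert_array_equal(mean, 2.0)
        np.testing.assert_array_equal(sd, 0.0)

    def test_two_stride_mean_and_sd_by_hand(self):
        x = np.concatenate([np.full(500, 1.0), np.full(500, 3.0)])
        rows = mech.resample_strides(x, [mech.StrideSegment(0, 1, 0, 500),
                                         mech.StrideSegment(1, 2, 500, 1000)])
        mean, sd = mech.average_profile(rows)
        np.testing.assert_allclose(mean, 2.0)
        np.testing.assert_allclose(sd, 1.0)  # population SD of {1, 3}
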