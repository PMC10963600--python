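"""Phase-portrait gait-phase estimation and the semi-trapezoidal profile."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import exoassist as ea
from exoassist.phase import TWO_PI, PhaseState, update_phase

from conftest import FS, circular_error, true_gait_fraction


class TestPhasePortrait:
    def test_sinusoid_maps_to_circle(self):
        T = 1.1
        t = np.arange(int(6 * T * FS)) / FS
        theta = 12.0 + 20.0 * np.sin(2 * np.pi * t / T)
        x, y = ea.build_phase_portrait(theta, FS, window=T)
        # after the de-mean/normalization windows have filled (~2 strides)
        r = np.hypot(x, y)[int(2.5 * T * FS):]
        assert np.all(np.abs(r - 0.5) <= 0.025)  # constant radius +/- 5%

    def test_constant_angle_is_degenerate(self):
        with pytest.raises(ea.DegeneratePortraitError):
            ea.build_phase_portrait(np.full(2000, 7.0), FS)

    def test_normalization_removes_amplitude(self):
        t = np.arange(3000) / FS
        theta = 5.0 + 10.0 * np.sin(2 * np.pi * t)
        x1, y1 = ea.build_phase_portrait(theta, FS, window=1.0)
        x2, y2 = ea.build_phase_portrait(2.0 * theta, FS, window=1.0)
        np.testing.assert_allclose(x2[600:], x1[600:], atol=1e-9)
        np.testing.assert_allclose(y2[600:], y1[600:], atol=1e-9)


class TestPhaseAngle:
    @pytest.mark.parametrize("x, y, expected", [
        (1.0, 0.0, 0.0),
        (0.0, 1.0, np.pi / 2),
        (-1.0, 0.0, np.pi),
        (0.0, -1.0, 3 * np.pi / 2),
    ])
    def test_axis_definitions(self, x, y, expected):
        assert ea.phase_angle(x, y) == pytest.approx(expected)

    def test_origin_is_degenerate(self):
        with pytest.raises(ea.DegeneratePortraitError):
            ea.phase_angle(0.0, 0.0)

    def test_sinusoid_phase_decreases_one_turn_per_stride(self):
        T = 1.1
        t = np.arange(int(8 * T * FS)) / FS
        theta = 10.0 + 20.0 * np.cos(2 * np.pi * t / T)
        x, y = ea.build_phase_portrait(theta, FS, window=T)
        phi = ea.phase_angle(x, y)
        i0, i1 = int(3 * T * FS), int(4 * T * FS)
        drop = np.unwrap(phi[i0:i1 + 1])[-1] - np.unwrap(phi[i0:i1 + 1])[0]
        assert drop == pytest.approx(-TWO_PI, rel=0.02)


class TestEstimatePgc:
    @pytest.mark.parametrize("phi, phi_hs, expected", [
        (np.pi / 2, np.pi / 2, 0.0),       # at heel-strike
        (np.pi / 4, np.pi / 2, 0.125),     # first branch
        (3 * np.pi / 2, np.pi / 2, 0.5),   # wrapped, second branch
    ])
    def test_branch_examples(self, phi, phi_hs, expected):
        assert ea.estimate_pGC(phi, phi_hs) == pytest.approx(expected)

    @given(phi=st.floats(0.0, TWO_PI, exclude_max=True),
           phi_hs=st.floats(0.0, TWO_PI, exclude_max=True))
    def test_result_in_unit_interval(self, phi, phi_hs):
        p = ea.estimate_pGC(phi, phi_hs)
        assert 0.0 <= p < 1.0


class TestUpdatePhase:
    def test_heelstrike_resets_and_reanchors(self):
        state = PhaseState(phi=1.0, phi_HS=2.0, p_GC=0.8)
        new = update_phase(state, phi=0.3, hs_event=True)
        assert new.p_GC == 0.0 and new.phi_HS == 0.3

    def test_decreasing_estimate_is_held(self):
        state = PhaseState(phi=0.0, phi_HS=np.pi, p_GC=0.40)
        # raw estimate (pi - 0.76*pi)/2pi = 0.12 < 0.40 -> held
        new = update_phase(state, phi=0.76 * np.pi, hs_event=False)
        assert new.p_GC == 0.40

    def test_increasing_estimate_passes_through(self):
        state = PhaseState(phi=0.0, phi_HS=np.pi, p_GC=0.40)
        new = update_phase(state, phi=0.1 * np.pi, hs_event=False)
        assert new.p_GC == pytest.approx(0.45)


class TestHeelStrikeDetector:
    def test_events_match_ground_truth(self, gait):
        signals, events = gait
        det = ea.detect_heelstrike(signals.omega_hip_L, signals.a_z, FS)
        truth = events.heelstrikes_L
        # one event per interior cycle, each within 30 ms of the truth
        matched = [t for t in det if np.min(np.abs(truth - t)) <= 0.030]
        assert len(matched) == len(det)
        assert len(det) >= len(truth) - 1
        assert np.all(np.diff(det) > 0.5 * 1.1)

    def test_flat_acceleration_gives_no_events(self):
        t = np.arange(2000) / FS
        omega = np.sin(2 * np.pi * t)
        assert len(ea.detect_heelstrike(omega, np.zeros(2000), FS)) == 0

    def test_refractory_merges_double_impacts(self):
        n = int(2.4 * FS)
        t = np.arange(n) / FS
        omega = 50 * np.sin(2 * np.pi * (t + 0.02) / 1.2)  # +>- crossing near t=0.58
        a_z = np.zeros(n)
        for t0 in (0.58, 0.60):  # two spikes 20 ms apart
            a_z[int(t0 * FS)] = 5.0
        cfg = ea.HeelStrikeConfig(assoc_window=0.05, init_period=1.2)
        det = ea.detect_heelstrike(omega, a_z, FS, cfg)
        assert len(det) == 1


class TestProfile:
    @pytest.mark.parametrize("p, expected", [
        (0.10, -135.0),   # extension plateau
        (0.30, 0.0),      # outside both supports
        (0.425, 33.75),   # midpoint of the flexion rise
        (0.60, 67.5),     # flexion plateau (peak time)
        (0.925, -67.5),   # midpoint of the wrapped extension rise
    ])
    def test_default_profile_values(self, p, expected):
        assert ea.hpt_profile(p, ea.HptParams()) == pytest.approx(expected)

    def test_periodicity_under_wraparound(self):
        params = ea.HptParams()
        p = np.linspace(0, 0.999, 321)
        np.testing.assert_allclose(ea.hpt_profile(p + 1.0, params),
                                   ea.hpt_profile(p, params), atol=1e-12)

    def test_sign_conventions_and_extremes(self):
        params = ea.HptParams()
        p = np.arange(0, 1, 1e-4)
        ext = params.extension_bout.evaluate(p)
        flx = params.flexion_bout.evaluate(p)
        assert np.all(ext <= 0) and np.all(flx >= 0)
        assert ext.min() == -135.0 and flx.max() == 67.5

    def test_overlapping_bouts_rejected(self):
        with pytest.raises(ea.ParameterError, match="overlap"):
            ea.HptParams(
                extension_bout=ea.BoutParams(100.0, 30.0, direction="extension"),
                flexion_bout=ea.BoutParams(50.0, 40.0, direction="flexion"))

    def test_zero_amplitude_profile_allowed(self):
        params = ea.HptParams(
            extension_bout=ea.BoutParams(0.0, 10.0, direction="extension"),
            flexion_bout=ea.BoutParams(0.0, 60.0, direction="flexion"))
        assert ea.hpt_profile(0.1, params) == 0.0


class TestRunHpt:
    def test_phase_tracking_accuracy(self, gait, hpt_params):
        signals, events = gait
        _, phases = ea.run_hpt(signals, hpt_params)
        truth = true_gait_fraction(signals.time, events.heelstrikes_L)
        mask = ((signals.time > events.heelstrikes_L[2])
                & (signals.time < events.heelstrikes_L[-1]))
        err = circular_error(phases.p_GC_L[mask], truth[mask])
        assert 100.0 * np.sqrt(np.mean(err ** 2)) < 5.0  # %GC

    def test_pgc_invariants_samplewise(self, gait, hpt_params):
        signals, _ = gait
        _, phases = ea.run_hpt(signals, hpt_params)
        p = phases.p_GC_L
        assert np.all((p >= 0.0) & (p < 1.0))
        hs_idx = np.round(phases.heelstrikes_L * FS).astype(int)
        assert np.all(p[hs_idx] == 0.0)
        between = np.diff(p)
        between[hs_idx[hs_idx > 0] - 1] = 0.0  # exclude the reset steps
        assert np.all(between >= -1e-12)

    def test_anchor_converges_on_periodic_gait(self, gait, hpt_params):
        signals, _ = gait
        _, phases = ea.run_hpt(signals, hpt_params)
        hs_idx = np.round(phases.heelstrikes_L[2:] * FS).astype(int)
        anchors = phases.phi_HS_L[hs_idx]
        assert np.ptp(anchors) < 0.02 * TWO_PI

    def test_deterministic(self, gait, hpt_params):
        signals, _ = gait
        cmd1, _ = ea.run_hpt(signals, hpt_params)
        cmd2, _ = ea.run_hpt(signals, hpt_params)
        np.testing.assert_array_equal(cmd1.T_L, cmd2.T_L)

    def test_null_profile_gives_zero_torque(self, gait):
        signals, _ = gait
        params = ea.HptParams(
            extension_bout=ea.BoutParams(0.0, 10.0, direction="extension"),
            flexion_bout=ea.BoutParams(0.0, 60.0, direction="flexion"))
        cmd, _ = ea.run_hpt(signals, params)
        np.testing.assert_array_equal(cmd.T_L, 0.0)
        np.testing.assert_array_equal(cmd.T_R, 0.0)

    def test_degenerate_input_flags_and_zeroes(self):
        n = 3000
        signals = ea.GaitSignals(
            time=np.arange(n) / FS,
            theta_hip_L=np.full(n, 5.0), theta_hip_R=np.full(n, 5.0),
            omega_hip_L=np.zeros(n), omega_hip_R=np.zeros(n),
            W_l=np.zeros(n), W_r=np.zeros(n), a_z=np.zeros(n),
            sample_rate=FS)
        with pytest.warns(UserWarning, match="degenerate"):
            cmd, phases = ea.run_hpt(signals, ea.HptParams())
        np.testing.assert_array_equal(cmd.T_L, 0.0)
        assert not np.any(phases.valid_L)
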