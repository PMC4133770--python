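import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings
from hypothesis import strategies as st

from cerebarm.control import (ExperimentConfig, IOEncodingSpec, TrajectorySpec,
                              corrective_torque, crude_command,
                              desired_trajectory, encode_io, resolve_config,
                              run_experiment, run_trial, run_trial_reference)
from cerebarm.network import WeightSet


def _no_plasticity(cfg):
    return replace(cfg, plasticity=cfg.plasticity.with_sites(
        pf_pc=False, mf_dcn=False, pc_dcn=False, io_dcn=False))


class TestDesiredTrajectory:
    def test_start_pose_is_phase_offset_sine(self):
        spec = TrajectorySpec(amplitudes=(1.0, 1.0, 1.0))
        q, qd, _ = desired_trajectory(spec, 0.0)
        assert q == pytest.approx(np.sin(np.array([1, 2, 3]) * np.pi / 4))
        assert q[0] == pytest.approx(0.7071, abs=1e-4)

    def test_endpoint_velocities_exactly_zero(self):
        spec = TrajectorySpec()
        for t in (0.0, spec.duration):
            qd = desired_trajectory(spec, t)[1]
            assert np.all(qd == 0.0)

    def test_periodic_phase_advances_by_two_pi(self):
        spec = TrajectorySpec()
        q0 = desired_trajectory(spec, 0.0)[0]
        q1 = desired_trajectory(spec, spec.duration)[0]
        assert q1 == pytest.approx(q0, abs=1e-12)

    def test_out_of_range_time_rejected(self):
        with pytest.raises(ValueError):
            desired_trajectory(TrajectorySpec(), 1.5)


class TestEncodeIO:
    SPEC = IOEncodingSpec(e_sat=0.3)

    @pytest.mark.parametrize("e,pair", [
        (0.3, (1.0, 0.0)), (0.0, (0.0, 0.0)), (-0.6, (0.0, 1.0)),
        (0.15, (0.5, 0.0)),
    ])
    def test_examples(self, e, pair):
        io = encode_io(np.array([e, 0.0, 0.0]), self.SPEC)
        assert (io[0], io[1]) == pytest.approx(pair)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(-5, 5, allow_nan=False))
    def test_at_most_one_of_pair_active(self, e):
        io = encode_io(np.array([e, e, e]), self.SPEC)
        assert np.all(io >= 0) and np.all(io <= 1)
        assert np.all(io[0::2] * io[1::2] == 0)

    def test_nonfinite_error_rejected(self):
        with pytest.raises(ValueError):
            encode_io(np.array([np.inf, 0, 0]), self.SPEC)


class TestCorrectiveTorque:
    def test_antagonist_cancellation(self):
        assert np.all(corrective_torque(np.full(6, 0.4), 10.0) == 0.0)

    def test_single_agonist_channel(self):
        dcn = np.zeros(6)
        dcn[0] = 1.0
        assert corrective_torque(dcn, 7.5)[0] == pytest.approx(7.5)

    def test_linear_in_gain(self):
        dcn = np.array([0.5, 0.1, 0.0, 0.3, 0.2, 0.0])
        assert corrective_torque(dcn, 4.0) == pytest.approx(
            2 * corrective_torque(dcn, 2.0))

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            corrective_torque(np.array([-0.1, 0, 0, 0, 0, 0]), 1.0)


class TestCrudeCommand:
    def test_rejects_model_with_payload(self, arm):
        q, qd, qdd = desired_trajectory(TrajectorySpec(), 0.3)
        with pytest.raises(ValueError):
            crude_command(arm.with_payload(2.0), q, qd, qdd)

    def test_crude_model_tracks_nominal_plant(self):
        """Spec'd sanity: no payload, no learning, the crude feedforward
        alone keeps the tracking MAE below 1e-3 rad."""
        cfg = resolve_config(_no_plasticity(ExperimentConfig(payload_kg=0.0, n_trials=1)))
        res = run_experiment(cfg, weights=WeightSet.zeros(cfg.network))
        assert res.mae[0] < 1e-3

    def test_payload_mismatch_leaves_persistent_error(self):
        cfg = resolve_config(_no_plasticity(ExperimentConfig(payload_kg=2.0, n_trials=3)))
        res = run_experiment(cfg, weights=WeightSet.zeros(cfg.network))
        assert np.all(res.mae > 0.05)
        assert res.mae[2] == res.mae[0]  # pure feedforward repeats exactly


class TestRunTrial:
    def test_weights_unchanged_when_all_sites_disabled(self, small_cfg, op_weights):
        cfg = resolve_config(_no_plasticity(small_cfg))
        plant = cfg.arm.with_payload(cfg.payload_kg)
        _, out = run_trial(cfg, op_weights, plant)
        assert np.array_equal(out.w_pf_pc, op_weights.w_pf_pc)
        assert np.array_equal(out.w_mf_dcn, op_weights.w_mf_dcn)

    def test_fused_kernel_matches_modular_reference(self, small_cfg, op_weights):
        """The numba trial loop and the pure-Python loop built from the
        public operations produce the same trajectory and weight updates."""
        cfg = resolve_config(replace(small_cfg, io_dcn_mode="adaptive"))
        plant = cfg.arm.with_payload(cfg.payload_kg)
        logk, wk = run_trial(cfg, op_weights, plant)
        logr, wr = run_trial_reference(cfg, op_weights, plant)
        assert np.abs(logk.q - logr.q).max() < 1e-7
        assert np.abs(logk.io - logr.io).max() < 1e-7
        assert logk.mae == pytest.approx(logr.mae, abs=1e-8)
        for name in ("w_pf_pc", "w_mf_dcn", "w_pc_dcn", "w_io_dcn"):
            assert np.abs(getattr(wk, name) - getattr(wr, name)).max() < 1e-7
        assert logk.contrib_io == pytest.approx(logr.contrib_io, abs=1e-6)

    def test_instability_flagged_not_raised(self, small_cfg, op_weights):
        cfg = resolve_config(replace(small_cfg, qerr_bound=1e-4))
        plant = cfg.arm.with_payload(cfg.payload_kg)
        log, _ = run_trial(cfg, op_weights, plant)
        assert log.unstable

    def test_positive_error_drives_positive_correction(self, small_cfg, op_weights):
        """Sign consistency: an IO drive on the agonist channel of joint 2
        (positive tracking error) yields positive corrective torque there."""
        cfg = resolve_config(small_cfg)
        w = op_weights.copy()
        w.w_io_dcn[:] = 1.0
        from cerebarm.network import dcn_rate, pc_rate
        io = np.zeros(6)
        io[2] = 0.5  # agonist of joint 2
        dcn = dcn_rate(w, pc_rate(w, 0), io)
        tau = corrective_torque(dcn, cfg.output_gain)
        assert tau[1] > 0
        assert tau[0] == pytest.approx(0.0)


class TestRunExperiment:
    def test_bit_identical_repetition(self, small_cfg):
        cfg = resolve_config(replace(small_cfg, n_trials=5, io_dcn_mode="adaptive"))
        r1 = run_experiment(cfg)
        r2 = run_experiment(cfg)
        assert np.array_equal(r1.mae, r2.mae)
        assert np.array_equal(r1.w_io, r2.w_io)

    def test_pure_feedforward_trials_identical(self, small_cfg):
        cfg = resolve_config(_no_plasticity(replace(small_cfg, n_trials=4)))
        res = run_experiment(cfg)
        assert np.all(res.mae == res.mae[0])

    def test_fixed_io_mode_keeps_weights_constant(self, small_cfg):
        fixed = np.full(6, 0.4)
        cfg = resolve_config(replace(small_cfg, n_trials=4, io_dcn_mode="fixed",
                                     fixed_io_weights=fixed))
        res = run_experiment(cfg)
        assert np.all(res.w_io == 0.4)

    def test_fixed_mode_requires_weights(self, small_cfg):
        cfg = resolve_config(replace(small_cfg, io_dcn_mode="fixed"))
        with pytest.raises(ValueError):
            run_experiment(cfg)

    def test_payload_schedule_switches_without_reset(self, small_cfg):
        cfg = resolve_config(replace(small_cfg, payload_schedule=((2.0, 2), (10.0, 2))))
        res = run_experiment(cfg)
        assert list(res.payload) == [2.0, 2.0, 10.0, 10.0]
        assert res.mae.size == 4


class TestSensorLatency:
    def test_proprioceptive_delay_plus_fast_modulation_winds_up(self):
        """With a 50 ms proprioceptive latency in the IO loop, a strongly
        modulated IO-DCN connection over-corrects faster than the delayed
        error can report, and the plant hits its instability bounds — the
        windup failure mode."""
        from cerebarm.metrics import LearningCurve, detect_windup
        base = resolve_config(ExperimentConfig(payload_kg=2.0,
                                               io_dcn_mode="adaptive",
                                               n_trials=60))
        cfg = replace(base,
                      io_encoding=replace(base.io_encoding, sensor_delay_steps=25),
                      plasticity=replace(base.plasticity, mt_base=100.0))
        res = run_experiment(cfg)
        flag, onset = detect_windup(LearningCurve(res.mae, unstable=res.unstable))
        assert flag
        assert res.unstable.any()


class TestCalibration:
    def test_resolved_gain_and_esat_are_positive(self, small_cfg):
        cfg = resolve_config(replace(small_cfg, output_gain=None, io_encoding=None))
        assert cfg.output_gain > 0
        assert cfg.io_encoding.e_sat > 0

    def test_explicit_values_pass_through(self, small_cfg):
        cfg = resolve_config(small_cfg)
        assert cfg.output_gain == 100.0
        assert cfg.io_encoding.e_sat == 0.5
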