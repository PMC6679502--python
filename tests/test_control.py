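import dataclasses

import numpy as np
import pytest

from lodlamp.control import (
    ControlTrace,
    ControllerConfig,
    compute_target,
    pd_step,
    run_calibration_phase,
    run_closed_loop,
    run_temperature_control,
    steady_state_mse,
)
from lodlamp.exceptions import (
    CalibrationTimeoutError,
    InvalidInputError,
    TransientNotSettledError,
)
from lodlamp.thermal import calibrate_plant
from lodlamp.tocs import intensity_from_temperature, temperature_from_intensity


def noiseless(cfg: ControllerConfig) -> ControllerConfig:
    return dataclasses.replace(cfg, noise_sd=0.0)


class TestCalibrationPhase:
    def test_noiseless_reaches_70C_plateau(self, plant, tocs_model, controller_cfg):
        cfg = noiseless(controller_cfg)
        result = run_calibration_phase(plant, tocs_model, cfg, 0)
        expected = intensity_from_temperature(70.0, "heating", tocs_model)
        assert abs(result.i_max - expected) < cfg.plateau_epsilon
        assert all(p == "calibration" for p in result.trace.phase)

    def test_zero_epsilon_with_noise_times_out(self, plant, tocs_model, controller_cfg):
        cfg = dataclasses.replace(
            controller_cfg, plateau_epsilon=0.0, calibration_timeout=120.0
        )
        with pytest.raises(CalibrationTimeoutError):
            run_calibration_phase(plant, tocs_model, cfg, 0)

    def test_doubled_capacity_same_plateau_later(self, plant, tocs_model, controller_cfg):
        cfg = noiseless(controller_cfg)
        slow_plant = dataclasses.replace(
            plant, heat_capacity=2 * plant.heat_capacity
        )
        fast = run_calibration_phase(plant, tocs_model, cfg, 0)
        slow = run_calibration_phase(slow_plant, tocs_model, cfg, 0)
        assert abs(slow.i_max - fast.i_max) < 2 * cfg.plateau_epsilon
        assert slow.elapsed > fast.elapsed


class TestTarget:
    @pytest.mark.parametrize(
        "i_max,fraction,expected",
        [(1.0, 0.5, 0.5), (0.8, 0.5, 0.4), (1.0, 0.99, 0.99)],
    )
    def test_fraction_of_maximum(self, i_max, fraction, expected):
        cfg = ControllerConfig(target_fraction=fraction)
        assert compute_target(i_max, cfg) == pytest.approx(expected)

    def test_nonpositive_maximum_rejected(self, controller_cfg):
        with pytest.raises(InvalidInputError):
            compute_target(0.0, controller_cfg)

    def test_setpoint_consistency(self, tocs_model, controller_cfg):
        # exact plateau value -> target maps back to 60 C within 0.1 C
        i_max = intensity_from_temperature(70.0, "heating", tocs_model)
        target = compute_target(i_max, controller_cfg)
        temp = temperature_from_intensity(target, "heating", tocs_model)
        assert temp == pytest.approx(60.0, abs=0.1)


class TestPDStep:
    def test_zero_error_keeps_duty(self, controller_cfg):
        assert pd_step(0.0, 0.0, 1.0, controller_cfg, 0.42) == pytest.approx(0.42)

    def test_large_error_saturates(self, controller_cfg):
        assert pd_step(10.0, 0.0, 1.0, controller_cfg, 0.5) == controller_cfg.duty_max

    def test_stated_law(self):
        cfg = ControllerConfig(kp=0.5, kd=0.0)
        assert pd_step(0.2, 0.2, 1.0, cfg, 0.3) == pytest.approx(0.4)

    def test_clipped_below(self, controller_cfg):
        assert pd_step(-10.0, 0.0, 1.0, controller_cfg, 0.5) == controller_cfg.duty_min

    def test_quantization(self):
        cfg = ControllerConfig(kp=1.0, kd=0.0, duty_quantum=0.01)
        duty = pd_step(0.123456, 0.123456, 1.0, cfg, 0.0)
        assert duty == pytest.approx(round(duty / 0.01) * 0.01)


class TestClosedLoop:
    def test_noiseless_holds_near_60(self, plant, tocs_model, controller_cfg):
        cfg = noiseless(controller_cfg)
        trace, _ = run_temperature_control(plant, tocs_model, cfg, 0,
                                           total_duration=2400.0)
        info = steady_state_mse(trace, 60.0, cfg=cfg)
        hold = np.array(
            [t for t, p in zip(trace.true_temperature, trace.phase) if p == "hold"]
        )
        times = np.array([t for t, p in zip(trace.time, trace.phase) if p == "hold"])
        settled = hold[times > info["transient_end_s"]]
        assert abs(settled.mean() - 60.0) < 0.3

    def test_zero_gains_drift_to_open_loop(self, plant, tocs_model, controller_cfg):
        cfg = dataclasses.replace(noiseless(controller_cfg), kp=0.0, kd=0.0)
        i_max = intensity_from_temperature(70.0, "heating", tocs_model)
        trace = run_closed_loop(plant, tocs_model, cfg, i_max, 0,
                                hold_duration=600.0)
        assert set(trace.duty) == {cfg.calibration_duty}
        assert trace.true_temperature[-1] > 65.0  # heading to the duty-0.5 steady state

    def test_determinism(self, plant, tocs_model, controller_cfg):
        t1, _ = run_temperature_control(plant, tocs_model, controller_cfg,
                                        np.random.default_rng(3), total_duration=900.0)
        t2, _ = run_temperature_control(plant, tocs_model, controller_cfg,
                                        np.random.default_rng(3), total_duration=900.0)
        assert t1.measured_intensity == t2.measured_intensity
        assert t1.duty == t2.duty

    def test_bounded_actuation_and_safe_band(self, plant, tocs_model, controller_cfg):
        trace, _ = run_temperature_control(plant, tocs_model, controller_cfg, 11,
                                           total_duration=2400.0)
        assert all(
            controller_cfg.duty_min <= d <= controller_cfg.duty_max
            for d in trace.duty
        )
        hold = [t for t, p in zip(trace.true_temperature, trace.phase) if p == "hold"]
        assert all(55.0 <= t <= 75.0 for t in hold)

    def test_unknown_i_max_rejected(self, plant, tocs_model, controller_cfg):
        with pytest.raises(InvalidInputError):
            run_closed_loop(plant, tocs_model, controller_cfg, 0.0, 0)


def hand_built_trace(values, phase="hold"):
    trace = ControlTrace()
    for i, v in enumerate(values):
        trace.append(float(i), 0.4, v, 0.5, v, phase)
    return trace


class TestSteadyStateMSE:
    def test_constant_at_setpoint_is_zero(self):
        trace = hand_built_trace([60.0] * 200)
        assert steady_state_mse(trace, 60.0)["mse"] == 0.0

    def test_alternating_04_gives_016(self):
        values = [60.0 + (0.4 if i % 2 else -0.4) for i in range(400)]
        trace = hand_built_trace(values)
        assert steady_state_mse(trace, 60.0)["mse"] == pytest.approx(0.16, abs=1e-9)

    def test_never_settles(self):
        trace = hand_built_trace([65.0] * 300)
        with pytest.raises(TransientNotSettledError):
            steady_state_mse(trace, 60.0)

    def test_no_hold_phase(self):
        trace = hand_built_trace([60.0] * 100, phase="calibration")
        with pytest.raises(InvalidInputError):
            steady_state_mse(trace, 60.0)

    def test_default_run_meets_reported_bound(self, plant, tocs_model, controller_cfg):
        trace, _ = run_temperature_control(plant, tocs_model, controller_cfg,
                                           np.random.default_rng(1),
                                           total_duration=2400.0)
        result = steady_state_mse(trace, 60.0, cfg=controller_cfg)
        assert result["mse"] <= 0.1677


class TestConfigValidation:
    def test_bad_duty_bounds(self):
        with pytest.raises(InvalidInputError):
            ControllerConfig(duty_min=0.5, duty_max=0.4)

    def test_bad_fraction(self):
        with pytest.raises(InvalidInputError):
            ControllerConfig(target_fraction=1.5)
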