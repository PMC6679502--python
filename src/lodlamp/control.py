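"""Two-phase PWM temperature controller.

Phase 1 (calibration): drive the laser at a fixed 1:1 duty until the sheet
intensity plateaus, and take the plateau value as the maximum intensity.
Phase 2 (hold): set the target to a fixed fraction (default 50%) of that
maximum and run PD feedback on the duty ratio, one decision per PWM period,
for the amplification hold.  A steady-state MSE of the estimated temperature
against the setpoint summarizes control quality.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    CalibrationTimeoutError,
    InvalidInputError,
    TransientNotSettledError,
)
from .thermal import PlantParams, ThermalState, step_plant
from .tocs import TOCSModel, observe, temperature_from_intensity

#: Relative margin used when clipping a noisy intensity into the invertible
#: open interval before temperature estimation.
_INVERT_MARGIN = 1e-6


@dataclass(frozen=True)
class ControllerConfig:
    """Gains, PWM timing, and detection rules for both phases.

    ``kp`` is duty per unit intensity error; ``kd`` duty*s per unit
    intensity error.  The duty law is incremental (velocity form) by
    default: each period the previous duty is the base.  ``positional=True``
    switches to the positional law around ``duty_bias``.
    """

    kp: float = 0.6
    kd: float = 1.2
    pwm_period: float = 1.0
    duty_min: float = 0.0
    duty_max: float = 1.0
    duty_quantum: float = 0.01
    hold_duration: float = 2400.0
    target_fraction: float = 0.5
    calibration_duty: float = 0.5
    plateau_window: float = 60.0
    smooth_window: float = 10.0
    plateau_epsilon: float = 0.005
    plateau_min_rise: float = 0.1
    calibration_timeout: float = 600.0
    noise_sd: float = 0.01
    settle_band: float = 0.5
    settle_window: float = 60.0
    positional: bool = False
    duty_bias: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.duty_min < self.duty_max <= 1:
            raise InvalidInputError("need 0 <= duty_min < duty_max <= 1")
        if not 0 < self.target_fraction < 1:
            raise InvalidInputError("target_fraction must be in (0, 1)")
        if self.hold_duration <= 0:
            raise InvalidInputError("hold_duration must be > 0")
        if self.pwm_period <= 0:
            raise InvalidInputError("pwm_period must be > 0")
        if self.plateau_window <= 0 or self.smooth_window <= 0:
            raise InvalidInputError("windows must be > 0")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")


@dataclass
class ControlTrace:
    """Per-PWM-period records of the simulated run."""

    time: list[float] = field(default_factory=list)
    duty: list[float] = field(default_factory=list)
    true_temperature: list[float] = field(default_factory=list)
    measured_intensity: list[float] = field(default_factory=list)
    estimated_temperature: list[float] = field(default_factory=list)
    phase: list[str] = field(default_factory=list)

    def append(
        self,
        time: float,
        duty: float,
        true_temperature: float,
        measured_intensity: float,
        estimated_temperature: float,
        phase: str,
    ) -> None:
        self.time.append(time)
        self.duty.append(duty)
        self.true_temperature.append(true_temperature)
        self.measured_intensity.append(measured_intensity)
        self.estimated_temperature.append(estimated_temperature)
        self.phase.append(phase)

    def extend(self, other: "ControlTrace") -> None:
        for name in ("time", "duty", "true_temperature", "measured_intensity",
                     "estimated_temperature", "phase"):
            getattr(self, name).extend(getattr(other, name))

    def __len__(self) -> int:
        return len(self.time)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "duty": self.duty,
                "temperature_C": self.true_temperature,
                "normalized_intensity": self.measured_intensity,
                "estimated_temperature_C": self.estimated_temperature,
                "phase": self.phase,
            }
        )


@dataclass(frozen=True)
class CalibrationResult:
    i_max: float
    trace: ControlTrace
    final_state: ThermalState
    elapsed: float


def _estimate_temperature(intensity: float, tocs: TOCSModel) -> float:
    """Invert the heating branch, clipping saturated readings to the margin.

    The closed loop stays on the heating branch: the major excursion of the
    sheet is the initial heat-up, and the small ripple around the setpoint
    does not re-trace the cooling branch.
    """
    span = tocs.i_max - tocs.i_min
    lo = tocs.i_min + _INVERT_MARGIN * span
    hi = tocs.i_max - _INVERT_MARGIN * span
    return temperature_from_intensity(min(max(intensity, lo), hi), "heating", tocs)


def _quantize_duty(duty: float, cfg: ControllerConfig) -> float:
    duty = min(max(duty, cfg.duty_min), cfg.duty_max)
    if cfg.duty_quantum > 0:
        duty = round(duty / cfg.duty_quantum) * cfg.duty_quantum
        duty = min(max(duty, cfg.duty_min), cfg.duty_max)
    return duty


def _apply_duty(
    state: ThermalState, plant: PlantParams, duty: float, period: float
) -> ThermalState:
    on_time = duty * period
    if on_time > 0:
        state = step_plant(state, plant, True, on_time)
    if period - on_time > 1e-12:
        state = step_plant(state, plant, False, period - on_time)
    return state


def run_calibration_phase(
    plant: PlantParams,
    tocs: TOCSModel,
    cfg: ControllerConfig,
    rng: np.random.Generator | int | None = None,
    initial_state: ThermalState | None = None,
) -> CalibrationResult:
    """Heat at the fixed calibration duty until the intensity plateaus.

    Readings (one per PWM period) are smoothed with a trailing moving
    average over ``smooth_window``; once the smoothed intensity has risen by
    at least ``plateau_min_rise`` from its starting value, the plateau is
    declared when it changes by less than ``plateau_epsilon`` over the
    trailing ``plateau_window``.  The smoothed value at that instant — the
    mean over the final smoothing window — is returned as ``i_max``.

    Raises
    ------
    CalibrationTimeoutError
        If no plateau is found within ``calibration_timeout`` seconds.
    """
    generator = (
        rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    )
    state = initial_state or ThermalState(time=0.0, temperature=plant.ambient_temp)
    t0 = state.time
    trace = ControlTrace()
    duty = _quantize_duty(cfg.calibration_duty, cfg)

    n_smooth = max(1, int(round(cfg.smooth_window / cfg.pwm_period)))
    lag = int(round(cfg.plateau_window / cfg.pwm_period))
    recent = deque(maxlen=n_smooth)
    smoothed: list[float] = []

    max_periods = int(math.ceil(cfg.calibration_timeout / cfg.pwm_period))
    for _ in range(max_periods):
        state = _apply_duty(state, plant, duty, cfg.pwm_period)
        reading = observe(
            state.temperature, "heating", tocs, cfg.noise_sd, generator, state.time
        )
        intensity = reading.normalized_intensity
        recent.append(intensity)
        s = sum(recent) / len(recent)
        smoothed.append(s)
        trace.append(
            state.time,
            duty,
            state.temperature,
            intensity,
            _estimate_temperature(intensity, tocs),
            "calibration",
        )
        # "until the color no longer changed": the signal must have visibly
        # changed first, or the flat pre-transition region triggers a false
        # plateau on slow plants.
        risen = s - smoothed[0] >= cfg.plateau_min_rise
        if risen and len(smoothed) > lag and len(recent) == n_smooth:
            if abs(s - smoothed[-1 - lag]) < cfg.plateau_epsilon:
                return CalibrationResult(
                    i_max=s,
                    trace=trace,
                    final_state=state,
                    elapsed=state.time - t0,
                )
    raise CalibrationTimeoutError(
        f"intensity plateau not reached within {cfg.calibration_timeout} s"
    )


def compute_target(i_max: float, cfg: ControllerConfig) -> float:
    """Target intensity: ``target_fraction`` of the plateau maximum."""
    if i_max <= 0:
        raise InvalidInputError("i_max must be > 0")
    return cfg.target_fraction * i_max


def pd_step(
    error: float,
    prev_error: float,
    dt: float,
    cfg: ControllerConfig,
    prev_duty: float,
) -> float:
    """One PD duty decision.

    Velocity form (default): duty = prev_duty + kp*e + kd*(e - e_prev)/dt.
    Positional form: duty = duty_bias + kp*e + kd*(e - e_prev)/dt.
    The result is clipped to [duty_min, duty_max] and quantized; clipping is
    defined behavior, not an error.
    """
    if dt <= 0:
        raise InvalidInputError("dt must be > 0")
    base = cfg.duty_bias if cfg.positional else prev_duty
    duty = base + cfg.kp * error + cfg.kd * (error - prev_error) / dt
    return _quantize_duty(duty, cfg)


def run_closed_loop(
    plant: PlantParams,
    tocs: TOCSModel,
    cfg: ControllerConfig,
    i_max: float,
    rng: np.random.Generator | int | None = None,
    initial_state: ThermalState | None = None,
    hold_duration: float | None = None,
) -> ControlTrace:
    """PD hold phase: one duty decision per PWM period for the hold duration."""
    if i_max <= 0:
        raise InvalidInputError("i_max must be > 0 (run calibration first)")
    generator = (
        rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    )
    state = initial_state or ThermalState(time=0.0, temperature=plant.ambient_temp)
    duration = cfg.hold_duration if hold_duration is None else hold_duration
    if duration <= 0:
        raise InvalidInputError("hold duration must be > 0")
    target = compute_target(i_max, cfg)
    trace = ControlTrace()
    duty = _quantize_duty(cfg.calibration_duty, cfg)
    reading = observe(
        state.temperature, "heating", tocs, cfg.noise_sd, generator, state.time
    )
    prev_error = target - reading.normalized_intensity
    n_periods = int(round(duration / cfg.pwm_period))
    for _ in range(n_periods):
        state = _apply_duty(state, plant, duty, cfg.pwm_period)
        reading = observe(
            state.temperature, "heating", tocs, cfg.noise_sd, generator, state.time
        )
        intensity = reading.normalized_intensity
        trace.append(
            state.time,
            duty,
            state.temperature,
            intensity,
            _estimate_temperature(intensity, tocs),
            "hold",
        )
        error = target - intensity
        duty = pd_step(error, prev_error, cfg.pwm_period, cfg, duty)
        prev_error = error
    return trace


def run_temperature_control(
    plant: PlantParams,
    tocs: TOCSModel,
    cfg: ControllerConfig,
    rng: np.random.Generator | int | None = None,
    total_duration: float | None = None,
) -> tuple[ControlTrace, dict]:
    """Full two-phase run: calibration then PD hold, one continuous trace.

    If ``total_duration`` is given, the hold is shortened so that
    calibration + hold together fill it (the protocol's heating step budget
    includes the calibration phase by default).
    """
    generator = (
        rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    )
    calib = run_calibration_phase(plant, tocs, cfg, generator)
    hold = cfg.hold_duration
    if total_duration is not None:
        hold = total_duration - calib.elapsed
        if hold <= 0:
            raise InvalidInputError(
                "calibration consumed the whole heating budget"
            )
    trace = calib.trace
    hold_trace = run_closed_loop(
        plant, tocs, cfg, calib.i_max, generator,
        initial_state=calib.final_state, hold_duration=hold,
    )
    trace.extend(hold_trace)
    info = {
        "i_max": calib.i_max,
        "target_intensity": compute_target(calib.i_max, cfg),
        "calibration_time_s": calib.elapsed,
        "hold_duration_s": hold,
    }
    return trace, info


def steady_state_mse(
    trace: ControlTrace,
    setpoint: float = 60.0,
    band: float | None = None,
    sustain_window: float | None = None,
    cfg: ControllerConfig | None = None,
) -> dict:
    """Steady-state MSE (degC^2) of estimated temperature against setpoint.

    The transient ends at the close of the first window of ``sustain_window``
    seconds during which |estimated - setpoint| <= band throughout; the MSE
    is the mean squared error over the remaining hold-phase samples.

    Returns a dict with ``mse``, ``transient_end_s`` and ``n_samples``.

    Raises
    ------
    TransientNotSettledError
        If no such window exists in the hold phase.
    InvalidInputError
        If the trace has no hold phase.
    """
    if cfg is None:
        cfg = ControllerConfig()
    band = cfg.settle_band if band is None else band
    sustain_window = cfg.settle_window if sustain_window is None else sustain_window

    idx = [i for i, p in enumerate(trace.phase) if p == "hold"]
    if not idx:
        raise InvalidInputError("trace contains no hold phase")
    times = np.asarray(trace.time, dtype=float)[idx]
    est = np.asarray(trace.estimated_temperature, dtype=float)[idx]
    in_band = np.abs(est - setpoint) <= band

    settle_end: int | None = None
    run_start = None
    for i, ok in enumerate(in_band):
        if ok:
            if run_start is None:
                run_start = i
            if times[i] - times[run_start] >= sustain_window:
                settle_end = i
                break
        else:
            run_start = None
    if settle_end is None:
        raise TransientNotSettledError(
            f"|estimate - {setpoint}| <= {band} never sustained {sustain_window} s"
        )
    tail = est[settle_end + 1 :]
    if tail.size == 0:
        raise TransientNotSettledError("no samples remain after the transient")
    mse = float(np.mean((tail - setpoint) ** 2))
    return {
        "mse": mse,
        "transient_end_s": float(times[settle_end]),
        "n_samples": int(tail.size),
    }
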