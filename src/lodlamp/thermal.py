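"""First-order lumped-capacitance model of the laser-heated amplification chamber.

The chamber is treated as a single well-mixed thermal node (the graphite
absorber film conducts far faster than the chamber loses heat), heated by an
on/off laser and passively cooled to ambient:

    C * dT/dt = P * 1[laser on] - k * (T - T_ambient)

The model is deliberately linear so a closed-form solution exists for any
constant input, which the test suite uses as an independent oracle for the
fixed-step integrator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import CalibrationError, InvalidInputError, SimulationError

#: Integrator sub-step ceiling (s).  Small enough that each 0.5 s PWM
#: half-period is resolved by >= 10 steps and Euler error stays far below
#: sensor noise.
MAX_SUBSTEP_S = 0.05


@dataclass(frozen=True)
class PlantParams:
    """Lumped thermal parameters of the amplification chamber.

    Attributes
    ----------
    ambient_temp:
        Ambient temperature (degC) the chamber relaxes to with the laser off.
    heat_capacity:
        Lumped heat capacity C (J/degC).
    loss_coeff:
        Heat-loss coefficient k (W/degC).
    absorbed_power:
        Laser power absorbed by the graphite film when the beam is on (W).
    duty_steady_70:
        Duty ratio whose time-averaged steady state is the calibration
        anchor temperature (dimensionless, default 0.5).
    """

    ambient_temp: float
    heat_capacity: float
    loss_coeff: float
    absorbed_power: float
    duty_steady_70: float = 0.5

    def __post_init__(self) -> None:
        if not all(
            math.isfinite(v)
            for v in (
                self.ambient_temp,
                self.heat_capacity,
                self.loss_coeff,
                self.absorbed_power,
                self.duty_steady_70,
            )
        ):
            raise InvalidInputError("plant parameters must be finite")
        if self.heat_capacity <= 0:
            raise InvalidInputError("heat_capacity must be > 0")
        if self.loss_coeff <= 0:
            raise InvalidInputError("loss_coeff must be > 0")
        if self.absorbed_power <= 0:
            raise InvalidInputError("absorbed_power must be > 0")
        if not 0 < self.duty_steady_70 <= 1:
            raise InvalidInputError("duty_steady_70 must be in (0, 1]")

    @property
    def time_constant(self) -> float:
        """Exponential time constant C / k (s)."""
        return self.heat_capacity / self.loss_coeff

    def steady_state_temperature(self, duty: float) -> float:
        """Time-averaged steady-state temperature at a constant duty ratio."""
        return self.ambient_temp + duty * self.absorbed_power / self.loss_coeff


@dataclass(frozen=True)
class ThermalState:
    """Instantaneous chamber state: simulation time (s) and temperature (degC)."""

    time: float
    temperature: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.time) and math.isfinite(self.temperature)):
            raise InvalidInputError("thermal state must be finite")


def step_plant(
    state: ThermalState, params: PlantParams, laser_on: bool, dt: float
) -> ThermalState:
    """Advance the chamber by ``dt`` seconds with the laser held on or off.

    Integrates the node ODE with fixed-step explicit Euler, internally
    sub-stepping so no step exceeds :data:`MAX_SUBSTEP_S`.

    Raises
    ------
    InvalidInputError
        If ``dt`` is not a positive finite number or the state is invalid.
    SimulationError
        If the integration produces a non-finite temperature.
    """
    if not math.isfinite(dt) or dt <= 0:
        raise InvalidInputError(f"dt must be positive and finite, got {dt!r}")
    n_sub = max(1, math.ceil(dt / MAX_SUBSTEP_S))
    h = dt / n_sub
    power = params.absorbed_power if laser_on else 0.0
    temp = state.temperature
    inv_c = 1.0 / params.heat_capacity
    for _ in range(n_sub):
        temp += h * (power - params.loss_coeff * (temp - params.ambient_temp)) * inv_c
    if not math.isfinite(temp):
        raise SimulationError("plant temperature diverged to a non-finite value")
    return ThermalState(time=state.time + dt, temperature=temp)


def calibrate_plant(
    t_amb: float,
    t_steady_at_half_duty: float,
    time_constant: float,
    anchor_duty: float = 0.5,
) -> PlantParams:
    """Back out plant parameters from the duty-0.5 steady-state anchor.

    Chooses P, k, C so that the time-averaged steady state at
    ``anchor_duty`` equals ``t_steady_at_half_duty`` and C/k equals
    ``time_constant``.  Only the ratios P/k and C/k are observable, so k is
    fixed at 1 W/degC.
    """
    if not 0 < anchor_duty <= 1:
        raise InvalidInputError("anchor_duty must be in (0, 1]")
    if time_constant <= 0:
        raise CalibrationError("time_constant must be > 0")
    if t_steady_at_half_duty <= t_amb:
        raise CalibrationError(
            "steady-state anchor must exceed ambient (no heating implies P = 0)"
        )
    loss_coeff = 1.0
    absorbed_power = loss_coeff * (t_steady_at_half_duty - t_amb) / anchor_duty
    heat_capacity = time_constant * loss_coeff
    return PlantParams(
        ambient_temp=t_amb,
        heat_capacity=heat_capacity,
        loss_coeff=loss_coeff,
        absorbed_power=absorbed_power,
        duty_steady_70=anchor_duty,
    )


def simulate_pwm(
    params: PlantParams,
    duty: float,
    duration: float,
    pwm_period: float = 1.0,
    initial_state: ThermalState | None = None,
) -> list[ThermalState]:
    """Open-loop PWM drive at a fixed duty ratio.

    Each period the laser is on for ``duty * pwm_period`` seconds then off
    for the remainder, so intra-period temperature ripple is retained.
    Returns the state at every period boundary (including the initial state).
    """
    if not 0 <= duty <= 1:
        raise InvalidInputError("duty must be in [0, 1]")
    if duration <= 0 or pwm_period <= 0:
        raise InvalidInputError("duration and pwm_period must be > 0")
    state = initial_state or ThermalState(time=0.0, temperature=params.ambient_temp)
    states = [state]
    n_periods = int(round(duration / pwm_period))
    on_time = duty * pwm_period
    off_time = pwm_period - on_time
    for _ in range(n_periods):
        if on_time > 0:
            state = step_plant(state, params, True, on_time)
        if off_time > 0:
            state = step_plant(state, params, False, off_time)
        states.append(state)
    return states


def pwm_time_average(
    params: PlantParams,
    duty: float,
    duration: float,
    average_window: float,
    pwm_period: float = 1.0,
    sample_dt: float = MAX_SUBSTEP_S,
) -> float:
    """Time-averaged temperature over the final ``average_window`` seconds
    of an open-loop PWM drive, sampled densely (every ``sample_dt``) so the
    intra-period ripple averages out rather than being aliased at period
    boundaries."""
    if average_window <= 0 or average_window > duration:
        raise InvalidInputError("average_window must be in (0, duration]")
    state = ThermalState(time=0.0, temperature=params.ambient_temp)
    on_time = duty * pwm_period
    n_periods = int(round(duration / pwm_period))
    acc = 0.0
    n_acc = 0
    t_start_avg = duration - average_window
    for _ in range(n_periods):
        period_start = state.time
        elapsed = 0.0
        while elapsed < pwm_period - 1e-12:
            laser_on = elapsed < on_time - 1e-12
            boundary = on_time if laser_on else pwm_period
            h = min(sample_dt, boundary - elapsed)
            state = step_plant(state, params, laser_on, h)
            elapsed = state.time - period_start
            if state.time > t_start_avg:
                acc += state.temperature
                n_acc += 1
    if n_acc == 0:
        raise SimulationError("no samples fell inside the averaging window")
    return acc / n_acc
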