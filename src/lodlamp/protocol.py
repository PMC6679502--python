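"""Disc driving sequence: a validated state machine over the printed protocol.

The default protocol is the seven-step disc sequence: inject the sample,
spin it into the channel, laser-open the LB valve, spin residual reagent to
waste, laser-melt the EVA sealing valve, spin at high speed to push the melt
radially, then laser-heat the amplification chamber at the adjusted duty
ratio for 40 minutes.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Callable

import pandas as pd

from .exceptions import InvalidInputError


class Operation(str, Enum):
    SAMPLE_INJECTION = "sample_injection"
    SPIN = "spin"
    LASER_VALVE_LB = "laser_valve_LB"
    LASER_VALVE_EVA = "laser_valve_EVA"
    LASER_HEATING = "laser_heating"


_LASER_OPS = {Operation.LASER_VALVE_LB, Operation.LASER_VALVE_EVA, Operation.LASER_HEATING}


@dataclass(frozen=True)
class ProtocolStep:
    """One row of the driving sequence."""

    index: int
    operation: Operation
    description: str = ""
    spin_speed: float | None = None  # rpm
    duration: float | None = None  # s

    def effective_duration(self) -> float:
        return self.duration if self.duration is not None else 0.0


@dataclass(frozen=True)
class ProtocolEvent:
    step_index: int
    operation: Operation
    start_s: float
    end_s: float
    spin_speed: float | None


@dataclass(frozen=True)
class ProtocolRun:
    events: tuple[ProtocolEvent, ...]
    total_duration: float
    heating_info: dict | None = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "step_index": e.step_index,
                    "operation": e.operation.value,
                    "start_s": e.start_s,
                    "end_s": e.end_s,
                    "rpm": e.spin_speed,
                }
                for e in self.events
            ]
        )


@dataclass(frozen=True)
class ValidationReport:
    violations: tuple[str, ...]

    @property
    def is_valid(self) -> bool:
        return not self.violations


def default_protocol() -> list[ProtocolStep]:
    """The seven printed steps, verbatim."""
    return [
        ProtocolStep(1, Operation.SAMPLE_INJECTION, "Sample injection"),
        ProtocolStep(2, Operation.SPIN, "Spin out to move samples in the channel",
                     spin_speed=3000, duration=30),
        ProtocolStep(3, Operation.LASER_VALVE_LB, "Irradiate laser to LB valve",
                     duration=10),
        ProtocolStep(4, Operation.SPIN, "Spin out the residual to waste chamber",
                     spin_speed=3000, duration=10),
        ProtocolStep(5, Operation.LASER_VALVE_EVA, "Irradiate laser to melting EVA valve",
                     duration=60),
        ProtocolStep(6, Operation.SPIN, "Spin out to push the melted EVA valve in radial way",
                     spin_speed=10_000, duration=60),
        ProtocolStep(7, Operation.LASER_HEATING,
                     "Irradiate laser to amplification chamber in adjusted duty ratio",
                     duration=2400),
    ]


def validate_protocol(steps: list[ProtocolStep]) -> ValidationReport:
    """Check per-step invariants and inter-step ordering rules.

    Ordering rules: EVA sealing (EVA melt followed by a spin) must precede
    laser heating — the melt must be spun radially to block the channel
    before the chamber is heated — and LB valve opening must precede a
    subsequent metering spin.  Violations are reported, not raised.
    """
    violations: list[str] = []
    prev_index: int | None = None
    for step in steps:
        if prev_index is not None and step.index <= prev_index:
            violations.append(
                f"step indices not strictly increasing at step {step.index}"
            )
        prev_index = step.index
        if step.operation is Operation.SPIN:
            if step.spin_speed is None or step.spin_speed <= 0:
                violations.append(f"spin step {step.index} needs spin_speed > 0")
        if step.operation in _LASER_OPS:
            if step.duration is None or step.duration <= 0:
                violations.append(f"laser step {step.index} needs duration > 0")

    def positions(op: Operation) -> list[int]:
        return [i for i, s in enumerate(steps) if s.operation is op]

    heating = positions(Operation.LASER_HEATING)
    eva = positions(Operation.LASER_VALVE_EVA)
    lb = positions(Operation.LASER_VALVE_LB)
    spins = positions(Operation.SPIN)

    if heating:
        h = heating[0]
        sealed = any(
            e < s < h for e in eva for s in spins
        )
        if eva and not sealed:
            violations.append(
                "EVA sealing (EVA melt then spin) must precede laser heating"
            )
        if not eva:
            violations.append("laser heating requires a prior EVA sealing step")
    if lb:
        if not any(s > lb[0] for s in spins):
            violations.append("LB valve opening must precede a metering spin")
    return ValidationReport(tuple(violations))


def simulate_protocol(
    steps: list[ProtocolStep],
    heating_hook: Callable[[float], dict] | None = None,
) -> ProtocolRun:
    """Execute steps sequentially, emitting a timestamped event log.

    ``heating_hook(duration)`` is called for laser-heating steps and may run
    the temperature controller inside the step's printed time budget; its
    returned info dict is attached to the run.  Without hooks the schedule is
    conserved exactly: total_duration equals the sum of declared durations.

    Raises
    ------
    InvalidInputError
        If the steps fail validation.
    """
    report = validate_protocol(steps)
    if not report.is_valid:
        raise InvalidInputError(
            "invalid protocol: " + "; ".join(report.violations)
        )
    t = 0.0
    events: list[ProtocolEvent] = []
    heating_info: dict | None = None
    for step in steps:
        duration = step.effective_duration()
        if step.operation is Operation.LASER_HEATING and heating_hook is not None:
            try:
                heating_info = heating_hook(duration)
            except Exception as exc:
                raise type(exc)(
                    f"step {step.index} ({step.operation.value}): {exc}"
                ) from exc
        events.append(
            ProtocolEvent(step.index, step.operation, t, t + duration, step.spin_speed)
        )
        t += duration
    return ProtocolRun(tuple(events), total_duration=t, heating_info=heating_info)
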