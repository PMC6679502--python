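"""Exception hierarchy shared across the package."""


class LodLampError(Exception):
    """Base class for all package errors."""


class InvalidInputError(LodLampError, ValueError):
    """An argument violates a documented precondition."""


class CalibrationError(LodLampError):
    """Plant calibration constraints are infeasible."""


class CalibrationTimeoutError(LodLampError):
    """The sensor-intensity plateau was not reached within the timeout."""


class OutOfRangeError(LodLampError, ValueError):
    """A value lies outside the invertible range of a curve."""


class TransientNotSettledError(LodLampError):
    """The control trace never satisfied the settling rule."""


class SimulationError(LodLampError):
    """The simulated plant produced a non-finite state."""


class NotFittedError(LodLampError, RuntimeError):
    """A model was used before being trained."""
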