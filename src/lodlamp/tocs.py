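"""Thermochromic-sheet (TOCS) optical sensor model.

Maps chamber temperature to the camera-observed normalized intensity and
back.  The sheet brightens with temperature along a logistic S-curve; the
heating and cooling branches share shape but are offset in temperature
(hysteresis), so the branch must be supplied explicitly.  Raw camera
readings are normalized by a per-disc reference intensity ``r_init`` to
absorb chamber-fabrication variation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.special import expit, logit

from .exceptions import InvalidInputError, OutOfRangeError

Branch = Literal["heating", "cooling"]

_BRANCHES = ("heating", "cooling")


@dataclass(frozen=True)
class TOCSModel:
    """Parametric intensity-vs-temperature curves with hysteresis.

    ``t50_heating`` / ``t50_cooling`` are the temperatures at which each
    branch crosses 50% of its dynamic range; the heating branch crosses at
    60 degC under the default configuration (the amplification setpoint).
    """

    t50_heating: float = 60.0
    t50_cooling: float = 57.0
    slope_width: float = 2.5
    i_min: float = 0.0
    i_max: float = 1.0
    r_init: float = 200.0

    def __post_init__(self) -> None:
        if self.t50_cooling >= self.t50_heating:
            raise InvalidInputError(
                "hysteresis requires t50_cooling < t50_heating"
            )
        if self.slope_width <= 0:
            raise InvalidInputError("slope_width must be > 0")
        if not 0 <= self.i_min < self.i_max:
            raise InvalidInputError("need 0 <= i_min < i_max")
        if self.r_init <= 0:
            raise InvalidInputError("r_init must be > 0")

    def t50(self, branch: Branch) -> float:
        if branch not in _BRANCHES:
            raise InvalidInputError(f"unknown branch {branch!r}")
        return self.t50_heating if branch == "heating" else self.t50_cooling


@dataclass(frozen=True)
class SensorReading:
    """One camera observation of the sheet."""

    time: float
    raw_intensity: float
    normalized_intensity: float
    branch: Branch


def intensity_from_temperature(temp: float, branch: Branch, model: TOCSModel) -> float:
    """Normalized intensity at ``temp`` on the selected branch.

    Logistic in temperature: crosses the midpoint of [i_min, i_max] exactly
    at the branch's t50 and is strictly increasing everywhere.
    """
    t50 = model.t50(branch)
    x = (temp - t50) / model.slope_width
    return model.i_min + (model.i_max - model.i_min) * float(expit(x))


def temperature_from_intensity(
    intensity: float, branch: Branch, model: TOCSModel
) -> float:
    """Invert :func:`intensity_from_temperature` on the same branch.

    Raises
    ------
    OutOfRangeError
        If ``intensity`` is outside the open interval (i_min, i_max); the
        asymptotes are never attained so saturated readings cannot be
        inverted.
    """
    t50 = model.t50(branch)
    if not model.i_min < intensity < model.i_max:
        raise OutOfRangeError(
            f"intensity {intensity!r} outside invertible range "
            f"({model.i_min}, {model.i_max})"
        )
    frac = (intensity - model.i_min) / (model.i_max - model.i_min)
    return t50 + model.slope_width * float(logit(frac))


def normalize_reading(raw: float, r_init: float) -> float:
    """Scale a raw camera intensity by the per-disc reference ``r_init``.

    Values above 1 are permitted: the reference is the disc's own initial
    intensity, which individual chambers may exceed.
    """
    if r_init <= 0:
        raise InvalidInputError("r_init must be > 0")
    return raw / r_init


def observe(
    temp: float,
    branch: Branch,
    model: TOCSModel,
    noise_sd: float = 0.01,
    rng: np.random.Generator | int | None = None,
    time: float = 0.0,
) -> SensorReading:
    """Simulate one noisy camera reading of the sheet at ``temp``.

    Additive zero-mean Gaussian noise of standard deviation ``noise_sd`` on
    the normalized intensity, clipped to [0, i_max + 5 * noise_sd].
    Deterministic when ``rng`` is a seed or a seeded generator.
    """
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be >= 0")
    clean = intensity_from_temperature(temp, branch, model)
    if noise_sd > 0:
        generator = (
            rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        )
        noisy = clean + generator.normal(0.0, noise_sd)
        noisy = min(max(noisy, 0.0), model.i_max + 5.0 * noise_sd)
    else:
        noisy = clean
    if not math.isfinite(noisy):
        raise InvalidInputError("non-finite sensor reading")
    return SensorReading(
        time=time,
        raw_intensity=noisy * model.r_init,
        normalized_intensity=noisy,
        branch=branch,
    )
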