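"""Run configuration: nested per-module blocks loadable from YAML."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .control import ControllerConfig
from .exceptions import InvalidInputError
from .imaging import ColorModel
from .tocs import TOCSModel


@dataclass(frozen=True)
class PlantCalibration:
    """Anchors handed to plant calibration (none are printed; all exposed)."""

    ambient_temp: float = 25.0
    steady_at_half_duty: float = 70.0
    time_constant: float = 60.0


@dataclass(frozen=True)
class ImagingConfig:
    n_train: int = 100
    n_test: int = 30
    color_model: ColorModel = field(default_factory=ColorModel)


@dataclass(frozen=True)
class RunConfig:
    plant: PlantCalibration = field(default_factory=PlantCalibration)
    tocs: TOCSModel = field(default_factory=TOCSModel)
    controller: ControllerConfig = field(default_factory=ControllerConfig)
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    setpoint: float = 60.0
    include_calibration_in_heating: bool = True


def _build(cls, block: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - names
    if unknown:
        raise InvalidInputError(f"unknown keys in {path}: {sorted(unknown)}")
    return cls(**block)


def run_config_from_dict(data: dict | None) -> RunConfig:
    """Build a RunConfig from a nested mapping, validating every block."""
    data = dict(data or {})
    kwargs: dict = {}
    if "plant" in data:
        kwargs["plant"] = _build(PlantCalibration, data.pop("plant"), "plant")
    if "tocs" in data:
        kwargs["tocs"] = _build(TOCSModel, data.pop("tocs"), "tocs")
    if "controller" in data:
        kwargs["controller"] = _build(
            ControllerConfig, data.pop("controller"), "controller"
        )
    if "imaging" in data:
        block = dict(data.pop("imaging"))
        if "color_model" in block:
            cm = block["color_model"]
            for key in ("negative_rgb", "positive_rgb"):
                if key in cm:
                    cm[key] = tuple(cm[key])
            block["color_model"] = _build(ColorModel, cm, "imaging.color_model")
        kwargs["imaging"] = _build(ImagingConfig, block, "imaging")
    for key in ("setpoint", "include_calibration_in_heating"):
        if key in data:
            kwargs[key] = data.pop(key)
    if data:
        raise InvalidInputError(f"unknown top-level config keys: {sorted(data)}")
    return RunConfig(**kwargs)


def load_run_config(path: str | Path | None) -> RunConfig:
    """Load YAML config; a missing path yields all defaults."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    return run_config_from_dict(yaml.safe_load(text) or {})
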