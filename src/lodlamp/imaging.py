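"""Synthetic labeled ROI images of the colorimetric detection chamber.

The HNB indicator renders unamplified (negative) reactions indigo and
amplified (positive) reactions sky-blue.  The generator emits 30x30 8-bit
RGB patches of one class with controllable realism degradations: partial
color change (ambiguity), per-image hue jitter, a linear illumination
gradient, and per-pixel Gaussian noise.  Everything is deterministic per
seed so datasets are reproducible bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.color import hsv2rgb, rgb2hsv

from .exceptions import InvalidInputError

ROI_SIZE = 30
LABELS = ("negative", "positive")


@dataclass(frozen=True)
class ColorModel:
    """Base colors and degradation parameters of the generator.

    ``ambiguity`` in [0, 1] pulls both class colors toward their common
    midpoint; at 1 the classes have identical expected color.
    """

    negative_rgb: tuple[int, int, int] = (40, 40, 120)
    positive_rgb: tuple[int, int, int] = (110, 180, 230)
    pixel_noise_sd: float = 8.0
    illumination_gradient_max: float = 0.15
    hue_jitter_sd: float = 4.0  # degrees
    ambiguity: float = 0.15

    def __post_init__(self) -> None:
        if tuple(self.negative_rgb) == tuple(self.positive_rgb):
            raise InvalidInputError("class base colors must be distinct")
        for name in ("pixel_noise_sd", "illumination_gradient_max", "hue_jitter_sd"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")
        if not 0 <= self.ambiguity <= 1:
            raise InvalidInputError("ambiguity must be in [0, 1]")

    def base_color(self, label: str) -> np.ndarray:
        """Class base color after ambiguity mixing, as float RGB."""
        if label not in LABELS:
            raise InvalidInputError(f"label must be one of {LABELS}, got {label!r}")
        own = np.asarray(
            self.positive_rgb if label == "positive" else self.negative_rgb,
            dtype=float,
        )
        other = np.asarray(
            self.negative_rgb if label == "positive" else self.positive_rgb,
            dtype=float,
        )
        # ambiguity = 1 puts both classes at the shared midpoint
        return own + 0.5 * self.ambiguity * (other - own)


@dataclass(frozen=True)
class ROIImage:
    """A labeled 30x30 RGB patch plus its generator provenance."""

    pixels: np.ndarray
    label: str
    seed: int
    generator_params: ColorModel

    def __post_init__(self) -> None:
        px = self.pixels
        if px.shape != (ROI_SIZE, ROI_SIZE, 3) or px.dtype != np.uint8:
            raise InvalidInputError(
                f"pixels must be uint8 of shape ({ROI_SIZE}, {ROI_SIZE}, 3)"
            )
        if self.label not in LABELS:
            raise InvalidInputError(f"unknown label {self.label!r}")


@dataclass(frozen=True)
class LabeledDataset:
    train: tuple[ROIImage, ...]
    test: tuple[ROIImage, ...]
    master_seed: int


def _jitter_hue(rgb: np.ndarray, jitter_deg: float) -> np.ndarray:
    hsv = rgb2hsv(rgb.reshape(1, 1, 3) / 255.0)
    hsv[..., 0] = (hsv[..., 0] + jitter_deg / 360.0) % 1.0
    return hsv2rgb(hsv).reshape(3) * 255.0


def _illumination_field(rng: np.random.Generator, gradient_max: float) -> np.ndarray:
    """Random linear brightness ramp with relative deviation <= gradient_max."""
    if gradient_max == 0:
        return np.ones((ROI_SIZE, ROI_SIZE))
    theta = rng.uniform(0.0, 2.0 * math.pi)
    amplitude = rng.uniform(0.0, gradient_max)
    coords = np.linspace(-1.0, 1.0, ROI_SIZE)
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    proj = xx * math.cos(theta) + yy * math.sin(theta)
    proj /= np.abs(proj).max()
    return 1.0 + amplitude * proj


def generate_roi(label: str, model: ColorModel, seed: int) -> ROIImage:
    """Render one labeled ROI patch.

    Pipeline: ambiguity-mixed base color -> per-image hue jitter ->
    multiplicative linear illumination gradient -> per-pixel Gaussian noise
    -> clip to [0, 255] and quantize to 8 bits.
    """
    rng = np.random.default_rng(seed)
    color = model.base_color(label)
    if model.hue_jitter_sd > 0:
        color = _jitter_hue(color, rng.normal(0.0, model.hue_jitter_sd))
    field_2d = _illumination_field(rng, model.illumination_gradient_max)
    pixels = color[None, None, :] * field_2d[:, :, None]
    if model.pixel_noise_sd > 0:
        pixels = pixels + rng.normal(0.0, model.pixel_noise_sd, pixels.shape)
    pixels = np.clip(np.rint(pixels), 0, 255).astype(np.uint8)
    return ROIImage(pixels=pixels, label=label, seed=seed, generator_params=model)


def generate_dataset(
    n_train: int = 100,
    n_test: int = 30,
    model: ColorModel | None = None,
    master_seed: int = 0,
) -> LabeledDataset:
    """Balanced train/test dataset with deterministic per-image child seeds.

    Child seeds are drawn from disjoint streams of ``SeedSequence(master_seed)``
    (stream 0 for train, stream 1 for test) so splits never share an image.
    """
    if n_train <= 0 or n_test <= 0:
        raise InvalidInputError("n_train and n_test must be > 0")
    model = model or ColorModel()
    train_ss, test_ss = np.random.SeedSequence(master_seed).spawn(2)

    def build(n: int, ss: np.random.SeedSequence) -> tuple[ROIImage, ...]:
        seeds = ss.generate_state(n, dtype=np.uint32)
        labels = [LABELS[i % 2] for i in range(n)]  # balanced within +/-1
        return tuple(
            generate_roi(label, model, int(s)) for label, s in zip(labels, seeds)
        )

    return LabeledDataset(
        train=build(n_train, train_ss),
        test=build(n_test, test_ss),
        master_seed=master_seed,
    )


def save_dataset(dataset: LabeledDataset, out_dir: str | Path) -> Path:
    """Write PNGs (lossless 8-bit) plus a manifest CSV; returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for split, images in (("train", dataset.train), ("test", dataset.test)):
        for i, roi in enumerate(images):
            name = f"{split}_{i:04d}_{roi.label}.png"
            Image.fromarray(roi.pixels).save(out / name, format="PNG")
            rows.append(
                {"filename": name, "split": split, "label": roi.label, "seed": roi.seed}
            )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_dataset(manifest_path: str | Path) -> LabeledDataset:
    """Re-read a saved dataset from its manifest and PNGs."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    root = manifest_path.parent
    splits: dict[str, list[ROIImage]] = {"train": [], "test": []}
    placeholder = ColorModel()
    for row in df.itertuples():
        pixels = np.asarray(Image.open(root / row.filename).convert("RGB"))
        splits[row.split].append(
            ROIImage(pixels=pixels, label=row.label, seed=int(row.seed),
                     generator_params=placeholder)
        )
    return LabeledDataset(
        train=tuple(splits["train"]), test=tuple(splits["test"]), master_seed=-1
    )
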