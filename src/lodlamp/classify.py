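"""Colorimetric endpoint caller: color features + regularized logistic model.

Stands in for a heavyweight CNN: the task is two-class color discrimination
on 30x30 patches, for which summary color statistics and a linear decision
boundary suffice and train in milliseconds on a CPU.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage.color import rgb2hsv
from sklearn.linear_model import LogisticRegression

from .exceptions import InvalidInputError, NotFittedError
from .imaging import ROI_SIZE, ROIImage

FEATURE_NAMES = (
    "hue_mean_deg",
    "hue_std_deg",
    "saturation_mean",
    "saturation_std",
    "value_mean",
    "value_std",
    "red_mean",
    "green_mean",
    "blue_mean",
    "blue_to_red_ratio",
)

POSITIVE, NEGATIVE = "positive", "negative"

#: Standardized features are winsorized at +/- this many train-set standard
#: deviations, in training and scoring alike, so out-of-distribution inputs
#: (e.g. a noise-free prototype patch) cannot extrapolate the linear score.
Z_CLIP = 3.0


@dataclass(frozen=True)
class FeatureVector:
    """Summary color statistics of one ROI (hue statistics are circular)."""

    hue_mean_deg: float
    hue_std_deg: float
    saturation_mean: float
    saturation_std: float
    value_mean: float
    value_std: float
    red_mean: float
    green_mean: float
    blue_mean: float
    blue_to_red_ratio: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)


@dataclass
class ClassifierModel:
    """Linear logistic endpoint caller with train-set normalization."""

    feature_mean: np.ndarray
    feature_std: np.ndarray
    weights: np.ndarray
    bias: float
    threshold: float = 0.5
    n_train: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise InvalidInputError("threshold must be in (0, 1)")

    def save(self, path: str | Path) -> None:
        payload = {
            "feature_names": list(FEATURE_NAMES),
            "feature_mean": self.feature_mean.tolist(),
            "feature_std": self.feature_std.tolist(),
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "threshold": self.threshold,
            "n_train": self.n_train,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            feature_mean=np.asarray(payload["feature_mean"], dtype=float),
            feature_std=np.asarray(payload["feature_std"], dtype=float),
            weights=np.asarray(payload["weights"], dtype=float),
            bias=float(payload["bias"]),
            threshold=float(payload["threshold"]),
            n_train=int(payload["n_train"]),
            seed=int(payload["seed"]),
        )


def _as_pixels(roi: ROIImage | np.ndarray) -> np.ndarray:
    pixels = roi.pixels if isinstance(roi, ROIImage) else np.asarray(roi)
    if pixels.shape != (ROI_SIZE, ROI_SIZE, 3):
        raise InvalidInputError(
            f"expected shape ({ROI_SIZE}, {ROI_SIZE}, 3), got {pixels.shape}"
        )
    return pixels


def extract_features(roi: ROIImage | np.ndarray) -> FeatureVector:
    """Deterministic color features of one ROI.

    Hue is averaged circularly (resultant-vector direction, degrees); its
    spread is the circular standard deviation.  Achromatic pixels carry hue 0
    and saturation 0, so a grayscale patch has zero mean saturation.
    """
    pixels = _as_pixels(roi).astype(float) / 255.0
    hsv = rgb2hsv(pixels)
    hue_rad = hsv[..., 0].ravel() * 2.0 * math.pi
    sat = hsv[..., 1].ravel()
    val = hsv[..., 2].ravel()
    c, s = np.cos(hue_rad).mean(), np.sin(hue_rad).mean()
    resultant = math.hypot(c, s)
    hue_mean = math.degrees(math.atan2(s, c)) % 360.0
    # circular std; guard against resultant rounding above 1
    hue_std = math.degrees(math.sqrt(max(0.0, -2.0 * math.log(min(resultant, 1.0)))))
    r_mean, g_mean, b_mean = pixels.reshape(-1, 3).mean(axis=0) * 255.0
    return FeatureVector(
        hue_mean_deg=hue_mean,
        hue_std_deg=hue_std,
        saturation_mean=float(sat.mean()),
        saturation_std=float(sat.std()),
        value_mean=float(val.mean()),
        value_std=float(val.std()),
        red_mean=float(r_mean),
        green_mean=float(g_mean),
        blue_mean=float(b_mean),
        blue_to_red_ratio=float(b_mean / (r_mean + 1e-9)),
    )


def _features_labels(images: Sequence[ROIImage]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([extract_features(img).to_array() for img in images])
    y = np.array([1 if img.label == POSITIVE else 0 for img in images])
    return x, y


def train_classifier(
    train: Sequence[ROIImage], seed: int = 0, threshold: float = 0.5
) -> ClassifierModel:
    """Fit the regularized logistic caller on extracted features.

    Raises
    ------
    InvalidInputError
        If the training set does not contain both classes.
    """
    if not train:
        raise InvalidInputError("empty training set")
    x, y = _features_labels(train)
    if len(np.unique(y)) < 2:
        raise InvalidInputError("training set must contain both classes")
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    z = np.clip((x - mean) / std, -Z_CLIP, Z_CLIP)
    clf = LogisticRegression(C=1.0, max_iter=2000, random_state=seed)
    clf.fit(z, y)
    return ClassifierModel(
        feature_mean=mean,
        feature_std=std,
        weights=clf.coef_.ravel().copy(),
        bias=float(clf.intercept_[0]),
        threshold=threshold,
        n_train=len(train),
        seed=seed,
    )


def classify(model: ClassifierModel, roi: ROIImage | np.ndarray) -> tuple[str, float]:
    """Score one ROI; label is positive iff score >= threshold.

    A score exactly at the threshold is called positive: the fail-safe
    direction is to flag a possible detection.
    """
    if model.weights is None or model.weights.size == 0:
        raise NotFittedError("classifier has no fitted weights")
    f = extract_features(roi).to_array()
    z = np.clip((f - model.feature_mean) / model.feature_std, -Z_CLIP, Z_CLIP)
    score = float(1.0 / (1.0 + math.exp(-(model.weights @ z + model.bias))))
    label = POSITIVE if score >= model.threshold else NEGATIVE
    return label, score


def evaluate(model: ClassifierModel, test: Sequence[ROIImage]) -> dict:
    """Accuracy and confusion counts on a labeled test set."""
    if not test:
        raise InvalidInputError("empty test set")
    counts = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
    for img in test:
        predicted, _ = classify(model, img)
        if img.label == POSITIVE:
            counts["tp" if predicted == POSITIVE else "fn"] += 1
        else:
            counts["tn" if predicted == NEGATIVE else "fp"] += 1
    n = len(test)
    correct = counts["tp"] + counts["tn"]
    return {
        "accuracy": correct / n,
        "n_test": n,
        "confusion": counts,
    }
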