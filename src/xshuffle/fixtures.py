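"""Synthetic fixtures: class images, oracle toys, manual segmentations, and
simulated observers.

Everything the package needs for testing and demonstration is generated here,
with no downloads: a 10-class set of shape-on-texture images standing in for a
10-class natural-image dataset, tiny distinct-valued toy images on which pixel
permutations can be tracked exactly, hand-built segmentation maps with known
region sizes, and simulated observer cohorts whose planted accuracies and
confidence models emulate the human/network behavioral contrast (human
confidence tracks accuracy; network confidence does not).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import draw as skdraw

from .errors import ParameterError, SpecError
from .image import as_generator
from .segmentation import SegmentationMap
from .stats import TRIAL_COLUMNS

__all__ = [
    "CLASS_NAMES",
    "SimulatedObserverSpec",
    "make_class_image",
    "make_toy_image",
    "make_manual_segmentation",
    "planted_condition_accuracies",
    "simulate_trials",
]

# 10 distinct (shape, fill color) combinations
_CLASS_SPECS = [
    ("disk", (220, 60, 60)),
    ("square", (60, 200, 60)),
    ("triangle", (70, 90, 230)),
    ("cross", (230, 200, 50)),
    ("ring", (200, 70, 200)),
    ("diamond", (60, 210, 210)),
    ("hbar", (240, 140, 40)),
    ("vbar", (140, 80, 200)),
    ("ellipse", (100, 180, 90)),
    ("chevron", (230, 120, 150)),
]

CLASS_NAMES = tuple(f"{shape}" for shape, _ in _CLASS_SPECS)


def _background(height: int, width: int, rng: np.random.Generator) -> np.ndarray:
    """Low-contrast texture: grayish noise with coarse structure so that
    superpixel segmentation has something to latch onto."""
    coarse = rng.integers(70, 130, size=(height // 8 + 1, width // 8 + 1, 3))
    bg = np.kron(coarse, np.ones((8, 8, 1)))[:height, :width]
    speckle = rng.integers(-18, 19, size=(height, width, 3))
    return np.clip(bg + speckle, 0, 255).astype(np.uint8)


def _shape_mask(shape: str, height: int, width: int) -> np.ndarray:
    cy, cx = height / 2, width / 2
    r = min(height, width) * 0.3
    mask = np.zeros((height, width), dtype=bool)
    if shape == "disk":
        rr, cc = skdraw.disk((cy, cx), r, shape=(height, width))
    elif shape == "square":
        rr, cc = skdraw.rectangle((int(cy - r), int(cx - r)),
                                  (int(cy + r), int(cx + r)))
    elif shape == "triangle":
        rr, cc = skdraw.polygon([cy - r, cy + r, cy + r],
                                [cx, cx - r, cx + r], shape=(height, width))
    elif shape == "cross":
        w = r / 3
        mask[int(cy - r):int(cy + r), int(cx - w):int(cx + w)] = True
        mask[int(cy - w):int(cy + w), int(cx - r):int(cx + r)] = True
        return mask
    elif shape == "ring":
        rr, cc = skdraw.disk((cy, cx), r, shape=(height, width))
        mask[rr, cc] = True
        rr, cc = skdraw.disk((cy, cx), r * 0.55, shape=(height, width))
        mask[rr, cc] = False
        return mask
    elif shape == "diamond":
        rr, cc = skdraw.polygon([cy - r, cy, cy + r, cy],
                                [cx, cx + r, cx, cx - r], shape=(height, width))
    elif shape == "hbar":
        rr, cc = skdraw.rectangle((int(cy - r / 3), int(cx - r)),
                                  (int(cy + r / 3), int(cx + r)))
    elif shape == "vbar":
        rr, cc = skdraw.rectangle((int(cy - r), int(cx - r / 3)),
                                  (int(cy + r), int(cx + r / 3)))
    elif shape == "ellipse":
        rr, cc = skdraw.ellipse(cy, cx, r * 0.55, r, shape=(height, width))
    elif shape == "chevron":
        rr, cc = skdraw.polygon(
            [cy - r, cy, cy + r, cy + r, cy, cy - r],
            [cx - r, cx, cx - r, cx - r / 3, cx + r, cx - r / 3],
            shape=(height, width))
    else:  # pragma: no cover - guarded by caller
        raise SpecError(f"unknown shape {shape!r}")
    mask[rr, cc] = True
    return mask


def make_class_image(class_id: int, height: int = 320, width: int = 320,
                     rng=0):
    """Deterministic class image: a centered colored shape on texture.

    Returns ``(image, class_label)``.  Classes are distinguishable by shape
    and fill color; the background texture varies with the seed so repeated
    calls can produce many distinct exemplars per class.  The default
    320 x 320 size is divisible by every block size in the study grid.
    """
    if not 0 <= int(class_id) <= 9:
        raise SpecError(f"class_id must be 0..9, got {class_id}")
    rng = as_generator(rng)
    shape, color = _CLASS_SPECS[int(class_id)]
    img = _background(height, width, rng)
    mask = _shape_mask(shape, height, width)
    jitter = rng.integers(-10, 11, size=(height, width, 3))
    fill = np.clip(np.asarray(color) + jitter, 0, 255).astype(np.uint8)
    img[mask] = fill[mask]
    return img, shape


def make_toy_image(height: int, width: int) -> np.ndarray:
    """Tiny image whose pixel triplets are pairwise distinct.

    Distinct values make every permutation of pixels exactly trackable, which
    is what the oracle and conservation tests need.  Limited to 64 pixels so
    distinctness is trivially guaranteed in 8-bit range.
    """
    n = height * width
    if n > 64:
        raise ParameterError(
            f"toy images are limited to 64 pixels, got {height}x{width}"
        )
    if n <= 0:
        raise ParameterError("toy image must be nonempty")
    i = np.arange(n)
    triplets = np.stack([4 * i + 1, (37 * i + 5) % 256, (91 * i + 17) % 256],
                        axis=1)
    return triplets.reshape(height, width, 3).astype(np.uint8)


def make_manual_segmentation(height: int, width: int,
                             layout="halves") -> SegmentationMap:
    """Hand-built segmentation with exactly known region geometry.

    ``layout`` is one of ``"halves"`` (top/bottom), ``"quadrants"``,
    ``"bands"`` (four horizontal bands), or a sequence of region sizes filled
    consecutively in row-major order — the latter deliberately supports
    unequal sizes to exercise the displacement resample/drop rule.
    """
    n = height * width
    if isinstance(layout, str):
        labels = np.zeros((height, width), dtype=np.int64)
        if layout == "halves":
            labels[height // 2:, :] = 1
        elif layout == "quadrants":
            labels[:height // 2, width // 2:] = 1
            labels[height // 2:, :width // 2] = 2
            labels[height // 2:, width // 2:] = 3
        elif layout == "bands":
            edges = np.linspace(0, height, 5).astype(int)
            for i in range(4):
                labels[edges[i]:edges[i + 1], :] = i
        else:
            raise ParameterError(f"unknown layout {layout!r}")
        sizes = list(np.bincount(labels.ravel()))
    else:
        sizes = [int(s) for s in layout]
        if sum(sizes) != n:
            raise ParameterError(
                f"region sizes sum to {sum(sizes)}, expected {n}"
            )
        labels = np.repeat(np.arange(len(sizes)), sizes).reshape(height, width)
    seg = SegmentationMap(labels=labels, k_requested=len(sizes))
    return seg


@dataclass(frozen=True)
class SimulatedObserverSpec:
    """Planted behavioral profile for one simulated observer.

    ``accuracy`` maps condition_id -> true per-condition accuracy in [0, 1].
    Human-like observers report confidence as a clipped, rounded affine map
    of the condition's true accuracy plus Gaussian noise (1–5 scale);
    network-like observers report a confidence in [0, 1] drawn independently
    of accuracy.
    """

    observer_id: str
    observer_type: str  # "human" | "network"
    accuracy: dict
    conf_slope: float = 4.0
    conf_intercept: float = 1.0
    conf_noise_sd: float = 0.35
    catch_accuracy: float = 0.98

    def __post_init__(self):
        if self.observer_type not in ("human", "network"):
            raise SpecError(f"unknown observer_type {self.observer_type!r}")
        for cid, acc in self.accuracy.items():
            if not 0.0 <= acc <= 1.0:
                raise SpecError(f"accuracy for {cid} outside [0, 1]: {acc}")
        if self.conf_noise_sd < 0:
            raise SpecError("conf_noise_sd must be >= 0")


def planted_condition_accuracies(conditions, rng, low: float = 0.15,
                                 high: float = 1.0) -> dict:
    """Draw one shared difficulty profile over ``conditions``.

    Baseline-like conditions sit at the top of the range; the rest are spread
    uniformly, giving the wide accuracy spread over conditions that drives a
    detectable confidence–accuracy correlation.
    """
    rng = as_generator(rng)
    out = {}
    for spec in conditions:
        cid = getattr(spec, "condition_id", spec)
        if cid == "baseline":
            out[cid] = 1.0
        else:
            out[cid] = float(rng.uniform(low, high))
    return out


def simulate_trials(observers, conditions, n_trials_per_condition: int, rng,
                    n_catch_trials: int = 6, n_classes: int = 10,
                    response_time_mean: float = 3.0) -> pd.DataFrame:
    """Simulate a full trial table for a cohort of observers.

    Per (observer, condition): ``n_trials_per_condition`` Bernoulli trials at
    the observer's planted accuracy; wrong answers are uniform over the other
    ``n_classes - 1`` labels.  Human confidence is
    ``clip(round(slope * accuracy + intercept + noise), 1, 5)`` per trial;
    network confidence is an independent uniform score in [0, 1].  Each
    observer additionally receives ``n_catch_trials`` easy catch trials at
    the planted near-ceiling catch accuracy, marked ``is_catch``.
    """
    if not len(list(conditions)):
        raise ParameterError("condition list is empty")
    rng = as_generator(rng)
    class_labels = [CLASS_NAMES[i % 10] if n_classes <= 10 else f"class{i}"
                    for i in range(n_classes)]
    rows = []

    def emit(obs, cid, planted, is_catch):
        true_class = class_labels[int(rng.integers(n_classes))]
        correct = rng.random() < planted
        if correct:
            predicted = true_class
        else:
            foils = [c for c in class_labels if c != true_class]
            predicted = foils[int(rng.integers(n_classes - 1))]
        if obs.observer_type == "human":
            conf = float(np.clip(
                np.round(obs.conf_slope * planted + obs.conf_intercept
                         + rng.normal(0.0, obs.conf_noise_sd)), 1, 5))
        else:
            conf = float(rng.random())
        rows.append({
            "observer_id": obs.observer_id,
            "observer_type": obs.observer_type,
            "condition_id": cid,
            "true_class": true_class,
            "predicted_class": predicted,
            "confidence": conf,
            "response_time": float(rng.exponential(response_time_mean)),
            "is_catch": is_catch,
        })

    for obs in observers:
        for spec in conditions:
            cid = getattr(spec, "condition_id", spec)
            planted = obs.accuracy[cid]
            for _ in range(n_trials_per_condition):
                emit(obs, cid, planted, False)
        for _ in range(n_catch_trials):
            emit(obs, "baseline", obs.catch_accuracy, True)

    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)
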