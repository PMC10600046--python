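"""Experiment condition grid and psychophysics stimulus-set builder.

The transform space is spanned by three independent variables — block size (or
segment count), per-pixel shuffle probability, and whether blocks/regions are
relocated.  The study grid instantiates it as:

* Full Random Shuffle at p in {0.5, 0.8, 1.0} (3 conditions)
* Grid Shuffle at block sizes {20, 40, 80, 160} (4)
* Within Grid Shuffle at those block sizes x p in {0.5, 1.0} (8)
* Local Structure Shuffle over the same grid (8)

23 block conditions in all, plus

* Segmentation Displacement Shuffle at k in {8, 16, 64} (3)
* Segmentation Within Shuffle at k in {8, 16, 64} x p in {0.5, 1.0} (6)

9 segmentation conditions, and with the untransformed baseline and Color
Flatten the full grid counts 34 conditions.  Three stimuli per condition gives
the 102-image test set of the behavioral study.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import block as _block
from . import segmentation as _seg
from .errors import SamplingError, SpecError
from .image import as_generator, save_image, validate_image

__all__ = [
    "TransformSpec",
    "FAMILIES",
    "BLOCK_SIZES",
    "SEGMENT_COUNTS",
    "enumerate_block_configs",
    "enumerate_segmentation_configs",
    "enumerate_all_conditions",
    "apply_condition",
    "build_stimulus_set",
    "load_manifest",
]

FAMILIES = (
    "baseline", "color_flatten", "full_random", "grid", "local_structure",
    "seg_displacement", "seg_within", "within_grid",
)

BLOCK_SIZES = (20, 40, 80, 160)
SEGMENT_COUNTS = (8, 16, 64)
FULL_RANDOM_PROBS = (0.5, 0.8, 1.0)
BLOCK_PROBS = (0.5, 1.0)

# which optional parameters each family carries
_PARAMS = {
    "baseline": (),
    "color_flatten": (),
    "full_random": ("probability",),
    "grid": ("block_size",),
    "within_grid": ("block_size", "probability"),
    "local_structure": ("block_size", "probability"),
    "seg_within": ("n_segments", "probability"),
    "seg_displacement": ("n_segments",),
}


@dataclass(frozen=True)
class TransformSpec:
    """One point in the 3-D transform parameter space.

    ``condition_id`` is a stable string key, unique within a grid and
    deterministic from the parameters; it round-trips through
    :meth:`from_condition_id`.
    """

    family: str
    block_size: int | None = None
    n_segments: int | None = None
    probability: float | None = None

    def __post_init__(self):
        if self.family not in _PARAMS:
            raise SpecError(f"unknown transform family {self.family!r}")
        required = _PARAMS[self.family]
        for param in ("block_size", "n_segments", "probability"):
            value = getattr(self, param)
            if param in required and value is None:
                raise SpecError(f"{self.family} requires {param}")
            if param not in required and value is not None:
                raise SpecError(f"{self.family} does not take {param}")
        if self.probability is not None and not 0.0 <= self.probability <= 1.0:
            raise SpecError(f"probability {self.probability} outside [0, 1]")

    @property
    def condition_id(self) -> str:
        parts = [self.family]
        if self.block_size is not None:
            parts.append(f"b{self.block_size}")
        if self.n_segments is not None:
            parts.append(f"k{self.n_segments}")
        if self.probability is not None:
            parts.append(f"p{self.probability:g}")
        return "_".join(parts)

    @classmethod
    def from_condition_id(cls, condition_id: str) -> "TransformSpec":
        tokens = condition_id.split("_")
        kwargs: dict = {}
        while tokens and re.fullmatch(r"[bkp]\d+(\.\d+)?", tokens[-1]):
            token = tokens.pop()
            key = {"b": "block_size", "k": "n_segments", "p": "probability"}[token[0]]
            kwargs[key] = float(token[1:]) if token[0] == "p" else int(token[1:])
        family = "_".join(tokens)
        try:
            return cls(family=family, **kwargs)
        except SpecError as exc:
            raise SpecError(f"cannot parse condition id {condition_id!r}: {exc}")

    def _sort_key(self):
        size = self.block_size if self.block_size is not None else self.n_segments
        return (self.family, size or 0, self.probability or 0.0)


def _sorted(specs):
    # deterministic lexicographic order: family, spatial parameter, probability
    return sorted(specs, key=TransformSpec._sort_key)


def enumerate_block_configs() -> list[TransformSpec]:
    """The 23 block-transform conditions of the study grid."""
    specs = [TransformSpec("full_random", probability=p) for p in FULL_RANDOM_PROBS]
    specs += [TransformSpec("grid", block_size=b) for b in BLOCK_SIZES]
    for family in ("within_grid", "local_structure"):
        specs += [
            TransformSpec(family, block_size=b, probability=p)
            for b in BLOCK_SIZES for p in BLOCK_PROBS
        ]
    return _sorted(specs)


def enumerate_segmentation_configs() -> list[TransformSpec]:
    """The 9 segmentation-transform conditions of the study grid."""
    specs = [TransformSpec("seg_displacement", n_segments=k)
             for k in SEGMENT_COUNTS]
    specs += [
        TransformSpec("seg_within", n_segments=k, probability=p)
        for k in SEGMENT_COUNTS for p in BLOCK_PROBS
    ]
    return _sorted(specs)


def enumerate_all_conditions() -> list[TransformSpec]:
    """Baseline + Color Flatten + 23 block + 9 segmentation = 34 conditions."""
    specs = [TransformSpec("baseline"), TransformSpec("color_flatten")]
    specs += enumerate_block_configs() + enumerate_segmentation_configs()
    return _sorted(specs)


def apply_condition(img: np.ndarray, spec: TransformSpec, rng):
    """Dispatch one condition to its transform.

    Returns a raster image for every family except ``color_flatten``, which
    returns :class:`~xshuffle.block.FlattenedChannels` (render with
    :func:`~xshuffle.block.render_flattened` for display).
    """
    img = validate_image(img)
    rng = as_generator(rng)
    family = spec.family
    if family == "baseline":
        return img.copy()
    if family == "color_flatten":
        return _block.color_flatten(img)
    if family == "full_random":
        return _block.full_random_shuffle(img, spec.probability, rng)
    if family == "grid":
        return _block.grid_shuffle(img, spec.block_size, rng)
    if family == "within_grid":
        return _block.within_grid_shuffle(img, spec.block_size,
                                          spec.probability, rng)
    if family == "local_structure":
        return _block.local_structure_shuffle(img, spec.block_size,
                                              spec.probability, rng)
    if family in ("seg_within", "seg_displacement"):
        seg = _seg.compute_superpixels(img, spec.n_segments)
        if family == "seg_within":
            return _seg.segmentation_within_shuffle(img, seg,
                                                    spec.probability, rng)
        return _seg.segmentation_displacement_shuffle(img, seg, rng)
    raise SpecError(f"unknown transform family {family!r}")  # pragma: no cover


MANIFEST_COLUMNS = [
    "condition_id", "family", "block_size", "n_segments", "probability",
    "source_image", "seed", "output_path", "true_class",
]


def build_stimulus_set(images, n_per_condition: int, rng, out_dir,
                       conditions=None,
                       unique_across_conditions: bool = True) -> pd.DataFrame:
    """Build the psychophysics stimulus set and its manifest.

    For each condition, ``n_per_condition`` source images are sampled without
    replacement, transformed with a freshly drawn per-stimulus seed, and
    written as PNG under ``out_dir``.  With ``unique_across_conditions`` (the
    study design: 102 unique stimuli from 34 x 3), no source image is reused
    by two conditions, which requires ``len(images) >= 34 * n_per_condition``.
    Color Flatten stimuli are written as the rendered 2-D display PNG plus a
    three-column CSV sidecar holding the channel vectors.

    ``images`` is a sequence of ``(image, true_class)`` pairs.  Returns the
    manifest as a DataFrame and writes it to ``out_dir / manifest.csv``; the
    manifest plus the source images and seeds fully determine every stimulus.
    """
    rng = as_generator(rng)
    conditions = list(conditions) if conditions is not None else enumerate_all_conditions()
    n_images = len(images)
    n_needed = (len(conditions) * n_per_condition if unique_across_conditions
                else n_per_condition)
    if n_images < n_needed:
        raise SamplingError(
            f"need at least {n_needed} source images, got {n_images}"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if unique_across_conditions:
        pool = rng.choice(n_images, size=len(conditions) * n_per_condition,
                          replace=False)
        picks = pool.reshape(len(conditions), n_per_condition)
    else:
        picks = np.stack([
            rng.choice(n_images, size=n_per_condition, replace=False)
            for _ in conditions
        ])

    rows = []
    for spec, indices in zip(conditions, picks):
        for idx in indices:
            img, true_class = images[int(idx)]
            seed = int(rng.integers(0, 2**31 - 1))
            result = apply_condition(img, spec, np.random.default_rng(seed))
            stem = f"{spec.condition_id}__img{int(idx):04d}"
            out_path = out_dir / f"{stem}.png"
            if isinstance(result, _block.FlattenedChannels):
                save_image(out_path, _block.render_flattened(result))
                pd.DataFrame({"red": result.red, "green": result.green,
                              "blue": result.blue}).to_csv(
                    out_dir / f"{stem}.channels.csv", index=False)
            else:
                save_image(out_path, result)
            rows.append({
                "condition_id": spec.condition_id,
                "family": spec.family,
                "block_size": spec.block_size,
                "n_segments": spec.n_segments,
                "probability": spec.probability,
                "source_image": f"img{int(idx):04d}",
                "seed": seed,
                "output_path": str(out_path),
                "true_class": true_class,
            })
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_manifest(path) -> pd.DataFrame:
    """Read a stimulus manifest written by :func:`build_stimulus_set`."""
    return pd.read_csv(path, dtype={"condition_id": str})
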