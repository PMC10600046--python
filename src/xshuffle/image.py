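"""Raster image validation, seeded-randomness plumbing, and PNG I/O.

An image is an ``H x W x 3`` ``uint8`` array of whole (R, G, B) pixels.  Every
transform in this package moves pixels as intact triplets, so the sorted
multiset of triplets is conserved by construction; that invariant only survives
lossless storage, hence PNG is the required output format (JPEG is accepted on
input with a warning).
"""

from __future__ import annotations

import warnings

import numpy as np
from PIL import Image

from .errors import DimensionError

__all__ = [
    "validate_image",
    "as_generator",
    "load_image",
    "save_image",
    "pixel_multiset",
]


def validate_image(img: np.ndarray) -> np.ndarray:
    """Validate and return ``img`` as a ``uint8`` H x W x 3 array.

    Raises
    ------
    DimensionError
        If the array is not 3-D with a trailing channel axis of 3, is empty,
        or holds intensities outside [0, 255].
    """
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise DimensionError(
            f"expected an H x W x 3 array, got shape {arr.shape}"
        )
    if arr.shape[0] == 0 or arr.shape[1] == 0:
        raise DimensionError(f"empty image: shape {arr.shape}")
    if arr.dtype != np.uint8:
        if arr.min() < 0 or arr.max() > 255:
            raise DimensionError("intensities must lie in [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


def as_generator(rng) -> np.random.Generator:
    """Coerce an int seed or an existing Generator into a Generator.

    Passing the same integer twice yields independent but identically seeded
    streams, so equal (inputs, parameters, seed) give bit-identical outputs.
    """
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def load_image(path) -> np.ndarray:
    """Load an RGB raster from disk.

    JPEG sources are accepted but trigger a warning: lossy storage breaks the
    exact pixel-multiset conservation guarantees of the transforms.
    """
    with Image.open(path) as im:
        if (im.format or "").upper() in {"JPEG", "JPG"}:
            warnings.warn(
                "JPEG input is lossy; conservation invariants only hold for "
                "lossless round trips (use PNG)",
                stacklevel=2,
            )
        return validate_image(np.asarray(im.convert("RGB")))


def save_image(path, img: np.ndarray) -> None:
    """Write an image to ``path`` as lossless PNG."""
    Image.fromarray(validate_image(img), mode="RGB").save(path, format="PNG")


def pixel_multiset(img: np.ndarray) -> np.ndarray:
    """Sorted (R, G, B) triplets of ``img`` — the conserved quantity.

    Two images are permutations of one another iff their sorted triplet
    arrays are equal.
    """
    flat = np.asarray(img).reshape(-1, 3)
    order = np.lexsort((flat[:, 2], flat[:, 1], flat[:, 0]))
    return flat[order]
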