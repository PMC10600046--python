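"""Block-structured shuffles and Color Flatten.

Five transforms act on whole (R, G, B) pixels:

* :func:`full_random_shuffle` — each pixel location is independently selected
  with probability ``p``; the pixels at the selected locations are rearranged
  by one uniform random permutation over exactly those locations.  At
  ``p = 1.0`` a natural image turns into colored noise while keeping its exact
  pixel values.
* :func:`grid_shuffle` — the image is cut into equal square blocks whose
  positions are permuted uniformly at random; block interiors are untouched,
  so only global structure is altered.
* :func:`within_grid_shuffle` — blocks stay in place; each block's interior
  receives an independent full-random shuffle, altering only local structure.
* :func:`local_structure_shuffle` — within-grid shuffle followed by a grid
  shuffle of the result, altering local and global structure together.
* :func:`color_flatten` — channel separation plus row-major flattening into
  three 1-D vectors, destroying all 2-D structure.

Randomness contract
-------------------
Every stochastic operation consumes draws from the supplied generator in a
fixed, documented order: first the Bernoulli selection mask (one uniform per
pixel, row-major), then one permutation over the selected locations.  Blocks
are visited in row-major grid order.  Equal (input, parameters, seed) therefore
give bit-identical output, and a two-stage composition consuming the same
stream reproduces :func:`local_structure_shuffle` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionError, DivisibilityError, LayoutError, ParameterError
from .image import as_generator, validate_image

__all__ = [
    "FlattenedChannels",
    "full_random_shuffle",
    "partition_blocks",
    "assemble_blocks",
    "grid_shuffle",
    "within_grid_shuffle",
    "local_structure_shuffle",
    "color_flatten",
    "color_unflatten",
    "render_flattened",
]


def _check_probability(p: float) -> float:
    p = float(p)
    if not 0.0 <= p <= 1.0:
        raise ParameterError(f"shuffle probability must be in [0, 1], got {p}")
    return p


def _check_block_size(img: np.ndarray, block_size: int) -> int:
    block_size = int(block_size)
    if block_size <= 0:
        raise ParameterError(f"block size must be positive, got {block_size}")
    h, w = img.shape[:2]
    if h % block_size:
        raise DivisibilityError(
            f"image height {h} not divisible by block size {block_size}"
        )
    if w % block_size:
        raise DivisibilityError(
            f"image width {w} not divisible by block size {block_size}"
        )
    return block_size


def _shuffle_flat(flat: np.ndarray, locations: np.ndarray,
                  rng: np.random.Generator) -> None:
    """Permute ``flat`` rows at ``locations`` in place, uniformly at random.

    Consumes exactly one ``permutation(len(locations))`` draw.  The pixel that
    ends up at ``locations[t]`` is the one that was at ``locations[perm[t]]``.
    """
    perm = rng.permutation(locations.size)
    flat[locations] = flat[locations[perm]]


def full_random_shuffle(img: np.ndarray, p: float, rng) -> np.ndarray:
    """Shuffle pixel locations selected by an independent Bernoulli(p) mask.

    The (R, G, B) triplets at the selected locations are rearranged by a
    uniform random permutation over exactly those locations; unselected pixels
    are untouched.  Output dimensions and the multiset of pixel triplets are
    identical to the input's.  A uniform permutation may have fixed points, so
    a selected pixel can land back on its own location.
    """
    img = validate_image(img)
    p = _check_probability(p)
    rng = as_generator(rng)
    h, w = img.shape[:2]
    mask = rng.random((h, w)) < p
    out = img.reshape(-1, 3).copy()
    _shuffle_flat(out, np.flatnonzero(mask.ravel()), rng)
    return out.reshape(img.shape)


@dataclass(frozen=True)
class _GridLayout:
    rows: int
    cols: int
    block_size: int


def partition_blocks(img: np.ndarray, block_size: int):
    """Cut ``img`` into non-overlapping square blocks in row-major grid order.

    Returns ``(blocks, layout)`` where ``blocks`` is a list of
    ``block_size x block_size x 3`` copies and ``layout`` carries the grid
    shape needed by :func:`assemble_blocks`.
    """
    img = validate_image(img)
    block_size = _check_block_size(img, block_size)
    h, w = img.shape[:2]
    rows, cols = h // block_size, w // block_size
    blocks = [
        img[r * block_size:(r + 1) * block_size,
            c * block_size:(c + 1) * block_size].copy()
        for r in range(rows) for c in range(cols)
    ]
    return blocks, _GridLayout(rows, cols, block_size)


def assemble_blocks(blocks, layout) -> np.ndarray:
    """Inverse of :func:`partition_blocks` for an unpermuted block list."""
    rows, cols, b = layout.rows, layout.cols, layout.block_size
    if len(blocks) != rows * cols:
        raise LayoutError(
            f"expected {rows * cols} blocks for a {rows}x{cols} grid, "
            f"got {len(blocks)}"
        )
    for blk in blocks:
        if blk.shape != (b, b, 3):
            raise LayoutError(
                f"block shape {blk.shape} does not match layout "
                f"({b}, {b}, 3)"
            )
    out = np.empty((rows * b, cols * b, 3), dtype=np.uint8)
    for i, blk in enumerate(blocks):
        r, c = divmod(i, cols)
        out[r * b:(r + 1) * b, c * b:(c + 1) * b] = blk
    return out


def grid_shuffle(img: np.ndarray, block_size: int, rng) -> np.ndarray:
    """Permute equal square blocks uniformly at random.

    Each output block's interior is bit-identical to some input block: only
    the global arrangement changes.  Consumes one ``permutation(n_blocks)``
    draw; output grid cell ``t`` receives input block ``perm[t]``.
    """
    blocks, layout = partition_blocks(img, block_size)
    rng = as_generator(rng)
    perm = rng.permutation(len(blocks))
    return assemble_blocks([blocks[i] for i in perm], layout)


def within_grid_shuffle(img: np.ndarray, block_size: int, p: float,
                        rng) -> np.ndarray:
    """Full-random shuffle applied independently inside each block.

    Block positions are unchanged and no pixel crosses a block boundary, so
    the per-block pixel multisets are conserved.  Blocks consume their
    (mask, permutation) draws in row-major grid order.
    """
    img = validate_image(img)
    block_size = _check_block_size(img, block_size)
    p = _check_probability(p)
    rng = as_generator(rng)
    blocks, layout = partition_blocks(img, block_size)
    return assemble_blocks(
        [full_random_shuffle(blk, p, rng) for blk in blocks], layout
    )


def local_structure_shuffle(img: np.ndarray, block_size: int, p: float,
                            rng) -> np.ndarray:
    """Within-grid shuffle followed by a grid shuffle of the result.

    Alters both local structure (pixels inside blocks) and global structure
    (block positions).  The two stages consume the stream sequentially, so the
    composition ``grid_shuffle(within_grid_shuffle(img), ...)`` on a shared
    stream reproduces this transform exactly.  The global pixel multiset is
    conserved because both stages conserve it.
    """
    rng = as_generator(rng)
    return grid_shuffle(within_grid_shuffle(img, block_size, p, rng),
                        block_size, rng)


@dataclass(frozen=True)
class FlattenedChannels:
    """Three channel-separated 1-D vectors in row-major pixel order."""

    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray
    height: int
    width: int

    def __post_init__(self):
        n = self.height * self.width
        for name in ("red", "green", "blue"):
            vec = getattr(self, name)
            if vec.ndim != 1 or vec.size != n:
                raise DimensionError(
                    f"{name} vector has {vec.size} entries, expected "
                    f"{self.height} x {self.width} = {n}"
                )


def color_flatten(img: np.ndarray) -> FlattenedChannels:
    """Separate RGB channels and flatten each to a row-major 1-D vector."""
    img = validate_image(img)
    h, w = img.shape[:2]
    return FlattenedChannels(
        red=img[:, :, 0].ravel().copy(),
        green=img[:, :, 1].ravel().copy(),
        blue=img[:, :, 2].ravel().copy(),
        height=h,
        width=w,
    )


def color_unflatten(fc: FlattenedChannels, height: int, width: int) -> np.ndarray:
    """Exact inverse of :func:`color_flatten`."""
    if fc.height != height or fc.width != width:
        raise DimensionError(
            f"flattened channels carry shape ({fc.height}, {fc.width}), "
            f"requested ({height}, {width})"
        )
    return validate_image(
        np.stack(
            [fc.red.reshape(height, width),
             fc.green.reshape(height, width),
             fc.blue.reshape(height, width)],
            axis=2,
        )
    )


def render_flattened(fc: FlattenedChannels) -> np.ndarray:
    """Render flattened channels as a 2-D display image for human viewing.

    Concatenates red ‖ green ‖ blue into one vector of length 3·H·W and
    reshapes it row-major to H x W x 3.  This rendering is deterministic and
    value-conserving; it is isolated here so an alternative display convention
    can be swapped in without touching :func:`color_flatten`.
    """
    stacked = np.concatenate([fc.red, fc.green, fc.blue])
    return stacked.reshape(fc.height, fc.width, 3).astype(np.uint8)
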