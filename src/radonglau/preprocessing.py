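"""Grayscale conversion and CLAHE contrast enhancement for fundus images.

Fundus photographs suffer from non-uniform illumination and low local
contrast at the optic nerve head.  Preprocessing converts the color image to
a single luminance channel and applies Contrast Limited Adaptive Histogram
Equalization (CLAHE): the image is split into a grid of contextual tiles,
each tile's histogram is clipped at a fraction of the pixel count to limit
noise amplification, the clipped excess is redistributed, and the per-tile
intensity mappings are bilinearly interpolated across the image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage import exposure

# ITU-R BT.601 luma weights; they sum to 1 so replicated-gray inputs are fixed points.
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class ClaheConfig:
    """CLAHE parameters.

    Parameters
    ----------
    clip_limit:
        Histogram clipping threshold as a fraction of the tile pixel count
        (the convention used by :func:`skimage.exposure.equalize_adapthist`).
        Must be positive; larger values allow stronger equalization.
    tile_grid:
        Number of contextual regions as ``(rows, cols)``.
    """

    clip_limit: float = 0.01
    tile_grid: tuple[int, int] = (8, 8)

    def __post_init__(self) -> None:
        if self.clip_limit <= 0:
            raise ValueError("clip_limit must be positive")
        if self.tile_grid[0] < 1 or self.tile_grid[1] < 1:
            raise ValueError("tile_grid must be at least (1, 1)")


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to 8-bit grayscale luminance.

    Uses the BT.601 weights ``0.299 R + 0.587 G + 0.114 B`` rounded to the
    nearest integer.  A 2-D input is returned unchanged (already grayscale).

    Raises
    ------
    ValueError
        If the input is neither 2-D nor a 3-channel image.
    """
    arr = np.asarray(image)
    if arr.ndim == 2:
        return arr.astype(np.uint8, copy=False)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) color image, got shape {arr.shape}")
    lum = arr.astype(np.float64) @ _LUMA_WEIGHTS
    return np.rint(lum).clip(0, 255).astype(np.uint8)


def clahe(image: np.ndarray, config: ClaheConfig | None = None) -> np.ndarray:
    """Apply CLAHE to an 8-bit grayscale image.

    The tile grid is converted to a kernel size in pixels; a grid finer than
    the image itself is reduced (with a warning) so every tile contains at
    least one pixel.  Output has the same shape and stays in [0, 255].
    """
    config = config or ClaheConfig()
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError("clahe expects a 2-D grayscale image")
    h, w = arr.shape
    rows, cols = config.tile_grid
    if rows > h or cols > w:
        rows, cols = min(rows, h), min(cols, w)
        warnings.warn(
            f"tile_grid {config.tile_grid} finer than image {arr.shape}; "
            f"reduced to {(rows, cols)}",
            stacklevel=2,
        )
    kernel = (max(1, h // rows), max(1, w // cols))
    if arr.max() == arr.min():
        # Degenerate histogram: a constant image has all mass in one bin and
        # maps to a single level; equalize_adapthist would rescale to mid-gray.
        return arr.astype(np.uint8, copy=True)
    out = exposure.equalize_adapthist(
        arr.astype(np.uint8), kernel_size=kernel, clip_limit=config.clip_limit
    )
    return np.rint(out * 255.0).clip(0, 255).astype(np.uint8)
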