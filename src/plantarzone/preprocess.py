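"""Preprocessing paths: labeling standardization and model-input preparation.

Two distinct resize paths exist and must not be confused:

* the *labeling* path scales a raw map proportionally into a 300×100 box
  (aspect preserved) and pads symmetrically with zeros to 310×110, giving
  annotators a uniform canvas with a margin;
* the *model* path min-max normalizes the raw map to [0, 1] and stretches it
  (anisotropically) to a square model-input grid — bilinear for images,
  nearest-neighbor for masks.

Every resize records a :class:`SpatialTransform` so key-point coordinates
can be mapped between raw, labeling, and model spaces at sub-pixel
precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from PIL import Image
from matplotlib import colormaps
from skimage.transform import resize as _sk_resize

from .config import (
    LABEL_FINAL_SHAPE,
    LABEL_FIT_SHAPE,
    MODEL_INPUT_SIZE,
    REGION_LABELS,
)
from .core import InputError, KeyPoint, PressureMap, RegionMaskSet, replace

__all__ = [
    "SpatialTransform",
    "standardize_for_labeling",
    "render_colormapped_png",
    "normalize_minmax",
    "resize_for_model",
    "map_point",
    "one_hot_encode",
]


@dataclass(frozen=True)
class SpatialTransform:
    """Affine record of one resize: per-axis scales followed by padding.

    Forward maps a point from source space to target space:
    ``x' = x * scale_x + pad_left``, ``y' = y * scale_y + pad_top``.
    """

    scale_y: float
    scale_x: float
    pad_top: int = 0
    pad_bottom: int = 0
    pad_left: int = 0
    pad_right: int = 0
    source_shape: tuple[int, int] = (0, 0)
    target_shape: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.scale_y <= 0 or self.scale_x <= 0:
            raise InputError("scales must be positive")
        if min(self.pad_top, self.pad_bottom, self.pad_left, self.pad_right) < 0:
            raise InputError("pads must be non-negative")


def _split_pad(total: int) -> tuple[int, int]:
    """Symmetric split of a padding amount; an odd remainder goes after."""
    before = total // 2
    return before, total - before


def standardize_for_labeling(
    pmap: PressureMap,
    fit_shape: tuple[int, int] = LABEL_FIT_SHAPE,
    final_shape: tuple[int, int] = LABEL_FINAL_SHAPE,
    blur_sigma: float = 0.0,
) -> tuple[np.ndarray, SpatialTransform]:
    """Scale a raw map proportionally into ``fit_shape`` and zero-pad to ``final_shape``.

    The scale is ``min(fit_rows/rows, fit_cols/cols)`` applied to both axes
    (aspect preserved; fractional target dimensions are floored to stay
    within the fit box), interpolation is bilinear, and the padded margins
    are split symmetrically with any odd pixel going to the bottom/right.
    Smoothing is implicit in the bilinear upsampling; ``blur_sigma`` adds an
    optional Gaussian blur on top (off by default).
    """
    rows, cols = pmap.rows, pmap.cols
    scale = min(fit_shape[0] / rows, fit_shape[1] / cols)
    out_rows = max(int(np.floor(rows * scale)), 1)
    out_cols = max(int(np.floor(cols * scale)), 1)
    resized = _sk_resize(
        pmap.grid, (out_rows, out_cols), order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    if blur_sigma > 0:
        from scipy.ndimage import gaussian_filter

        resized = gaussian_filter(resized, blur_sigma)
    pad_top, pad_bottom = _split_pad(final_shape[0] - out_rows)
    pad_left, pad_right = _split_pad(final_shape[1] - out_cols)
    if min(pad_top, pad_bottom, pad_left, pad_right) < 0:
        raise InputError(
            f"input {rows}x{cols} does not fit the target box {final_shape}"
        )
    out = np.pad(resized, ((pad_top, pad_bottom), (pad_left, pad_right)))
    transform = SpatialTransform(
        scale_y=scale, scale_x=scale,
        pad_top=pad_top, pad_bottom=pad_bottom,
        pad_left=pad_left, pad_right=pad_right,
        source_shape=(rows, cols), target_shape=final_shape,
    )
    return out.astype(float), transform


def _white_zero_jet(n: int = 256):
    """Jet-derived colormap whose lowest bin (zero pressure) is white."""
    jet = colormaps["jet"].resampled(n)
    colors = jet(np.linspace(0, 1, n))
    colors[0] = (1.0, 1.0, 1.0, 1.0)
    return colors


def render_colormapped_png(image: np.ndarray, path: str) -> None:
    """Export a pressure image as an RGB PNG with zero pressure shown white.

    No axes or colorbars are drawn; identical inputs produce byte-identical
    files. Positive values are mapped through a jet colormap scaled to the
    image maximum; exact zeros land in the white bin.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise InputError("expected a 2D image")
    if np.any(image < 0):
        raise InputError("pressure image must be non-negative")
    colors = _white_zero_jet()
    vmax = image.max()
    if vmax > 0:
        # exact zeros -> bin 0 (white); positives -> bins 1..255
        idx = np.where(
            image > 0, 1 + np.minimum((image / vmax * 254).astype(int), 254), 0
        )
    else:
        idx = np.zeros(image.shape, dtype=int)
    rgb = (colors[idx][..., :3] * 255).round().astype(np.uint8)
    Image.fromarray(rgb, mode="RGB").save(path, format="PNG", optimize=False)


def normalize_minmax(pmap: PressureMap) -> np.ndarray:
    """Per-sample min-max scaling to [0, 1], preserving relative intensities.

    A constant grid (max == min) degenerates to all zeros with a warning.
    """
    grid = pmap.grid
    lo, hi = float(grid.min()), float(grid.max())
    if hi == lo:
        warnings.warn(
            "constant pressure grid: min-max normalization returns all zeros",
            stacklevel=2,
        )
        return np.zeros_like(grid, dtype=float)
    return (grid - lo) / (hi - lo)


def resize_for_model(
    image: np.ndarray,
    masks: RegionMaskSet | None = None,
    size: int = MODEL_INPUT_SIZE,
) -> tuple[np.ndarray, RegionMaskSet | None, SpatialTransform]:
    """Stretch an image (bilinear) and masks (nearest) onto a ``size``² grid.

    Unlike the labeling path this does NOT preserve aspect ratio: the full
    input grid maps onto the square model input, and the per-axis scales are
    recorded in the returned transform.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise InputError("expected a 2D image")
    rows, cols = image.shape
    if masks is not None and masks.shape != (rows, cols):
        raise InputError(
            f"image shape {(rows, cols)} and mask shape {masks.shape} differ"
        )
    out_img = _sk_resize(
        image, (size, size), order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    ).astype(float)
    out_masks = None
    if masks is not None:
        resized = {
            lab: _sk_resize(
                masks[lab], (size, size), order=0, mode="edge",
                anti_aliasing=False, preserve_range=True,
            ).astype(np.uint8)
            for lab in REGION_LABELS
        }
        out_masks = RegionMaskSet(**resized)
    transform = SpatialTransform(
        scale_y=size / rows, scale_x=size / cols,
        source_shape=(rows, cols), target_shape=(size, size),
    )
    return out_img, out_masks, transform


def map_point(
    p: KeyPoint, t: SpatialTransform, direction: Literal["forward", "inverse"] = "forward"
) -> KeyPoint:
    """Map a key point through a recorded resize, keeping sub-pixel precision."""
    if direction == "forward":
        return replace(p, x=p.x * t.scale_x + t.pad_left, y=p.y * t.scale_y + t.pad_top)
    if direction == "inverse":
        return replace(p, x=(p.x - t.pad_left) / t.scale_x, y=(p.y - t.pad_top) / t.scale_y)
    raise InputError(f"direction must be 'forward' or 'inverse', got {direction!r}")


def one_hot_encode(masks: RegionMaskSet, size: int = MODEL_INPUT_SIZE) -> np.ndarray:
    """Stack region masks into a (size, size, 4) binary tensor.

    Channel order is the canonical ``REGION_LABELS`` order
    (hallux, met1, met_all, heel). Channels are independent binaries:
    a pixel in met1 is also set in met_all.
    """
    if masks.shape != (size, size):
        raise InputError(
            f"masks must be on a {size}x{size} grid for encoding, got {masks.shape}"
        )
    return np.stack([masks[lab] for lab in REGION_LABELS], axis=-1).astype(np.float32)
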