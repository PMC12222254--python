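"""Deterministic landmark derivation from masks.

The anatomical medial–lateral axis of the foot runs from the interdigital
space between toes 2 and 3 (id23) to the center of the heel. Because the
toes are often faint in pressure data, a surrogate landmark is used: the
point on that line at the highest position (smallest row index) still inside
the metatarsal band. This module derives both landmarks, region centers, and
the mean-of-methods ensemble point from binary or probabilistic masks.
"""

from __future__ import annotations

import numpy as np

from .config import PROB_THRESHOLD, REGION_LABELS
from .core import (
    EmptyRegionError,
    InputError,
    KeyPoint,
    NoIntersectionError,
    ProbabilityMaskSet,
    RegionMaskSet,
)

__all__ = [
    "mask_center",
    "threshold_probs",
    "shifted_interdigital",
    "ensemble_point",
    "center_met1_from_segmentation",
]


def mask_center(mask: np.ndarray, label: str = "met1_center") -> KeyPoint:
    """Robust center of a binary region: per-axis median of foreground pixels.

    The x and y medians are taken independently (even counts average the two
    middle values), which tolerates irregular shapes and yields sub-pixel
    centers. Raises :class:`EmptyRegionError` on an empty mask.
    """
    mask = np.asarray(mask)
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise EmptyRegionError("cannot compute the center of an empty mask")
    return KeyPoint(x=float(np.median(xs)), y=float(np.median(ys)), label=label)


def threshold_probs(probs: ProbabilityMaskSet, t: float = PROB_THRESHOLD) -> RegionMaskSet:
    """Binarize sigmoid outputs at threshold ``t`` (boundary inclusive, >= t)."""
    if not 0.0 < t < 1.0:
        raise InputError(f"threshold must lie in (0, 1), got {t}")
    binary = (probs.probs >= t).astype(np.uint8)
    return RegionMaskSet(**{lab: binary[..., i] for i, lab in enumerate(REGION_LABELS)})


def _segment_pixels(p0: np.ndarray, p1: np.ndarray, step: float = 0.5) -> np.ndarray:
    """Integer pixels visited by densely sampling the closed segment p0→p1.

    Samples at spacing <= ``step`` px, rounds to the nearest pixel, and
    deduplicates while preserving the order of first visit from ``p0``.
    """
    length = float(np.hypot(*(p1 - p0)))
    n = max(int(np.ceil(length / step)) + 1, 2)
    ts = np.linspace(0.0, 1.0, n)
    pts = np.rint(p0[None, :] + ts[:, None] * (p1 - p0)[None, :]).astype(int)
    _, first = np.unique(pts, axis=0, return_index=True)
    return pts[np.sort(first)]

def shifted_interdigital(
    id23: KeyPoint, heel_mask: np.ndarray, met_all_mask: np.ndarray
) -> KeyPoint:
    """Shift id23 along the line to the heel center, into the metatarsal band.

    The heel center is the per-axis median center of ``heel_mask``. A band
    pixel lies "on the line" when its center is within 0.5 px perpendicular
    distance of the id23→heel-center line and its projection falls inside
    the closed segment. Among those pixels the one with minimal row index
    ("highest" on the image) is returned, ties broken toward id23 along the
    segment. The result carries the pixel's integer coordinates as a
    continuous point.

    If the half-pixel tube contains no band pixel (a very thin diagonal
    band can slip between pixel centers), the segment is densely sampled at
    <= 0.5 px spacing and rounded to pixels as a fallback before giving up
    with :class:`NoIntersectionError`.
    """
    met_all_mask = np.asarray(met_all_mask)
    heel_center = mask_center(heel_mask, label="heel_center")
    if met_all_mask.sum() == 0:
        raise EmptyRegionError("metatarsal band mask is empty")
    p0 = id23.as_array()
    p1 = heel_center.as_array()
    length = float(np.hypot(*(p1 - p0)))
    if length == 0:
        raise NoIntersectionError("id23 coincides with the heel center")
    u = (p1 - p0) / length
    ys, xs = np.nonzero(met_all_mask)
    pts = np.stack([xs, ys], axis=1).astype(float)
    rel = pts - p0
    t = rel @ u
    perp = np.abs(rel[:, 0] * u[1] - rel[:, 1] * u[0])
    on_line = (perp <= 0.5) & (t >= 0.0) & (t <= length)
    if on_line.any():
        cand, tc = pts[on_line], t[on_line]
    else:  # fallback: Chebyshev tube via dense sampling
        rows, cols = met_all_mask.shape
        pixels = _segment_pixels(p0, p1)
        inb = (
            (pixels[:, 0] >= 0) & (pixels[:, 0] < cols)
            & (pixels[:, 1] >= 0) & (pixels[:, 1] < rows)
        )
        pixels = pixels[inb]
        hits = pixels[met_all_mask[pixels[:, 1], pixels[:, 0]] > 0]
        if hits.shape[0] == 0:
            raise NoIntersectionError(
                "the id23→heel-center segment does not intersect the metatarsal band"
            )
        cand = hits.astype(float)
        tc = (cand - p0) @ u
    top = cand[:, 1] == cand[:, 1].min()
    cand, tc = cand[top], tc[top]
    best = cand[np.argmin(tc)]
    return KeyPoint(x=float(best[0]), y=float(best[1]), label="id23_shifted")


def ensemble_point(p_seg: KeyPoint, p_reg: KeyPoint) -> KeyPoint:
    """Coordinate-wise mean of the segmentation- and regression-derived points."""
    if p_seg.label != p_reg.label:
        raise InputError(
            f"cannot ensemble points with different labels: {p_seg.label!r} vs {p_reg.label!r}"
        )
    return KeyPoint(
        x=(p_seg.x + p_reg.x) / 2.0, y=(p_seg.y + p_reg.y) / 2.0, label=p_seg.label
    )


def center_met1_from_segmentation(
    probs: ProbabilityMaskSet, t: float = PROB_THRESHOLD
) -> KeyPoint:
    """Center of the first metatarsal area from thresholded segmentation output."""
    masks = threshold_probs(probs, t)
    return mask_center(masks.met1, label="met1_center")
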