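"""Polygon/point annotations in the Labelme JSON dialect.

Records hold at most one polygon per anatomical region (hallux, met1,
met_all, heel) and optionally a single id23 point. Rasterization uses
pixel-center membership with an inclusive boundary: a pixel belongs to a
polygon if its center lies inside or on the outline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely

from .config import KNOWN_LABELS, POINT_LABELS, REGION_LABELS
from .core import EmptyRegionError, FormatError, KeyPoint, RegionMaskSet

__all__ = ["AnnotationRecord", "read_labelme", "write_labelme", "rasterize"]

_DIALECT_VERSION = "5.0.0"


@dataclass
class AnnotationRecord:
    """One rater's annotation of one image: region polygons plus the id23 point."""

    image_ref: str
    image_shape: tuple[int, int]  # (rows, cols)
    polygons: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    points: dict[str, tuple[float, float]] = field(default_factory=dict)
    rater_id: str = "rater0"

    def __post_init__(self) -> None:
        rows, cols = self.image_shape
        for label, verts in self.polygons.items():
            if label not in REGION_LABELS:
                raise FormatError(f"unknown region label {label!r}")
            if len(verts) < 3:
                raise FormatError(f"polygon {label!r} has {len(verts)} vertices (< 3)")
            for x, y in verts:
                if not (-0.5 <= x <= cols - 0.5 and -0.5 <= y <= rows - 0.5):
                    raise FormatError(
                        f"polygon {label!r} vertex ({x}, {y}) outside image {self.image_shape}"
                    )
        for label, (x, y) in self.points.items():
            if label not in POINT_LABELS:
                raise FormatError(f"unknown point label {label!r}")
            if not (-0.5 <= x <= cols - 0.5 and -0.5 <= y <= rows - 0.5):
                raise FormatError(f"point {label!r} at ({x}, {y}) outside image")

    @property
    def n_shapes(self) -> int:
        return len(self.polygons) + len(self.points)


def read_labelme(json_path: str | Path) -> AnnotationRecord:
    """Parse a Labelme-dialect JSON file into an :class:`AnnotationRecord`.

    Labels are validated against the five known labels; unknown labels,
    missing image size, or duplicate shapes raise :class:`FormatError`
    naming the offending field.
    """
    path = Path(json_path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: malformed JSON ({exc})") from exc
    for key in ("imageHeight", "imageWidth", "shapes"):
        if key not in payload:
            raise FormatError(f"{path}: missing required field {key!r}")
    rows, cols = int(payload["imageHeight"]), int(payload["imageWidth"])
    polygons: dict[str, list[tuple[float, float]]] = {}
    points: dict[str, tuple[float, float]] = {}
    for i, shape in enumerate(payload["shapes"]):
        label = shape.get("label")
        if label not in KNOWN_LABELS:
            raise FormatError(
                f"{path}: shapes[{i}].label = {label!r} is not one of {KNOWN_LABELS}"
            )
        stype = shape.get("shape_type", "polygon")
        pts = [(float(x), float(y)) for x, y in shape.get("points", [])]
        if stype == "polygon":
            if label in polygons:
                raise FormatError(f"{path}: duplicate polygon for label {label!r}")
            polygons[label] = pts
        elif stype == "point":
            if len(pts) != 1:
                raise FormatError(f"{path}: shapes[{i}] point must have exactly 1 vertex")
            if label in points:
                raise FormatError(f"{path}: duplicate point for label {label!r}")
            points[label] = pts[0]
        else:
            raise FormatError(f"{path}: shapes[{i}].shape_type = {stype!r} unsupported")
    return AnnotationRecord(
        image_ref=str(payload.get("imagePath", path.stem)),
        image_shape=(rows, cols),
        polygons=polygons,
        points=points,
        rater_id=str(payload.get("rater_id", "rater0")),
    )


def write_labelme(rec: AnnotationRecord, path: str | Path) -> None:
    """Serialize a record as Labelme-dialect JSON with stable key ordering."""
    shapes = []
    for label in REGION_LABELS:  # canonical order keeps output byte-stable
        if label in rec.polygons:
            shapes.append(
                {
                    "label": label,
                    "points": [[float(x), float(y)] for x, y in rec.polygons[label]],
                    "shape_type": "polygon",
                }
            )
    for label in POINT_LABELS:
        if label in rec.points:
            x, y = rec.points[label]
            shapes.append(
                {"label": label, "points": [[float(x), float(y)]], "shape_type": "point"}
            )
    payload = {
        "version": _DIALECT_VERSION,
        "imagePath": rec.image_ref,
        "imageHeight": int(rec.image_shape[0]),
        "imageWidth": int(rec.image_shape[1]),
        "rater_id": rec.rater_id,
        "shapes": shapes,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _fill_polygon(verts: list[tuple[float, float]], shape: tuple[int, int]) -> np.ndarray:
    """Boundary-inclusive pixel-center fill of one polygon on an image grid."""
    poly = shapely.Polygon(verts)
    if poly.area == 0:
        raise EmptyRegionError("degenerate polygon (zero area) rasterizes to nothing")
    rows, cols = shape
    minx, miny, maxx, maxy = poly.bounds
    x0, x1 = max(int(np.floor(minx)), 0), min(int(np.ceil(maxx)), cols - 1)
    y0, y1 = max(int(np.floor(miny)), 0), min(int(np.ceil(maxy)), rows - 1)
    mask = np.zeros(shape, dtype=np.uint8)
    if x1 < x0 or y1 < y0:
        raise EmptyRegionError("polygon lies fully outside the image grid")
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    inside = shapely.intersects_xy(poly, xs.ravel(), ys.ravel())
    mask[ys.ravel()[inside], xs.ravel()[inside]] = 1
    if mask.sum() == 0:
        raise EmptyRegionError("polygon covers no pixel centers")
    return mask


def rasterize(rec: AnnotationRecord) -> tuple[RegionMaskSet, KeyPoint | None]:
    """Rasterize a record into binary region masks plus the id23 point.

    Every region must carry a polygon; the id23 point, if present, passes
    through as a continuous coordinate.
    """
    masks = {}
    for label in REGION_LABELS:
        if label not in rec.polygons:
            raise FormatError(f"record is missing a polygon for region {label!r}")
        masks[label] = _fill_polygon(rec.polygons[label], rec.image_shape)
    id23 = None
    if "id23" in rec.points:
        x, y = rec.points["id23"]
        id23 = KeyPoint(x=x, y=y, label="id23")
    return RegionMaskSet(**masks), id23
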