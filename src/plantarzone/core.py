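"""Core domain types and exceptions shared across the pipeline.

Coordinate convention: 0-based, ``x`` is the column index (rightward),
``y`` is the row index (downward). Pressure maps are oriented with the toes
at the top (low ``y``) and the heel at the bottom, so an anatomically
"higher" location has a *smaller* ``y``. Coordinates are continuous
(sub-pixel); pixel centers sit at integer coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .config import KEYPOINT_LABELS, REGION_LABELS

__all__ = [
    "PlantarZoneError",
    "InputError",
    "FormatError",
    "GenerationError",
    "EmptyRegionError",
    "NoIntersectionError",
    "KeyPoint",
    "PressureMap",
    "RegionMaskSet",
    "ProbabilityMaskSet",
    "replace",
]


class PlantarZoneError(Exception):
    """Base class for all package-specific failures."""


class InputError(PlantarZoneError, ValueError):
    """An operation received structurally invalid input."""


class FormatError(PlantarZoneError, ValueError):
    """An annotation file violates the expected dialect."""


class GenerationError(PlantarZoneError, RuntimeError):
    """Phantom geometry became degenerate (e.g. blobs out of bounds)."""


class EmptyRegionError(PlantarZoneError, ValueError):
    """A mask expected to be non-empty contained no foreground."""


class NoIntersectionError(PlantarZoneError, RuntimeError):
    """The id23→heel-center segment never enters the metatarsal band."""


@dataclass(frozen=True)
class KeyPoint:
    """A continuous pixel coordinate with an anatomical label."""

    x: float
    y: float
    label: str = "id23"

    def __post_init__(self) -> None:
        if self.label not in KEYPOINT_LABELS:
            raise InputError(
                f"unknown key-point label {self.label!r}; expected one of {KEYPOINT_LABELS}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass
class PressureMap:
    """A raw 2D plantar pressure grid with acquisition metadata.

    ``grid`` holds non-negative pressure magnitudes in device units; for
    dynamic trials it is the per-pixel peak over one stride, so a single
    image summarizes the recording.
    """

    grid: np.ndarray
    subject_id: str = "unknown"
    side: Literal["left", "right"] = "right"
    condition: Literal["static", "dynamic"] = "static"
    device_id: str = "A"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2 or self.grid.size == 0:
            raise InputError("pressure grid must be a non-empty 2D array")
        if np.any(self.grid < 0):
            raise InputError("pressure values must be non-negative")
        if not np.any(self.grid > 0):
            raise InputError("pressure grid must contain at least one positive value")

    @property
    def rows(self) -> int:
        return self.grid.shape[0]

    @property
    def cols(self) -> int:
        return self.grid.shape[1]


@dataclass
class RegionMaskSet:
    """Co-registered binary masks for the four anatomical zones.

    ``met1`` (first metatarsal head) is by construction a subset of
    ``met_all`` (all five metatarsal heads); the channels are therefore not
    mutually exclusive.
    """

    hallux: np.ndarray
    met1: np.ndarray
    met_all: np.ndarray
    heel: np.ndarray

    def __post_init__(self) -> None:
        shapes = {np.asarray(m).shape for m in self.as_tuple()}
        if len(shapes) != 1:
            raise InputError(f"masks must share one grid shape, got {shapes}")
        for name in REGION_LABELS:
            m = np.asarray(getattr(self, name))
            if m.ndim != 2:
                raise InputError(f"mask {name!r} must be 2D")
            if not np.isin(m, (0, 1)).all():
                raise InputError(f"mask {name!r} must be binary (0/1)")
            setattr(self, name, m.astype(np.uint8))

    def as_tuple(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        return (self.hallux, self.met1, self.met_all, self.heel)

    def __getitem__(self, label: str) -> np.ndarray:
        if label not in REGION_LABELS:
            raise InputError(f"unknown region label {label!r}")
        return getattr(self, label)

    @property
    def shape(self) -> tuple[int, int]:
        return self.hallux.shape


@dataclass
class ProbabilityMaskSet:
    """Per-pixel sigmoid outputs, one channel per region in canonical order."""

    probs: np.ndarray  # (rows, cols, 4) in [0, 1]

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 3 or self.probs.shape[-1] != len(REGION_LABELS):
            raise InputError(
                f"probability set must be (rows, cols, {len(REGION_LABELS)}), "
                f"got {self.probs.shape}"
            )
        if self.probs.min() < 0 or self.probs.max() > 1:
            raise InputError("probabilities must lie in [0, 1]")

    def channel(self, label: str) -> np.ndarray:
        return self.probs[..., REGION_LABELS.index(label)]

    @property
    def shape(self) -> tuple[int, int]:
        return self.probs.shape[:2]


@dataclass(frozen=True)
class MetricSummary:
    """Robust summary of one metric over samples.

    ``mad`` is the raw median absolute deviation (no normal-consistency
    scaling); the CI is a percentile bootstrap of the median.
    """

    metric_name: str
    n: int
    median: float
    mad: float
    ci_low: float
    ci_high: float
    seed: int | None = None
    n_boot: int = field(default=1000, compare=False)
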