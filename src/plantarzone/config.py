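"""Package-wide constants and run configuration.

Every fixed convention of the pipeline is pinned here so that outputs are
bit-stable across runs: region label vocabulary, one-hot channel order,
standardization target sizes, simulated device grids, and cohort composition
proportions.
"""

from __future__ import annotations

import logging
from typing import Any

import yaml

#: Region labels in canonical order; this IS the one-hot channel order.
#: Channels are independent binaries (met1 overlaps met_all), not a partition.
REGION_LABELS: tuple[str, ...] = ("hallux", "met1", "met_all", "heel")

#: Point labels understood by the annotation reader.
POINT_LABELS: tuple[str, ...] = ("id23",)

#: All labels a Labelme-dialect record may carry.
KNOWN_LABELS: tuple[str, ...] = REGION_LABELS + POINT_LABELS

#: Key-point labels used throughout the pipeline.
KEYPOINT_LABELS: tuple[str, ...] = ("id23", "id23_shifted", "met1_center", "heel_center")

#: Labeling-standardization path: aspect-preserving fit box and padded size.
LABEL_FIT_SHAPE: tuple[int, int] = (300, 100)   # (rows, cols)
LABEL_FINAL_SHAPE: tuple[int, int] = (310, 110)

#: Model-input side length (square). The scaled-down experiments use 128.
MODEL_INPUT_SIZE: int = 256

#: Probability threshold applied to sigmoid outputs before mask metrics.
PROB_THRESHOLD: float = 0.5

#: Simulated sensor grids (rows, cols) of the two measurement devices.
DEVICE_RESOLUTIONS: dict[str, tuple[int, int]] = {"A": (128, 48), "B": (96, 40)}

#: Cohort composition: fraction of samples recorded standing still.
STATIC_FRACTION: float = 0.53

#: Bootstrap resamples for the 95% CI of the median.
N_BOOTSTRAP: int = 1000

logger = logging.getLogger("plantarzone")


def setup_logging(level: int = logging.INFO, logfile: str | None = None) -> None:
    """Configure console (and optional file) logging for CLI runs."""
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


def load_run_config(path: str) -> dict[str, Any]:
    """Load a YAML run configuration and return it as a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"run config {path!r} must be a YAML mapping")
    return cfg


def dump_run_config(cfg: dict[str, Any]) -> str:
    """Serialize a resolved run configuration for the audit log."""
    return yaml.safe_dump(cfg, sort_keys=True)
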