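"""Synthetic plantar-pressure phantom with exact ground truth.

The phantom emulates the statistical structure of a multicenter plantar
pressure dataset — per-subject left/right feet, static and dynamic trials,
two sensor grids, arch variation, partially visible toes — while providing
exact zone masks and landmark coordinates for every sample.

The foot template is a 2D Gaussian-mixture blob layout (heel ellipse at the
bottom, five metatarsal-head lobes in a band, hallux blob top-medial, small
toe blobs at the top). Ground-truth masks are level sets of the *noiseless,
unblurred* component intensities, while the rendered pressure image applies
per-region boundary blur. The blur ordering (heel crispest, first metatarsal
most diffuse) makes the heel the easiest region to segment and metatarsal
area 1 the hardest, mirroring how real pressure data behave: the first
metatarsal head has no distinct pressure boundary of its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import shapely
from scipy import ndimage

from .annotations import AnnotationRecord, rasterize, read_labelme, write_labelme
from .config import DEVICE_RESOLUTIONS, REGION_LABELS, STATIC_FRACTION
from .core import (
    GenerationError,
    InputError,
    KeyPoint,
    PressureMap,
    RegionMaskSet,
)
from .geometry import mask_center, shifted_interdigital

__all__ = [
    "PhantomParams",
    "PhantomSample",
    "sample_phantom_params",
    "generate_foot",
    "generate_cohort",
    "perturb_annotation",
    "save_cohort",
    "load_cohort",
]

# ---------------------------------------------------------------------------
# Template constants (fractions of foot length L / width W, right foot;
# the medial border is on the LEFT of the image for a right foot).
# Each component: (u_center, v_center, sigma_u, sigma_v, amplitude).

_COMPONENTS: dict[str, tuple[float, float, float, float, float]] = {
    "hallux": (0.09, 0.22, 0.068, 0.118, 0.85),
    "toe2": (0.055, 0.35, 0.030, 0.045, 0.45),
    "toe3": (0.065, 0.49, 0.028, 0.042, 0.40),
    "toe4": (0.085, 0.64, 0.026, 0.040, 0.35),
    "toe5": (0.110, 0.79, 0.025, 0.038, 0.30),
    "met1": (0.300, 0.24, 0.075, 0.105, 1.00),
    "met2": (0.270, 0.42, 0.065, 0.085, 0.95),
    "met3": (0.270, 0.56, 0.063, 0.080, 0.88),
    "met4": (0.280, 0.70, 0.060, 0.075, 0.80),
    "met5": (0.300, 0.82, 0.058, 0.070, 0.72),
    "midfoot": (0.550, 0.45, 0.160, 0.160, 0.50),
    "heel": (0.820, 0.52, 0.095, 0.140, 1.00),
}

#: Extra boundary blur (px) applied to the rendered image per component
#: class. The heel keeps the crispest boundary and met1 the most diffuse,
#: which fixes the expected segmentation difficulty ordering.
_REGION_BLUR_PX: dict[str, float] = {
    "heel": 0.0,
    "met_all": 1.8,
    "hallux": 0.4,
    "met1": 4.0,
    "toes": 0.8,
    "midfoot": 2.0,
}

#: Fixed level-set thresholds (normalized intensity units) for the crisp
#: regions. The metatarsal thresholds are drawn per sample instead (below):
#: the first metatarsal head has no intensity boundary of its own, so its
#: annotated extent varies between raters; that aleatoric spread is emulated
#: by jittering the level defining the truth mask while the rendered image
#: stays driven by the same lobes.
_MASK_THRESHOLDS: dict[str, float] = {"hallux": 0.30, "heel": 0.30}

#: Per-sample threshold ranges for the ambiguous metatarsal regions.
#: met1's lower bound equals met_all's upper bound, so met1 ⊆ met_all always.
_MET_ALL_THRESHOLD_RANGE = (0.28, 0.33)
_MET1_THRESHOLD_RANGE = (0.33, 0.55)

#: Std. dev. (px) of the per-sample displacement of the met1 truth-mask
#: lobe (clipped at ±2.5 px); position disagreement between annotators.
_MET1_CENTER_JITTER_PX = 1.2

_DYNAMIC_PEAK_FACTOR = 1.35
_DYNAMIC_SHARPNESS = 0.85  # dynamic lobes are sharper (smaller sigma)


@dataclass(frozen=True)
class PhantomParams:
    """Generation parameters of one synthetic foot.

    ``arch_factor`` interpolates between a flat arch (0: pronounced midfoot
    pressure) and a high arch (1: midfoot gap). ``toe_visibility`` carries
    per-toe presence probabilities for toes 2–5; toe 2 is forced visible so
    the id23 landmark is always defined.
    """

    foot_length_px: int
    foot_width_px: int
    arch_factor: float
    toe_visibility: tuple[float, float, float, float] = (1.0, 0.8, 0.8, 0.8)
    hallux_scale: float = 1.0
    peak_pressure: float = 100.0
    noise_sd: float = 1.0
    side: Literal["left", "right"] = "right"
    condition: Literal["static", "dynamic"] = "static"
    device_resolution: tuple[int, int] = DEVICE_RESOLUTIONS["A"]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.foot_length_px <= 0 or self.foot_width_px <= 0:
            raise InputError("foot dimensions must be positive")
        if self.foot_length_px <= self.foot_width_px:
            raise InputError("foot_length_px must exceed foot_width_px")
        if not 0.0 <= self.arch_factor <= 1.0:
            raise InputError("arch_factor must lie in [0, 1]")
        if self.hallux_scale <= 0 or self.peak_pressure <= 0:
            raise InputError("hallux_scale and peak_pressure must be positive")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be non-negative")


@dataclass
class PhantomSample:
    """One generated foot: pressure image, exact masks, exact landmarks."""

    pressure: PressureMap
    truth_masks: RegionMaskSet
    truth_points: dict[str, KeyPoint]
    subject_id: str
    params: PhantomParams
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not self.sample_id:
            self.sample_id = (
                f"{self.subject_id}_{self.params.side}_{self.params.condition}"
            )


def sample_phantom_params(
    rng_seed: int, device_id: Literal["A", "B"] = "A"
) -> PhantomParams:
    """Draw a random but plausible parameter set for one subject's foot.

    Deterministic for a fixed seed. ``device_id`` selects one of the two
    configured sensor grids.
    """
    if device_id not in DEVICE_RESOLUTIONS:
        raise InputError(f"unknown device {device_id!r}")
    rows, cols = DEVICE_RESOLUTIONS[device_id]
    rng = np.random.default_rng(rng_seed)
    return PhantomParams(
        foot_length_px=int(round(rng.uniform(0.62, 0.92) * rows)),
        foot_width_px=int(round(rng.uniform(0.52, 0.80) * cols)),
        arch_factor=float(rng.uniform(0.0, 1.0)),
        toe_visibility=(1.0, *(float(v) for v in np.round(rng.uniform(0.5, 1.0, size=3), 4))),
        hallux_scale=float(rng.uniform(0.85, 1.20)),
        peak_pressure=float(rng.uniform(80.0, 120.0)),
        noise_sd=float(rng.uniform(0.5, 2.5)),
        side="right",
        condition="static",
        device_resolution=(rows, cols),
        seed=int(rng_seed),
    )


def _component_field(
    shape: tuple[int, int],
    center: tuple[float, float],
    sigma: tuple[float, float],
    amp: float,
) -> np.ndarray:
    """Anisotropic Gaussian blob evaluated on the pixel grid (rows, cols)."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    cy, cx = center
    sy, sx = sigma
    return amp * np.exp(-0.5 * (((yy - cy) / sy) ** 2 + ((xx - cx) / sx) ** 2))


def _blur_class(name: str) -> str:
    if name.startswith("toe"):
        return "toes"
    if name in ("met2", "met3", "met4", "met5"):
        return "met_all"
    return name


def generate_foot(params: PhantomParams) -> PhantomSample:
    """Render one synthetic foot and derive its exact ground truth.

    The right-foot template is laid out in a centered foot box, rendered as
    a sum of blurred Gaussian lobes scaled by peak pressure, with additive
    Gaussian noise clipped at zero. Masks are level sets of the unblurred
    components; a left foot is the exact horizontal mirror of the right
    foot generated from the same parameters.
    """
    rows, cols = params.device_resolution
    L, W = params.foot_length_px, params.foot_width_px
    if L > 0.95 * rows or W > 0.95 * cols:
        raise GenerationError(
            f"foot box {L}x{W} does not fit device grid {rows}x{cols}"
        )
    row0 = (rows - L) / 2.0
    col0 = (cols - W) / 2.0
    rng = np.random.default_rng(params.seed)

    # Per-sample toe visibility (toe 2 forced on).
    toe_draws = rng.uniform(size=4)
    visible = {
        "toe2": True,
        "toe3": bool(toe_draws[1] < params.toe_visibility[1]),
        "toe4": bool(toe_draws[2] < params.toe_visibility[2]),
        "toe5": bool(toe_draws[3] < params.toe_visibility[3]),
    }
    # Per-sample annotation-convention jitter for the ambiguous regions:
    # the truth level-set threshold varies, and the met1 lobe used for the
    # MASK is displaced slightly, emulating disagreement about where the
    # first metatarsal head region sits. The rendered image is unchanged.
    theta_met_all = float(rng.uniform(*_MET_ALL_THRESHOLD_RANGE))
    theta_met1 = float(rng.uniform(*_MET1_THRESHOLD_RANGE))
    met1_shift = rng.normal(0.0, _MET1_CENTER_JITTER_PX, size=2)
    met1_shift = np.clip(met1_shift, -2.5, 2.5)

    sharp = _DYNAMIC_SHARPNESS if params.condition == "dynamic" else 1.0
    peak = params.peak_pressure * (
        _DYNAMIC_PEAK_FACTOR if params.condition == "dynamic" else 1.0
    )

    shape = (rows, cols)
    image = np.zeros(shape, dtype=float)
    clean: dict[str, np.ndarray] = {}
    for name, (u, v, su, sv, amp) in _COMPONENTS.items():
        if name.startswith("toe") and not visible.get(name, True):
            continue
        if name == "midfoot":
            amp = amp * (1.0 - params.arch_factor)
            if amp <= 0:
                continue
        scale = params.hallux_scale if name == "hallux" else 1.0
        cy, cx = row0 + u * L, col0 + v * W
        sy, sx = su * L * scale, sv * W * scale
        if name in ("hallux", "met1", "heel") or name.startswith("met"):
            clean[name] = _component_field(shape, (cy, cx), (sy, sx), amp)
        if name == "met1":
            clean["met1_mask_field"] = _component_field(
                shape, (cy + met1_shift[0], cx + met1_shift[1]), (sy, sx), amp
            )
        # image uses blurred lobes: variance adds in quadrature, peak
        # rescaled to conserve the lobe integral
        b = _REGION_BLUR_PX[_blur_class(name)]
        sy_b, sx_b = np.hypot(sy * sharp, b), np.hypot(sx * sharp, b)
        amp_b = amp * (sy * sx * sharp * sharp) / (sy_b * sx_b)
        image += _component_field(shape, (cy, cx), (sy_b, sx_b), amp_b)

    met_all_mask = (
        sum(clean[f"met{i}"] for i in range(1, 6)) >= theta_met_all
    ).astype(np.uint8)
    masks = {
        "hallux": (clean["hallux"] >= _MASK_THRESHOLDS["hallux"]).astype(np.uint8),
        "heel": (clean["heel"] >= _MASK_THRESHOLDS["heel"]).astype(np.uint8),
        # intersecting with the band keeps met1 ⊆ met_all despite the shift
        "met1": ((clean["met1_mask_field"] >= theta_met1) & (met_all_mask > 0)).astype(
            np.uint8
        ),
        "met_all": met_all_mask,
    }
    for name, m in masks.items():
        if m.sum() == 0:
            raise GenerationError(f"degenerate geometry: empty {name!r} mask")
        n_comp = ndimage.label(m)[1]
        if n_comp != 1:
            raise GenerationError(
                f"degenerate geometry: {name!r} mask split into {n_comp} components"
            )

    # id23: between toes 2 and 3, at the middle height of toe 2.
    t2, t3 = _COMPONENTS["toe2"], _COMPONENTS["toe3"]
    id23 = KeyPoint(
        x=col0 + 0.5 * (t2[1] + t3[1]) * W, y=row0 + t2[0] * L, label="id23"
    )

    image = image * peak
    if params.noise_sd > 0:
        image = image + rng.normal(0.0, params.noise_sd, size=shape)
    image = np.clip(image, 0.0, None)

    if params.side == "left":
        image = image[:, ::-1].copy()
        masks = {k: m[:, ::-1].copy() for k, m in masks.items()}
        id23 = replace(id23, x=(cols - 1) - id23.x)

    mask_set = RegionMaskSet(**masks)
    points = {
        "id23": id23,
        "heel_center": mask_center(mask_set.heel, label="heel_center"),
        "met1_center": mask_center(mask_set.met1, label="met1_center"),
        "id23_shifted": shifted_interdigital(id23, mask_set.heel, mask_set.met_all),
    }
    pmap = PressureMap(
        grid=image,
        subject_id="unassigned",
        side=params.side,
        condition=params.condition,
        device_id="A" if params.device_resolution == DEVICE_RESOLUTIONS["A"] else "B",
    )
    return PhantomSample(
        pressure=pmap,
        truth_masks=mask_set,
        truth_points=points,
        subject_id="unassigned",
        params=params,
    )


def generate_cohort(n_subjects: int, seed: int = 0) -> list[PhantomSample]:
    """Generate a deterministic multicenter-style cohort.

    Each subject contributes 2–4 samples sharing one subject identifier and
    one (side-mirrored) foot geometry: at least a left/right pair, with
    additional repeat trials for some subjects. Devices alternate evenly;
    conditions are drawn per sample at the configured static fraction.
    """
    if n_subjects < 1:
        raise InputError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    cohort: list[PhantomSample] = []
    for i in range(n_subjects):
        subject_id = f"S{i:04d}"
        device = "A" if rng.uniform() < 0.5 else "B"
        base = sample_phantom_params(int(rng.integers(2**31)), device)
        n_samples = int(rng.choice([2, 3, 4], p=[0.4, 0.3, 0.3]))
        sides = ["left", "right"] * 2
        for j in range(n_samples):
            cond = "static" if rng.uniform() < STATIC_FRACTION else "dynamic"
            params_j = replace(
                base, side=sides[j], condition=cond, seed=int(rng.integers(2**31))
            )
            sample = generate_foot(params_j)
            sample.subject_id = subject_id
            sample.pressure.subject_id = subject_id
            sample.sample_id = f"{subject_id}_{j}_{params_j.side}_{cond}"
            cohort.append(sample)
    return cohort


# ---------------------------------------------------------------------------
# Simulated raters


def _trace_mask_polygon(mask: np.ndarray) -> list[tuple[float, float]]:
    """Exact boundary polygon of a pixel set, vertices at pixel corners.

    The polygon rasterizes back to exactly ``mask`` under the
    boundary-inclusive pixel-center fill used by :func:`annotations.rasterize`.
    """
    ys, xs = np.nonzero(mask)
    boxes = [shapely.box(x - 0.5, y - 0.5, x + 0.5, y + 0.5) for x, y in zip(xs, ys)]
    merged = shapely.unary_union(boxes)
    if merged.geom_type == "MultiPolygon":
        merged = max(merged.geoms, key=lambda g: g.area)
    return [(float(x), float(y)) for x, y in merged.exterior.coords[:-1]]


def perturb_annotation(
    sample: PhantomSample, rater_noise_px: float, seed: int = 0
) -> AnnotationRecord:
    """Simulate one human rater annotating a phantom sample.

    Region outlines are traced from the truth masks and their vertices
    jittered by zero-mean Gaussian noise of scale ``rater_noise_px``; the
    id23 point is jittered the same way. At zero noise the rasterized
    record reproduces the truth masks exactly.
    """
    if rater_noise_px < 0:
        raise InputError("rater_noise_px must be non-negative")
    rows, cols = sample.truth_masks.shape
    rng = np.random.default_rng(seed)
    polygons: dict[str, list[tuple[float, float]]] = {}
    for label in REGION_LABELS:
        verts = _trace_mask_polygon(sample.truth_masks[label])
        if rater_noise_px > 0:
            poly = shapely.Polygon(verts).simplify(0.7)
            pts = np.array(poly.exterior.coords[:-1], dtype=float)
            pts = pts + rng.normal(0.0, rater_noise_px, size=pts.shape)
            fixed = shapely.Polygon(pts).buffer(0)  # repair self-intersections
            if fixed.geom_type == "MultiPolygon":
                fixed = max(fixed.geoms, key=lambda g: g.area)
            verts = [
                (
                    float(np.clip(x, -0.5, cols - 0.5)),
                    float(np.clip(y, -0.5, rows - 0.5)),
                )
                for x, y in fixed.exterior.coords[:-1]
            ]
        polygons[label] = verts
    p = sample.truth_points["id23"]
    jitter = rng.normal(0.0, rater_noise_px, size=2) if rater_noise_px > 0 else (0, 0)
    points = {
        "id23": (
            float(np.clip(p.x + jitter[0], -0.5, cols - 0.5)),
            float(np.clip(p.y + jitter[1], -0.5, rows - 0.5)),
        )
    }
    return AnnotationRecord(
        image_ref=sample.sample_id,
        image_shape=(rows, cols),
        polygons=polygons,
        points=points,
        rater_id=f"sim_rater_{seed}",
    )


# ---------------------------------------------------------------------------
# Serialization


def save_cohort(cohort: list[PhantomSample], out_dir: str | Path) -> Path:
    """Write a cohort to disk: pressure arrays, truth annotations, manifest.

    Layout: ``<out_dir>/pressure/<sample_id>.npy``,
    ``<out_dir>/annotations/<sample_id>.json`` (Labelme dialect),
    ``<out_dir>/keypoints.csv`` and ``<out_dir>/manifest.csv``.
    """
    import pandas as pd

    out = Path(out_dir)
    (out / "pressure").mkdir(parents=True, exist_ok=True)
    (out / "annotations").mkdir(parents=True, exist_ok=True)
    manifest_rows, kp_rows = [], []
    for s in cohort:
        ppath = out / "pressure" / f"{s.sample_id}.npy"
        apath = out / "annotations" / f"{s.sample_id}.json"
        np.save(ppath, s.pressure.grid)
        write_labelme(perturb_annotation(s, 0.0), apath)
        for label, kp in s.truth_points.items():
            kp_rows.append(
                {"sample_id": s.sample_id, "label": label, "x": kp.x, "y": kp.y}
            )
        manifest_rows.append(
            {
                "sample_id": s.sample_id,
                "subject_id": s.subject_id,
                "side": s.params.side,
                "condition": s.params.condition,
                "device_id": s.pressure.device_id,
                "pressure_path": str(ppath.relative_to(out)),
                "annotation_path": str(apath.relative_to(out)),
            }
        )
    pd.DataFrame(manifest_rows).to_csv(out / "manifest.csv", index=False)
    pd.DataFrame(kp_rows).to_csv(out / "keypoints.csv", index=False)
    return out / "manifest.csv"


def load_cohort(cohort_dir: str | Path) -> list:
    """Load a saved cohort as sample views (pressure, masks, points, ids)."""
    from types import SimpleNamespace

    import pandas as pd

    root = Path(cohort_dir)
    manifest = pd.read_csv(root / "manifest.csv")
    kps = pd.read_csv(root / "keypoints.csv")
    out = []
    for _, row in manifest.iterrows():
        grid = np.load(root / row["pressure_path"])
        pmap = PressureMap(
            grid=grid,
            subject_id=row["subject_id"],
            side=row["side"],
            condition=row["condition"],
            device_id=row["device_id"],
        )
        rec = read_labelme(root / row["annotation_path"])
        masks, _ = rasterize(rec)
        sub = kps[kps["sample_id"] == row["sample_id"]]
        points = {
            r["label"]: KeyPoint(x=r["x"], y=r["y"], label=r["label"])
            for _, r in sub.iterrows()
        }
        out.append(
            SimpleNamespace(
                pressure=pmap,
                truth_masks=masks,
                truth_points=points,
                subject_id=row["subject_id"],
                sample_id=row["sample_id"],
            )
        )
    return out
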