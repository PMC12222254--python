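"""Evaluation protocol: grouped 5-fold CV, overlap/distance metrics, robust
summaries, and the inter-rater reliability harness.

All samples of one subject (left/right feet, static/dynamic trials) stay in
the same partition role within every fold, so no participant identity leaks
between training and testing. Metrics are summarized as the median with
(unscaled) median absolute deviation and a percentile-bootstrap 95% CI of
the median.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import N_BOOTSTRAP, PROB_THRESHOLD, REGION_LABELS
from .core import InputError, KeyPoint, MetricSummary

__all__ = [
    "dice", "iou", "euclidean", "summarize",
    "FoldAssignment", "grouped_splits",
    "cross_validate", "inter_rater",
]


# ---------------------------------------------------------------------------
# Metrics


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise InputError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a.astype(bool), b.astype(bool)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient 2|A∩B|/(|A|+|B|); both-empty pairs score 1.0."""
    a, b = _check_pair(a, b)
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (sa + sb)


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union |A∩B|/|A∪B|; both-empty pairs score 1.0."""
    a, b = _check_pair(a, b)
    union = int((a | b).sum())
    if union == 0:
        return 1.0
    return int((a & b).sum()) / union


def euclidean(p: KeyPoint, q: KeyPoint) -> float:
    """Euclidean distance between two key points, in pixels."""
    return float(np.hypot(p.x - q.x, p.y - q.y))


def summarize(
    values, metric_name: str = "metric", n_boot: int = N_BOOTSTRAP, seed: int = 0
) -> MetricSummary:
    """Median, unscaled MAD, and percentile-bootstrap 95% CI of the median.

    The CI takes the 2.5/97.5 percentiles of ``n_boot`` resample medians;
    deterministic for a fixed seed.
    """
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise InputError("cannot summarize an empty list of values")
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    rng = np.random.default_rng(seed)
    boots = np.median(
        values[rng.integers(0, values.size, size=(n_boot, values.size))], axis=1
    )
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return MetricSummary(
        metric_name=metric_name, n=int(values.size), median=med, mad=mad,
        ci_low=float(min(lo, med)), ci_high=float(max(hi, med)),
        seed=seed, n_boot=n_boot,
    )


# ---------------------------------------------------------------------------
# Grouped splits


@dataclass
class FoldAssignment:
    """Role (train/val/test) of every sample in one cross-validation fold."""

    fold_index: int
    roles: list[str]  # per-sample role, aligned with the input subject_ids
    subject_ids: list[str] = field(repr=False, default_factory=list)

    def indices(self, role: str) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.roles) if r == role], dtype=int)

    def subjects(self, role: str) -> set[str]:
        return {s for s, r in zip(self.subject_ids, self.roles) if r == role}


def grouped_splits(subject_ids, k: int = 5, seed: int = 0) -> list[FoldAssignment]:
    """Grouped k-fold assignment with a train/val/test ≈ 70/10/20 split.

    Subjects are partitioned into ``k`` sample-balanced test folds; within
    each fold the remaining subjects are split so that validation holds
    about one eighth of the non-test samples (≈10% of the total). No
    subject ever appears in more than one role within a fold, and every
    sample is a test sample in exactly one fold.
    """
    subject_ids = list(subject_ids)
    subjects = sorted(set(subject_ids))
    if len(subjects) < k:
        raise InputError(f"need at least {k} distinct subjects, got {len(subjects)}")
    rng = np.random.default_rng(seed)
    counts = {s: subject_ids.count(s) for s in subjects}
    # sample-balanced partition: largest subjects first, into the lightest fold
    shuffled = list(rng.permutation(subjects))
    ordered = sorted(shuffled, key=lambda s: -counts[s])
    fold_of: dict[str, int] = {}
    loads = [0] * k
    for s in ordered:
        f = int(np.argmin(loads))
        fold_of[s] = f
        loads[f] += counts[s]

    folds = []
    for f in range(k):
        rest = [s for s in subjects if fold_of[s] != f]
        rest = list(rng.permutation(rest))
        n_rest_samples = sum(counts[s] for s in rest)
        val_target = n_rest_samples / 8.0  # 10% of total ≈ 1/8 of the 80% remainder
        val_set: set[str] = set()
        acc = 0
        for s in rest:
            if acc >= val_target:
                break
            val_set.add(s)
            acc += counts[s]
        roles = [
            "test" if fold_of[s] == f else ("val" if s in val_set else "train")
            for s in subject_ids
        ]
        folds.append(FoldAssignment(fold_index=f, roles=roles, subject_ids=subject_ids))
    return folds


# ---------------------------------------------------------------------------
# End-to-end cross-validation

#: Row labels of the key-point report, in canonical order.
KEYPOINT_METHODS = (
    "met1_center_via_segmentation",
    "met1_center_via_regression",
    "met1_center_ensemble",
    "id23",
    "id23_shifted",
)

_REGRESSION_TARGETS = ("met1_center", "id23", "id23_shifted")


def _prepare_inputs(cohort, input_size: int):
    """Normalize, resize, and encode a phantom cohort for model training."""
    from .preprocess import map_point, normalize_minmax, one_hot_encode, resize_for_model

    images, targets, points, subject_ids = [], [], [], []
    for sample in cohort:
        norm = normalize_minmax(sample.pressure)
        img, masks, transform = resize_for_model(
            norm, sample.truth_masks, size=input_size
        )
        images.append(img.astype(np.float32))
        targets.append(one_hot_encode(masks, size=input_size))
        points.append(
            {
                lab: map_point(kp, transform, "forward")
                for lab, kp in sample.truth_points.items()
            }
        )
        subject_ids.append(sample.subject_id)
    return np.stack(images), np.stack(targets), points, subject_ids


def cross_validate(
    cohort,
    seg_cfg=None,
    reg_cfg=None,
    seed: int = 0,
    k: int = 5,
    folds: list[int] | None = None,
    pool_mode: str = "samples",
) -> dict:
    """Run the full grouped-CV evaluation of segmentation and key points.

    Per fold: train the U-Net on the train split, train the three landmark
    regressors on frozen bottleneck features, then on the test split compute
    per-region Dice/IoU (after 0.5 thresholding) and Euclidean distances for
    the five key-point methods (met1 center via segmentation / regression /
    ensemble, id23, shifted id23). Test-set values are pooled across folds
    (``pool_mode='samples'``) or reduced to per-fold medians
    (``pool_mode='folds'``) before robust summarization.

    Samples whose thresholded met1 channel is empty are counted as
    segmentation failures and excluded from the distance rows. ``folds``
    optionally restricts the run to a subset of fold indices.
    """
    from . import models
    from .core import EmptyRegionError
    from .geometry import (
        center_met1_from_segmentation,
        ensemble_point,
        threshold_probs,
    )

    seg_cfg = seg_cfg or models.SegTrainConfig()
    reg_cfg = reg_cfg or models.RegTrainConfig()
    x, y, points, subject_ids = _prepare_inputs(cohort, seg_cfg.input_size)
    assignments = grouped_splits(subject_ids, k=k, seed=seed)
    run_folds = list(range(k)) if folds is None else list(folds)

    region_values: dict[tuple[str, str], list] = {
        (lab, m): [] for lab in REGION_LABELS for m in ("dice", "iou")
    }
    point_values: dict[str, list] = {m: [] for m in KEYPOINT_METHODS}
    per_fold: dict[int, dict] = {}
    n_empty_met1 = 0

    for f in run_folds:
        fold = assignments[f]
        tr, va, te = (fold.indices(r) for r in ("train", "val", "test"))
        train_pairs = list(zip(x[tr], y[tr]))
        val_pairs = list(zip(x[va], y[va]))
        unet, seg_hist = models.train_segmentation(train_pairs, val_pairs, seg_cfg)

        regressors = {}
        for label in _REGRESSION_TARGETS:
            reg = models.build_regression(unet, reg_cfg)
            reg_train = [(x[i], points[i][label]) for i in tr]
            reg_val = [(x[i], points[i][label]) for i in va]
            reg, _ = models.train_regression(reg, reg_train, reg_val, label, reg_cfg)
            regressors[label] = reg

        fold_regions = {key: [] for key in region_values}
        fold_points = {m: [] for m in KEYPOINT_METHODS}
        for i in te:
            probs = models.predict_probs(unet, x[i])[0]
            pred_masks = threshold_probs(probs, PROB_THRESHOLD)
            for lab in REGION_LABELS:
                truth = y[i, ..., REGION_LABELS.index(lab)].astype(np.uint8)
                fold_regions[(lab, "dice")].append(dice(pred_masks[lab], truth))
                fold_regions[(lab, "iou")].append(iou(pred_masks[lab], truth))
            reg_preds = {
                lab: models.predict_point(regressors[lab], x[i])
                for lab in _REGRESSION_TARGETS
            }
            try:
                p_seg = center_met1_from_segmentation(probs)
            except EmptyRegionError:
                n_empty_met1 += 1
                p_seg = None
            truth_met1 = points[i]["met1_center"]
            if p_seg is not None:
                fold_points["met1_center_via_segmentation"].append(
                    euclidean(p_seg, truth_met1)
                )
                fold_points["met1_center_ensemble"].append(
                    euclidean(
                        ensemble_point(p_seg, reg_preds["met1_center"]), truth_met1
                    )
                )
            fold_points["met1_center_via_regression"].append(
                euclidean(reg_preds["met1_center"], truth_met1)
            )
            fold_points["id23"].append(euclidean(reg_preds["id23"], points[i]["id23"]))
            fold_points["id23_shifted"].append(
                euclidean(reg_preds["id23_shifted"], points[i]["id23_shifted"])
            )
        for key, vals in fold_regions.items():
            region_values[key].extend(
                vals if pool_mode == "samples" else [float(np.median(vals))]
            )
        for m, vals in fold_points.items():
            if vals:
                point_values[m].extend(
                    vals if pool_mode == "samples" else [float(np.median(vals))]
                )
        per_fold[f] = {
            "n_test": len(te),
            "seg_epochs": len(seg_hist),
            "final_val_miou": seg_hist[-1]["val_miou"] if seg_hist else None,
        }

    report = {
        "segmentation": {
            lab: {
                m: summarize(region_values[(lab, m)], f"{lab}_{m}", seed=seed)
                for m in ("dice", "iou")
            }
            for lab in REGION_LABELS
        },
        "keypoints": {
            m: summarize(point_values[m], m, seed=seed)
            for m in KEYPOINT_METHODS
            if point_values[m]
        },
        "n_empty_met1": n_empty_met1,
        "folds": per_fold,
        "pool_mode": pool_mode,
    }
    return report


# ---------------------------------------------------------------------------
# Inter-rater reliability


def inter_rater(
    records_per_image: list[list],
    model_input_shape: tuple[int, int],
    seed: int = 0,
) -> dict:
    """Agreement among human raters, with the model's evaluation metrics.

    ``records_per_image`` holds, per image, the AnnotationRecords of all
    raters (>= 2; images with fewer are skipped with a warning). Records
    are rasterized, masks resized (nearest) and the id23 point rescaled to
    ``model_input_shape``; per image all rater pairs are compared
    (Dice/IoU per region, Euclidean for id23) and aggregated by the mean,
    then summarized across images.
    """
    import warnings
    from itertools import combinations

    from .annotations import rasterize
    from .preprocess import map_point, resize_for_model

    region_means: dict[tuple[str, str], list] = {
        (lab, m): [] for lab in REGION_LABELS for m in ("dice", "iou")
    }
    dist_means: list[float] = []

    for idx, records in enumerate(records_per_image):
        if len(records) < 2:
            warnings.warn(f"image {idx}: fewer than 2 rater records, skipped",
                          stacklevel=2)
            continue
        prepared = []
        for rec in records:
            masks, id23 = rasterize(rec)
            dummy = np.zeros(rec.image_shape, dtype=float)
            _, masks_rs, transform = resize_for_model(
                dummy, masks, size=model_input_shape[0]
            )
            id23_rs = map_point(id23, transform, "forward") if id23 else None
            prepared.append((masks_rs, id23_rs))
        pair_vals = {key: [] for key in region_means}
        pair_dists = []
        for (ma, pa), (mb, pb) in combinations(prepared, 2):
            for lab in REGION_LABELS:
                pair_vals[(lab, "dice")].append(dice(ma[lab], mb[lab]))
                pair_vals[(lab, "iou")].append(iou(ma[lab], mb[lab]))
            if pa is not None and pb is not None:
                pair_dists.append(euclidean(pa, pb))
        for key, vals in pair_vals.items():
            region_means[key].append(float(np.mean(vals)))
        if pair_dists:
            dist_means.append(float(np.mean(pair_dists)))

    report = {
        "segmentation": {
            lab: {
                m: summarize(region_means[(lab, m)], f"interrater_{lab}_{m}", seed=seed)
                for m in ("dice", "iou")
            }
            for lab in REGION_LABELS
            if region_means[(lab, "dice")]
        },
        "id23_distance": summarize(dist_means, "interrater_id23", seed=seed)
        if dist_means
        else None,
        "n_images": len([r for r in records_per_image if len(r) >= 2]),
    }
    return report
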