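"""Metrics, robust summaries, grouped splits, and the inter-rater harness."""

import numpy as np
import pytest

from plantarzone import evaluation, phantom
from plantarzone.core import InputError, KeyPoint
from plantarzone.evaluation import dice, euclidean, grouped_splits, iou, summarize


def _mask(shape, coords):
    m = np.zeros(shape, np.uint8)
    for y, x in coords:
        m[y, x] = 1
    return m


class TestOverlapMetrics:
    def test_identical_masks_score_one(self):
        m = _mask((5, 5), [(1, 1), (2, 2)])
        assert dice(m, m) == 1.0 and iou(m, m) == 1.0

    def test_disjoint_masks_score_zero(self):
        a = _mask((5, 5), [(0, 0), (0, 1)])
        b = _mask((5, 5), [(4, 4), (4, 3)])
        assert dice(a, b) == 0.0 and iou(a, b) == 0.0

    def test_half_overlap_closed_forms(self):
        a = _mask((5, 5), [(0, 0), (0, 1)])
        b = _mask((5, 5), [(0, 1), (0, 2)])
        assert dice(a, b) == pytest.approx(0.5)  # 2*1/(2+2)
        assert iou(a, b) == pytest.approx(1 / 3)  # 1/(2+2-1)

    def test_both_empty_convention(self):
        z = np.zeros((4, 4), np.uint8)
        assert dice(z, z) == 1.0 and iou(z, z) == 1.0

    def test_one_empty_scores_zero(self):
        z = np.zeros((4, 4), np.uint8)
        m = _mask((4, 4), [(1, 1)])
        assert dice(z, m) == 0.0 and iou(m, z) == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InputError):
            dice(np.zeros((3, 3)), np.zeros((4, 4)))

    def test_dice_iou_identity_and_symmetry_on_random_masks(self, rng):
        """Dice = 2·IoU/(1+IoU) holds pixel-for-pixel on random mask pairs."""
        for _ in range(1000):
            a = (rng.uniform(size=(12, 12)) > 0.6).astype(np.uint8)
            b = (rng.uniform(size=(12, 12)) > 0.6).astype(np.uint8)
            d, j = dice(a, b), iou(a, b)
            assert d == pytest.approx(2 * j / (1 + j))
            assert d == dice(b, a) and j == iou(b, a)
            assert d == pytest.approx(dice(a[:, ::-1], b[:, ::-1]))


class TestEuclidean:
    @pytest.mark.parametrize(
        "p,q,want",
        [
            ((0, 0), (3, 4), 5.0),
            ((2, 2), (2, 2), 0.0),
            ((1, 2), (4, 6), 5.0),
        ],
    )
    def test_closed_forms(self, p, q, want):
        a = KeyPoint(*p, "id23")
        b = KeyPoint(*q, "id23")
        assert euclidean(a, b) == pytest.approx(want)


class TestSummarize:
    def test_median_and_mad_hand_computed(self):
        s = summarize([1, 2, 3, 4, 5], seed=0)
        assert s.median == 3 and s.mad == 1
        assert s.n == 5

    def test_constant_list_degenerates(self):
        s = summarize([7.5] * 10, seed=0)
        assert s.median == 7.5 and s.mad == 0.0
        assert s.ci_low == s.ci_high == 7.5

    def test_deterministic_under_seed(self):
        vals = list(np.random.default_rng(3).normal(size=40))
        a = summarize(vals, seed=5)
        b = summarize(vals, seed=5)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_ci_contains_median(self, rng):
        for _ in range(10):
            vals = rng.normal(size=25)
            s = summarize(vals, seed=1)
            assert s.ci_low <= s.median <= s.ci_high

    def test_ci_narrows_with_sample_size(self):
        rng = np.random.default_rng(0)
        widths = []
        for n in (20, 200, 2000):
            ws = []
            for rep in range(5):
                s = summarize(rng.normal(size=n), seed=rep)
                ws.append(s.ci_high - s.ci_low)
            widths.append(np.mean(ws))
        assert widths[0] > widths[1] > widths[2]

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            summarize([])


class TestGroupedSplits:
    def _structure(self, rng, n_subjects):
        ids = []
        for i in range(n_subjects):
            ids.extend([f"S{i}"] * int(rng.integers(2, 5)))
        return ids

    def test_every_sample_tests_exactly_once(self):
        ids = self._structure(np.random.default_rng(0), 12)
        folds = grouped_splits(ids, k=5, seed=0)
        test_count = np.zeros(len(ids), dtype=int)
        for f in folds:
            test_count[f.indices("test")] += 1
        assert (test_count == 1).all()

    @pytest.mark.parametrize("seed", range(50))
    def test_no_subject_leakage_on_random_structures(self, seed):
        rng = np.random.default_rng(seed)
        ids = self._structure(rng, int(rng.integers(8, 40)))
        for f in grouped_splits(ids, k=5, seed=seed):
            tr, va, te = f.subjects("train"), f.subjects("val"), f.subjects("test")
            assert not (tr & va) and not (tr & te) and not (va & te)

    def test_role_proportions_near_70_10_20(self):
        ids = self._structure(np.random.default_rng(1), 100)
        n = len(ids)
        for f in grouped_splits(ids, k=5, seed=1):
            fr = {r: len(f.indices(r)) / n for r in ("train", "val", "test")}
            assert abs(fr["test"] - 0.20) < 0.05
            assert abs(fr["val"] - 0.10) < 0.05
            assert abs(fr["train"] - 0.70) < 0.05

    def test_too_few_subjects_rejected(self):
        with pytest.raises(InputError):
            grouped_splits(["A", "A", "B"], k=5)

    def test_deterministic(self):
        ids = self._structure(np.random.default_rng(2), 15)
        a = grouped_splits(ids, k=5, seed=9)
        b = grouped_splits(ids, k=5, seed=9)
        assert all(x.roles == y.roles for x, y in zip(a, b))


class TestInterRater:
    def _records(self, cohort, noise, n_raters=3):
        return [
            [
                phantom.perturb_annotation(s, noise, seed=1000 + 37 * r + i)
                for r in range(n_raters)
            ]
            for i, s in enumerate(cohort)
        ]

    def test_identical_raters_agree_perfectly(self, small_cohort):
        records = self._records(small_cohort[:3], 0.0)
        rep = evaluation.inter_rater(records, (128, 128), seed=0)
        for lab in ("hallux", "met1", "met_all", "heel"):
            assert rep["segmentation"][lab]["dice"].median == 1.0
            assert rep["segmentation"][lab]["iou"].median == 1.0
        assert rep["id23_distance"].median == 0.0

    def test_noise_degrades_agreement(self, small_cohort):
        lo = evaluation.inter_rater(
            self._records(small_cohort[:4], 2.0), (128, 128), seed=0
        )
        hi = evaluation.inter_rater(
            self._records(small_cohort[:4], 6.0), (128, 128), seed=0
        )
        for lab in ("hallux", "met1", "met_all", "heel"):
            assert (
                lo["segmentation"][lab]["dice"].median
                > hi["segmentation"][lab]["dice"].median
            )

    def test_images_with_single_rater_skipped(self, small_cohort):
        records = self._records(small_cohort[:2], 0.0)
        records.append([phantom.perturb_annotation(small_cohort[2], 0.0, seed=0)])
        with pytest.warns(UserWarning, match="fewer than 2"):
            rep = evaluation.inter_rater(records, (64, 64), seed=0)
        assert rep["n_images"] == 2

    def test_three_raters_yield_three_pairs(self, small_cohort):
        # mean of C(3,2)=3 pairwise distances: verify against a manual computation
        from itertools import combinations

        from plantarzone.annotations import rasterize
        from plantarzone.preprocess import map_point, resize_for_model

        recs = self._records(small_cohort[:1], 1.5)[0]
        assert len(list(combinations(recs, 2))) == 3
        rep = evaluation.inter_rater([recs], (128, 128), seed=0)
        pts = []
        for rec in recs:
            _, p = rasterize(rec)
            dummy = np.zeros(rec.image_shape)
            _, _, t = resize_for_model(dummy, size=128)
            pts.append(map_point(p, t))
        manual = np.mean(
            [evaluation.euclidean(a, b) for a, b in combinations(pts, 2)]
        )
        assert rep["id23_distance"].median == pytest.approx(manual)
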