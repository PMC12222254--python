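"""Preprocessing paths: standardization, normalization, resizing, mapping."""

import hashlib

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plantarzone.core import InputError, KeyPoint, PressureMap, RegionMaskSet
from plantarzone import preprocess
from plantarzone.preprocess import SpatialTransform


def _pmap(rows, cols, value=1.0):
    grid = np.zeros((rows, cols))
    grid[rows // 2, cols // 2] = value
    return PressureMap(grid=grid)


class TestStandardizeForLabeling:
    @pytest.mark.parametrize(
        "shape,scale,pads",
        [
            ((150, 50), 2.0, (5, 5, 5, 5)),
            ((300, 100), 1.0, (5, 5, 5, 5)),
            ((600, 100), 0.5, (5, 5, 30, 30)),
        ],
    )
    def test_known_scales_and_pads(self, shape, scale, pads):
        out, t = preprocess.standardize_for_labeling(_pmap(*shape))
        assert out.shape == (310, 110)
        assert t.scale_y == t.scale_x == scale
        assert (t.pad_top, t.pad_bottom, t.pad_left, t.pad_right) == pads

    @settings(max_examples=40, deadline=None)
    @given(rows=st.integers(8, 700), cols=st.integers(8, 300))
    def test_always_310_by_110(self, rows, cols):
        out, t = preprocess.standardize_for_labeling(_pmap(rows, cols))
        assert out.shape == (310, 110)
        assert t.scale_y == t.scale_x > 0
        # pads are symmetric up to the odd-pixel-to-bottom/right convention
        assert 0 <= t.pad_bottom - t.pad_top <= 1
        assert 0 <= t.pad_right - t.pad_left <= 1

    def test_foreground_aspect_ratio_preserved(self):
        grid = np.zeros((200, 80))
        grid[50:150, 20:60] = 5.0  # 100 x 40 block
        out, t = preprocess.standardize_for_labeling(PressureMap(grid=grid))
        ys, xs = np.nonzero(out > 0.5)
        h, w = ys.max() - ys.min() + 1, xs.max() - xs.min() + 1
        assert abs(h / w - 100 / 40) < 0.1


class TestColormappedPng:
    def test_all_zero_image_is_white(self, tmp_path):
        from PIL import Image

        path = tmp_path / "zero.png"
        preprocess.render_colormapped_png(np.zeros((20, 10)), path)
        rgb = np.asarray(Image.open(path))
        assert (rgb == 255).all()

    def test_positive_pixel_is_nonwhite(self, tmp_path):
        from PIL import Image

        img = np.zeros((20, 10))
        img[4, 7] = 3.0
        path = tmp_path / "one.png"
        preprocess.render_colormapped_png(img, path)
        rgb = np.asarray(Image.open(path))
        assert not (rgb[4, 7] == 255).all()
        mask = (rgb != 255).any(axis=-1)
        assert mask.sum() == 1

    def test_byte_identical_across_runs(self, tmp_path, rng):
        img = rng.uniform(0, 50, size=(31, 11))
        p1, p2 = tmp_path / "a.png", tmp_path / "b.png"
        preprocess.render_colormapped_png(img, p1)
        preprocess.render_colormapped_png(img, p2)
        assert hashlib.sha256(p1.read_bytes()).hexdigest() == hashlib.sha256(
            p2.read_bytes()
        ).hexdigest()


class TestNormalizeMinmax:
    def test_scales_to_unit_interval(self):
        grid = np.array([[0.0, 5.0], [10.0, 2.0]])
        out = preprocess.normalize_minmax(PressureMap(grid=grid))
        assert out.min() == 0.0 and out.max() == 1.0
        assert np.isclose(out[0, 1], 0.5)

    def test_nonzero_minimum_shifted(self):
        grid = np.array([[5.0, 10.0], [15.0, 7.0]])
        out = preprocess.normalize_minmax(PressureMap(grid=grid))
        assert np.isclose(out[0, 1], 0.5)

    def test_constant_grid_warns_and_zeroes(self):
        pm = PressureMap(grid=np.full((4, 4), 3.0))
        with pytest.warns(UserWarning):
            out = preprocess.normalize_minmax(pm)
        assert (out == 0).all()


def _mask_set(shape, block):
    m = np.zeros(shape, dtype=np.uint8)
    m[block] = 1
    return RegionMaskSet(hallux=m, met1=m, met_all=m, heel=m)


class TestResizeForModel:
    def test_identity_on_matching_size(self):
        img = np.random.default_rng(0).uniform(size=(64, 64))
        out, _, t = preprocess.resize_for_model(img, size=64)
        assert np.allclose(out, img)
        assert t.scale_y == t.scale_x == 1.0

    def test_masks_stay_binary(self):
        masks = _mask_set((40, 30), (slice(5, 20), slice(4, 18)))
        _, out_masks, _ = preprocess.resize_for_model(
            np.ones((40, 30)), masks, size=64
        )
        for lab in ("hallux", "met1", "met_all", "heel"):
            assert set(np.unique(out_masks[lab])) <= {0, 1}

    def test_phantom_grid_scales(self):
        img = np.ones((128, 48))
        _, _, t = preprocess.resize_for_model(img, size=256)
        assert np.isclose(t.scale_y, 2.0)
        assert np.isclose(t.scale_x, 256 / 48)

    def test_shape_mismatch_rejected(self):
        masks = _mask_set((10, 10), (slice(1, 3), slice(1, 3)))
        with pytest.raises(InputError):
            preprocess.resize_for_model(np.ones((12, 10)), masks)


class TestMapPoint:
    def test_pure_pad_translates(self):
        t = SpatialTransform(1.0, 1.0, pad_top=5, pad_left=5)
        q = preprocess.map_point(KeyPoint(0, 0, "id23"), t)
        assert (q.x, q.y) == (5, 5)

    def test_scale_then_pad(self):
        t = SpatialTransform(2.0, 2.0, 5, 5, 5, 5)
        q = preprocess.map_point(KeyPoint(x=20, y=10, label="id23"), t)
        assert (q.x, q.y) == (45, 25)

    @settings(max_examples=50, deadline=None)
    @given(
        x=st.floats(0, 100, allow_nan=False),
        y=st.floats(0, 100, allow_nan=False),
        sy=st.floats(0.1, 10),
        sx=st.floats(0.1, 10),
        pad=st.integers(0, 20),
    )
    def test_round_trip_within_tolerance(self, x, y, sy, sx, pad):
        t = SpatialTransform(sy, sx, pad, pad, pad, pad)
        p = KeyPoint(x=x, y=y, label="id23")
        back = preprocess.map_point(preprocess.map_point(p, t, "forward"), t, "inverse")
        assert abs(back.x - x) < 1e-9 and abs(back.y - y) < 1e-9


class TestOneHot:
    def test_four_channels_in_canonical_order(self):
        shape = (64, 64)
        hallux = np.zeros(shape, np.uint8); hallux[1, 1] = 1
        met1 = np.zeros(shape, np.uint8); met1[10, 10] = 1
        met_all = np.zeros(shape, np.uint8); met_all[10, 10] = 1; met_all[12, 12] = 1
        heel = np.zeros(shape, np.uint8); heel[50, 30] = 1
        masks = RegionMaskSet(hallux=hallux, met1=met1, met_all=met_all, heel=heel)
        enc = preprocess.one_hot_encode(masks, size=64)
        assert enc.shape == (64, 64, 4)
        # overlap contract: a met1 pixel is set in both met1 and met_all
        assert enc[10, 10, 1] == 1 and enc[10, 10, 2] == 1
        # channel splitting recovers the masks exactly
        for i, lab in enumerate(("hallux", "met1", "met_all", "heel")):
            assert np.array_equal(enc[..., i].astype(np.uint8), masks[lab])

    def test_empty_masks_all_zero(self):
        z = np.zeros((64, 64), np.uint8)
        enc = preprocess.one_hot_encode(
            RegionMaskSet(hallux=z, met1=z, met_all=z, heel=z), size=64
        )
        assert enc.shape == (64, 64, 4) and not enc.any()

    def test_wrong_grid_size_rejected(self):
        z = np.zeros((32, 32), np.uint8)
        with pytest.raises(InputError):
            preprocess.one_hot_encode(
                RegionMaskSet(hallux=z, met1=z, met_all=z, heel=z), size=64
            )
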