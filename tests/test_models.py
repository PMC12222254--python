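"""U-Net and regression head: architecture contracts, augmentation, training."""

import numpy as np
import pytest

from plantarzone import models, nn
from plantarzone.core import InputError, KeyPoint


TINY_SEG = models.SegTrainConfig(
    input_size=32, base_filters=4, depth=2, dropout_rate=0.2,
    learning_rate=1e-3, batch_size=4, steps_per_epoch=None, max_epochs=3,
    augment=False, seed=3,
)
TINY_REG = models.RegTrainConfig(max_epochs=5, batch_size=4, seed=3)


@pytest.fixture(scope="module")
def tiny_unet():
    return models.build_unet(TINY_SEG)


def _blob_dataset(n, size=32, seed=0):
    """Tiny synthetic segmentation set: a bright square is all four zones."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        img = rng.uniform(0, 0.1, size=(size, size)).astype(np.float32)
        y0, x0 = rng.integers(4, size - 12, size=2)
        img[y0 : y0 + 8, x0 : x0 + 8] += 0.9
        target = np.zeros((size, size, 4), dtype=np.float32)
        target[y0 : y0 + 8, x0 : x0 + 8, :] = 1.0
        out.append((img, target))
    return out


class TestBuildUnet:
    def test_output_shape_four_sigmoid_channels(self, tiny_unet, rng):
        x = rng.uniform(size=(2, 32, 32, 1)).astype(np.float32)
        logits = tiny_unet.forward(x)
        assert logits.shape == (2, 32, 32, 4)
        probs = nn.sigmoid(logits)
        assert probs.min() >= 0 and probs.max() <= 1

    def test_same_seed_identical_initial_weights(self):
        a = models.build_unet(TINY_SEG)
        b = models.build_unet(TINY_SEG)
        assert a.weights_digest() == b.weights_digest()

    def test_different_seed_changes_weights(self):
        import dataclasses

        other = dataclasses.replace(TINY_SEG, seed=99)
        assert models.build_unet(TINY_SEG).weights_digest() != models.build_unet(
            other
        ).weights_digest()

    def test_indivisible_depth_rejected(self):
        with pytest.raises(InputError):
            models.build_unet(
                models.SegTrainConfig(input_size=100, base_filters=4, depth=3)
            )


class TestAugmentPair:
    def _masks(self, size=32):
        m = np.zeros((size, size, 4), dtype=np.uint8)
        m[8:16, 8:16, 1] = 1  # met1
        m[6:20, 4:24, 2] = 1  # met_all ⊇ met1
        m[2:6, 2:8, 0] = 1
        m[24:30, 10:20, 3] = 1
        return m

    def test_zero_ranges_no_flip_is_identity(self, rng):
        cfg = models.AugmentConfig(
            rotation_deg=0, zoom_frac=0, shift_frac=0, horizontal_flip=False,
            shear_deg=0,
        )
        img = rng.uniform(size=(32, 32))
        masks = self._masks()
        out_img, out_masks = models.augment_pair(img, masks, cfg, rng)
        assert np.allclose(out_img, img, atol=1e-6)
        assert np.array_equal(out_masks, masks)

    def test_flip_only_mirrors_horizontally(self):
        cfg = models.AugmentConfig(
            rotation_deg=0, zoom_frac=0, shift_frac=0, horizontal_flip=True,
            shear_deg=0,
        )
        rng = np.random.default_rng(0)
        img = np.arange(32 * 32, dtype=float).reshape(32, 32)
        masks = self._masks()
        # draw until the coin lands on flip
        for _ in range(20):
            out_img, _ = models.augment_pair(img, masks, cfg, rng)
            if not np.allclose(out_img, img):
                break
        assert np.allclose(out_img, img[:, ::-1], atol=1e-6)

    @pytest.mark.parametrize("draw", range(100))
    def test_masks_stay_binary_and_nested(self, draw):
        """Any affine draw keeps masks in {0,1} and met1 ⊆ met_all."""
        rng = np.random.default_rng(draw)
        cfg = models.AugmentConfig()
        img = rng.uniform(size=(32, 32))
        _, out_masks = models.augment_pair(img, self._masks(), cfg, rng)
        assert set(np.unique(out_masks)) <= {0, 1}
        assert (out_masks[..., 1] & ~out_masks[..., 2]).sum() == 0

    def test_mismatched_shapes_rejected(self, rng):
        with pytest.raises(InputError):
            models.augment_pair(
                np.ones((16, 16)), np.ones((32, 32, 4)), models.AugmentConfig(), rng
            )


class TestTrainSegmentation:
    def test_loss_decreases_on_homogeneous_data(self):
        data = _blob_dataset(1, seed=5) * 5
        model, hist = models.train_segmentation(data, data, TINY_SEG)
        losses = [h["loss"] for h in hist]
        assert losses[-1] < losses[0]
        assert all(set(h) >= {"epoch", "loss", "val_miou", "lr"} for h in hist)

    def test_monitor_equals_evaluation_mean_iou(self):
        from plantarzone.evaluation import iou
        from plantarzone.geometry import threshold_probs

        data = _blob_dataset(4, seed=6)
        model, hist = models.train_segmentation(data, data, TINY_SEG)
        probsets = models.predict_probs(
            model, np.stack([d[0] for d in data])
        )
        vals = []
        for probs, (_, target) in zip(probsets, data):
            pred = threshold_probs(probs)
            for c, lab in enumerate(("hallux", "met1", "met_all", "heel")):
                vals.append(iou(pred[lab], target[..., c].astype(np.uint8)))
        assert hist[-1]["val_miou"] == pytest.approx(float(np.mean(vals)), abs=1e-6)

    def test_empty_dataset_rejected(self):
        with pytest.raises(InputError):
            models.train_segmentation([], [], TINY_SEG)


class TestPredictProbs:
    def test_shapes_and_range(self, tiny_unet, rng):
        maps = rng.uniform(size=(3, 32, 32)).astype(np.float32)
        probsets = models.predict_probs(tiny_unet, maps)
        assert len(probsets) == 3
        for p in probsets:
            assert p.probs.shape == (32, 32, 4)
            assert p.probs.min() >= 0 and p.probs.max() <= 1

    def test_batch_equals_per_sample(self, tiny_unet, rng):
        maps = rng.uniform(size=(3, 32, 32)).astype(np.float32)
        batch = models.predict_probs(tiny_unet, maps)
        singles = [models.predict_probs(tiny_unet, m)[0] for m in maps]
        for b, s in zip(batch, singles):
            assert np.allclose(b.probs, s.probs, atol=1e-6)

    def test_wrong_size_rejected(self, tiny_unet, rng):
        with pytest.raises(InputError):
            models.predict_probs(tiny_unet, rng.uniform(size=(16, 16)))


def _point_dataset(n, label, size=32, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        img = rng.uniform(0, 0.1, size=(size, size)).astype(np.float32)
        y0, x0 = rng.integers(4, size - 12, size=2)
        img[y0 : y0 + 8, x0 : x0 + 8] += 0.9
        out.append((img, KeyPoint(x=float(x0 + 4), y=float(y0 + 4), label=label)))
    return out


class TestRegression:
    def test_output_has_two_coordinates(self, tiny_unet, rng):
        reg = models.build_regression(tiny_unet, TINY_REG)
        reg.target_label = "met1_center"
        p = models.predict_point(reg, rng.uniform(size=(32, 32)).astype(np.float32))
        assert isinstance(p, KeyPoint) and p.label == "met1_center"

    def test_frozen_unet_bit_identical_after_training(self, tiny_unet):
        reg = models.build_regression(tiny_unet, TINY_REG)
        data = _point_dataset(6, "id23", seed=7)
        before_unet = tiny_unet.weights_digest()
        before_head = reg.head_digest()
        reg, hist = models.train_regression(reg, data, data, "id23", TINY_REG)
        assert tiny_unet.weights_digest() == before_unet
        assert reg.head_digest() != before_head
        assert len(hist) >= 1

    def test_early_stop_restores_checkpointed_best(self, tiny_unet):
        import dataclasses

        cfg = dataclasses.replace(TINY_REG, max_epochs=12, early_stop_patience=2)
        reg = models.build_regression(tiny_unet, cfg)
        data = _point_dataset(6, "met1_center", seed=8)
        reg, hist = models.train_regression(reg, data, data, "met1_center", cfg)
        preds = reg.predict(np.stack([d[0] for d in data]))
        targets = np.array([[kp.x, kp.y] for _, kp in data])
        final = float(np.mean(np.linalg.norm(preds - targets, axis=1)))
        best_recorded = min(h["val_euclidean"] for h in hist)
        assert final == pytest.approx(best_recorded, rel=1e-4)

    def test_mixed_target_labels_rejected(self, tiny_unet):
        reg = models.build_regression(tiny_unet, TINY_REG)
        data = _point_dataset(3, "id23") + _point_dataset(2, "met1_center")
        with pytest.raises(InputError, match="mixed"):
            models.train_regression(reg, data, data, "id23", TINY_REG)

    def test_identical_config_hash_across_targets(self):
        cfgs = [TINY_REG for _ in ("met1_center", "id23", "id23_shifted")]
        digests = {models.config_digest(c) for c in cfgs}
        assert len(digests) == 1

    def test_repeated_prediction_is_identical(self, tiny_unet, rng):
        reg = models.build_regression(tiny_unet, TINY_REG)
        reg.target_label = "id23"
        m = rng.uniform(size=(32, 32)).astype(np.float32)
        a = models.predict_point(reg, m)
        b = models.predict_point(reg, m)
        assert (a.x, a.y) == (b.x, b.y)

    def test_prediction_maps_back_to_raw_space(self, tiny_unet, rng):
        from plantarzone.preprocess import map_point, resize_for_model

        reg = models.build_regression(tiny_unet, TINY_REG)
        reg.target_label = "id23"
        raw = rng.uniform(0.1, 1.0, size=(64, 24))
        img, _, t = resize_for_model(raw, size=32)
        p_model = models.predict_point(reg, img)
        p_raw = map_point(p_model, t, "inverse")
        back = map_point(p_raw, t, "forward")
        assert abs(back.x - p_model.x) < 1e-9 and abs(back.y - p_model.y) < 1e-9

    def test_wrong_input_shape_rejected(self, tiny_unet, rng):
        reg = models.build_regression(tiny_unet, TINY_REG)
        reg.target_label = "id23"
        with pytest.raises(InputError):
            models.predict_point(reg, rng.uniform(size=(16, 16)))
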