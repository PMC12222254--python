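"""Segmentation U-Net and frozen-encoder key-point regression.

The segmentation model is an encoder–decoder U-Net with skip connections:
each stage applies two 3×3 conv → batch-norm → LeakyReLU blocks; the encoder
halves resolution with 2×2 max-pooling while doubling filters, the bottleneck
applies dropout, and the decoder upsamples (nearest), concatenates the
matching encoder features, and convolves again. The output is a 1×1
convolution to four sigmoid channels — one per anatomical zone, with
overlapping channels (met1 ⊂ met_all), which is why training uses binary
cross-entropy rather than a mutually exclusive softmax.

Key-point models reuse the trained U-Net as a frozen feature extractor: the
bottleneck feature map feeds a lightweight convolutional regression head
(conv 128 → conv 64 → global average pooling → dense residual block → 2
linear outputs) trained with Huber loss on raw pixel coordinates, one
independent model per landmark with identical hyperparameters.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage

from . import nn
from .core import InputError, KeyPoint, ProbabilityMaskSet

__all__ = [
    "SegTrainConfig", "RegTrainConfig", "AugmentConfig", "config_digest",
    "UNet", "RegressionModel", "build_unet", "build_regression",
    "augment_pair", "train_segmentation", "train_regression",
    "predict_probs", "predict_point",
]

N_OUT_CHANNELS = 4


@dataclass(frozen=True)
class SegTrainConfig:
    """U-Net architecture and training schedule.

    Defaults follow the reference configuration: Adam at 1e-4 with binary
    cross-entropy, batches of 16, 150 steps per epoch, LR halved after 5
    epochs without validation improvement, early stop after 5, monitoring
    mean IoU across the four channels at threshold 0.5.
    """

    input_size: int = 256
    base_filters: int = 32
    depth: int = 4
    dropout_rate: float = 0.5
    kernel: int = 3
    learning_rate: float = 1e-4
    batch_size: int = 16
    steps_per_epoch: int | None = 150
    max_epochs: int = 100
    lr_reduce_factor: float = 0.5
    lr_patience: int = 5
    early_stop_patience: int = 5
    restore_best: bool = True
    augment: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise InputError("depth must be >= 1")
        for name in ("input_size", "base_filters", "learning_rate", "batch_size",
                     "max_epochs"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")


@dataclass(frozen=True)
class RegTrainConfig:
    """Regression-head training schedule (shared across the three landmarks).

    Adam at 1e-3 with Huber loss; LR halved after 5 stale epochs; early stop
    after 8 with best-weight restore, checkpointing on validation Euclidean
    distance.
    """

    learning_rate: float = 1e-3
    huber_delta: float = 1.0
    batch_size: int = 16
    max_epochs: int = 100
    lr_reduce_factor: float = 0.5
    lr_patience: int = 5
    early_stop_patience: int = 8
    restore_best: bool = True
    dropout_rate: float = 0.2
    kernel: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.max_epochs <= 0:
            raise InputError("learning_rate, batch_size, max_epochs must be positive")


@dataclass(frozen=True)
class AugmentConfig:
    """Paired image/mask affine augmentation ranges."""

    rotation_deg: float = 20.0
    zoom_frac: float = 0.10
    shift_frac: float = 0.10
    horizontal_flip: bool = True
    shear_deg: float = 5.0
    fill: str = "nearest"

    def __post_init__(self) -> None:
        if min(self.rotation_deg, self.zoom_frac, self.shift_frac, self.shear_deg) < 0:
            raise InputError("augmentation ranges must be non-negative")


def config_digest(cfg) -> str:
    """Stable hash of a training configuration (standardization contract)."""
    payload = json.dumps(asdict(cfg), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


# ---------------------------------------------------------------------------
# U-Net


class _ConvBlock:
    """(conv → BN → LeakyReLU) × 2."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        self.layers = [
            nn.Conv2D(c_in, c_out, kernel, rng), nn.BatchNorm(c_out), nn.LeakyReLU(),
            nn.Conv2D(c_out, c_out, kernel, rng), nn.BatchNorm(c_out), nn.LeakyReLU(),
        ]

    def forward(self, x, training):
        for l in self.layers:
            x = l.forward(x, training)
        return x

    def backward(self, d):
        for l in reversed(self.layers):
            d = l.backward(d)
        return d


class UNet:
    """Encoder–decoder segmentation network with skip connections."""

    def __init__(self, cfg: SegTrainConfig):
        if cfg.input_size % (2**cfg.depth) != 0:
            raise InputError(
                f"input_size {cfg.input_size} not divisible by 2^depth = {2**cfg.depth}"
            )
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self._dropout_rng = np.random.default_rng(cfg.seed + 1)
        f = cfg.base_filters
        self.encoders: list[_ConvBlock] = []
        self.pools: list[nn.MaxPool2] = []
        c_in = 1
        for i in range(cfg.depth):
            self.encoders.append(_ConvBlock(c_in, f * 2**i, cfg.kernel, rng))
            self.pools.append(nn.MaxPool2())
            c_in = f * 2**i
        self.bottleneck = _ConvBlock(c_in, f * 2**cfg.depth, cfg.kernel, rng)
        self.bottleneck_dropout = nn.Dropout(cfg.dropout_rate, self._dropout_rng)
        self.ups: list[nn.Upsample2] = []
        self.decoders: list[_ConvBlock] = []
        c_prev = f * 2**cfg.depth
        for i in reversed(range(cfg.depth)):
            self.ups.append(nn.Upsample2())
            self.decoders.append(
                _ConvBlock(c_prev + f * 2**i, f * 2**i, cfg.kernel, rng)
            )
            c_prev = f * 2**i
        self.out_conv = nn.Conv2D(c_prev, N_OUT_CHANNELS, 1, rng)

    @property
    def layers(self) -> list[nn.Layer]:
        out: list[nn.Layer] = []
        for b in self.encoders:
            out.extend(b.layers)
        out.extend(self.bottleneck.layers)
        out.append(self.bottleneck_dropout)
        for b in self.decoders:
            out.extend(b.layers)
        out.append(self.out_conv)
        return out

    @property
    def bottleneck_channels(self) -> int:
        return self.cfg.base_filters * 2**self.cfg.depth

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Logits of shape (n, input_size, input_size, 4)."""
        skips = []
        h = x.astype(np.float32)
        for enc, pool in zip(self.encoders, self.pools):
            h = enc.forward(h, training)
            skips.append(h)
            h = pool.forward(h)
        h = self.bottleneck.forward(h, training)
        self._bottleneck_out = h
        h = self.bottleneck_dropout.forward(h, training)
        self._skip_channels = [s.shape[-1] for s in skips]
        for up, dec, skip in zip(self.ups, self.decoders, reversed(skips)):
            h = up.forward(h)
            h = np.concatenate([skip, h], axis=-1)
            h = dec.forward(h, training)
        return self.out_conv.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.out_conv.backward(dlogits)
        dskips: list[np.ndarray] = []
        for up, dec, c_skip in zip(
            reversed(self.ups), reversed(self.decoders), self._skip_channels
        ):
            d = dec.backward(d)
            dskips.append(d[..., :c_skip])
            d = up.backward(d[..., c_skip:])
        d = self.bottleneck_dropout.backward(d)
        d = self.bottleneck.backward(d)
        # dskips were collected shallowest-first; encoders unwind deepest-first
        for enc, pool, dskip in zip(
            reversed(self.encoders), reversed(self.pools), reversed(dskips)
        ):
            d = pool.backward(d)
            d = d + dskip
            d = enc.backward(d)

    def bottleneck_features(self, x: np.ndarray) -> np.ndarray:
        """Inference-mode feature map at the deepest encoder resolution."""
        self.forward(x, training=False)
        return self._bottleneck_out

    def weights_digest(self) -> str:
        return nn.weights_digest(self.layers)


def build_unet(cfg: SegTrainConfig) -> UNet:
    """Construct a U-Net per config; deterministic for a fixed seed."""
    return UNet(cfg)


# ---------------------------------------------------------------------------
# Augmentation


def augment_pair(
    image: np.ndarray,
    masks: np.ndarray,
    cfg: AugmentConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply ONE random affine identically to an image and its mask channels.

    Rotation, zoom, shift, and shear are drawn uniformly within the
    configured ranges; the horizontal flip is a fair coin when enabled. The
    image is resampled bilinearly, masks with nearest-neighbor (staying
    binary), both with nearest-edge fill.
    """
    image = np.asarray(image, dtype=float)
    masks = np.asarray(masks)
    if image.shape[:2] != masks.shape[:2]:
        raise InputError("image and masks must be co-registered")
    rows, cols = image.shape[:2]
    theta = np.deg2rad(rng.uniform(-cfg.rotation_deg, cfg.rotation_deg))
    shear = np.deg2rad(rng.uniform(-cfg.shear_deg, cfg.shear_deg))
    zoom = 1.0 + rng.uniform(-cfg.zoom_frac, cfg.zoom_frac)
    dy = rng.uniform(-cfg.shift_frac, cfg.shift_frac) * rows
    dx = rng.uniform(-cfg.shift_frac, cfg.shift_frac) * cols
    flip = cfg.horizontal_flip and rng.uniform() < 0.5

    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    # forward transform (input -> output), row-major (y, x) convention
    rot = np.array(
        [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
    )
    shr = np.array([[1, np.tan(shear), 0], [0, 1, 0], [0, 0, 1]])
    zm = np.diag([zoom, zoom, 1.0])
    fl = np.diag([1.0, -1.0 if flip else 1.0, 1.0])
    t_c = np.array([[1, 0, cy], [0, 1, cx], [0, 0, 1]])
    t_ic = np.array([[1, 0, -cy], [0, 1, -cx], [0, 0, 1]])
    t_shift = np.array([[1, 0, dy], [0, 1, dx], [0, 0, 1]])
    fwd = t_shift @ t_c @ rot @ shr @ zm @ fl @ t_ic
    inv = np.linalg.inv(fwd)

    def _warp(channel: np.ndarray, order: int) -> np.ndarray:
        return ndimage.affine_transform(
            channel, inv[:2, :2], offset=inv[:2, 2], order=order, mode=cfg.fill
        )

    out_img = (
        _warp(image, 1)
        if image.ndim == 2
        else np.stack([_warp(image[..., c], 1) for c in range(image.shape[-1])], axis=-1)
    )
    if masks.ndim == 2:
        out_masks = _warp(masks.astype(float), 0).astype(masks.dtype)
    else:
        out_masks = np.stack(
            [
                _warp(masks[..., c].astype(float), 0)
                for c in range(masks.shape[-1])
            ],
            axis=-1,
        ).astype(masks.dtype)
    return out_img, out_masks


# ---------------------------------------------------------------------------
# Segmentation training


def _as_xy(dataset) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = zip(*dataset)
    x = np.stack([np.asarray(v, dtype=np.float32) for v in xs])
    if x.ndim == 3:
        x = x[..., None]
    return x, np.stack([np.asarray(v, dtype=np.float32) for v in ys])


def _predict_logits(model: UNet, x: np.ndarray, batch: int = 8) -> np.ndarray:
    return np.concatenate(
        [model.forward(x[i : i + batch]) for i in range(0, len(x), batch)]
    )


def _mean_iou(model: UNet, x: np.ndarray, y: np.ndarray, t: float = 0.5) -> float:
    from .evaluation import iou  # deferred: evaluation imports models lazily

    probs = nn.sigmoid(_predict_logits(model, x))
    pred = (probs >= t).astype(np.uint8)
    vals = [
        iou(pred[i, ..., c], y[i, ..., c].astype(np.uint8))
        for i in range(len(x))
        for c in range(N_OUT_CHANNELS)
    ]
    return float(np.mean(vals))


def train_segmentation(
    train, val, cfg: SegTrainConfig, aug_cfg: AugmentConfig | None = None,
    model: UNet | None = None,
) -> tuple[UNet, list[dict]]:
    """Train the U-Net with BCE loss, LR-plateau and early stopping.

    ``train``/``val`` are sequences of (image, 4-channel one-hot target)
    pairs on the model-input grid. The validation metric is mean IoU across
    channels at threshold 0.5; the LR is halved after ``lr_patience`` stale
    epochs and training stops after ``early_stop_patience``. Returns the
    trained model and a per-epoch history (loss, val_miou, lr, lr_reduced).
    """
    if len(train) == 0 or len(val) == 0:
        raise InputError("train and val datasets must be non-empty")
    x_tr, y_tr = _as_xy(train)
    x_va, y_va = _as_xy(val)
    if model is None:
        model = build_unet(cfg)
    if aug_cfg is None and cfg.augment:
        aug_cfg = AugmentConfig()
    rng = np.random.default_rng(cfg.seed + 2)
    opt = nn.Adam(model.layers, lr=cfg.learning_rate)
    plateau = nn.ReduceLROnPlateau(
        opt, factor=cfg.lr_reduce_factor, patience=cfg.lr_patience, mode="max"
    )
    stopper = nn.EarlyStopping(
        model.layers, patience=cfg.early_stop_patience, mode="max",
        restore_best=cfg.restore_best,
    )
    steps = cfg.steps_per_epoch or int(np.ceil(len(x_tr) / cfg.batch_size))
    history: list[dict] = []
    order = rng.permutation(len(x_tr))
    cursor = 0
    for epoch in range(cfg.max_epochs):
        losses = []
        for _ in range(steps):
            if cursor + cfg.batch_size > len(order):
                order = rng.permutation(len(x_tr))
                cursor = 0
            idx = order[cursor : cursor + cfg.batch_size]
            cursor += cfg.batch_size
            xb, yb = x_tr[idx], y_tr[idx]
            if aug_cfg is not None and cfg.augment:
                xb = xb.copy()
                yb = yb.copy()
                for i in range(len(idx)):
                    xi, yi = augment_pair(xb[i, ..., 0], yb[i], aug_cfg, rng)
                    xb[i, ..., 0], yb[i] = xi, yi
            logits = model.forward(xb, training=True)
            loss, dlogits = nn.bce_with_logits(logits, yb)
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        val_miou = _mean_iou(model, x_va, y_va)
        reduced = plateau.on_epoch_end(val_miou)
        history.append(
            {
                "epoch": epoch,
                "loss": float(np.mean(losses)),
                "val_miou": val_miou,
                "lr": opt.lr,
                "lr_reduced": reduced,
            }
        )
        if stopper.on_epoch_end(val_miou, epoch):
            break
    stopper.restore()
    return model, history


def predict_probs(model: UNet, maps: np.ndarray) -> list[ProbabilityMaskSet]:
    """Sigmoid zone probabilities for one map or a batch of maps."""
    maps = np.asarray(maps, dtype=np.float32)
    single = maps.ndim == 2
    if single:
        maps = maps[None]
    if maps.ndim == 3:
        maps = maps[..., None]
    size = model.cfg.input_size
    if maps.shape[1:3] != (size, size):
        raise InputError(f"expected {size}x{size} inputs, got {maps.shape[1:3]}")
    probs = nn.sigmoid(_predict_logits(model, maps))
    return [ProbabilityMaskSet(np.clip(p, 0.0, 1.0)) for p in probs]


# ---------------------------------------------------------------------------
# Regression


class RegressionModel:
    """Frozen U-Net encoder + trainable coordinate-regression head."""

    def __init__(self, unet: UNet, cfg: RegTrainConfig):
        if not hasattr(unet, "bottleneck_features"):
            raise InputError("U-Net handle lacks an identifiable bottleneck")
        self.unet = unet
        self.cfg = cfg
        self.target_label: str | None = None
        rng = np.random.default_rng(cfg.seed + 10)
        drop_rng = np.random.default_rng(cfg.seed + 11)
        c_in = unet.bottleneck_channels
        k = cfg.kernel
        self.conv1 = nn.Conv2D(c_in, 128, k, rng)
        self.act1 = nn.ReLU()
        self.bn1 = nn.BatchNorm(128)
        self.drop = nn.Dropout(cfg.dropout_rate, drop_rng)
        self.conv2 = nn.Conv2D(128, 64, k, rng)
        self.act2 = nn.ReLU()
        self.bn2 = nn.BatchNorm(64)
        self.gap = nn.GlobalAvgPool()
        self.fc1 = nn.Dense(64, 128, rng)
        self.fc1_act = nn.ReLU()
        self.fc1_bn = nn.BatchNorm(128)
        self.res_fc1 = nn.Dense(128, 128, rng)
        self.res_act = nn.ReLU()
        self.res_bn = nn.BatchNorm(128)
        self.res_fc2 = nn.Dense(128, 128, rng)
        self.out = nn.Dense(128, 2, rng)

    @property
    def head_layers(self) -> list[nn.Layer]:
        return [
            self.conv1, self.act1, self.bn1, self.drop,
            self.conv2, self.act2, self.bn2, self.gap,
            self.fc1, self.fc1_act, self.fc1_bn,
            self.res_fc1, self.res_act, self.res_bn, self.res_fc2,
            self.out,
        ]

    def forward_features(self, feats: np.ndarray, training: bool = False) -> np.ndarray:
        h = self.conv1.forward(feats, training)
        h = self.act1.forward(h, training)
        h = self.bn1.forward(h, training)
        h = self.drop.forward(h, training)
        h = self.conv2.forward(h, training)
        h = self.act2.forward(h, training)
        h = self.bn2.forward(h, training)
        h = self.gap.forward(h, training)
        v = self.fc1.forward(h, training)
        v = self.fc1_act.forward(v, training)
        v = self.fc1_bn.forward(v, training)
        r = self.res_fc1.forward(v, training)
        r = self.res_act.forward(r, training)
        r = self.res_bn.forward(r, training)
        r = self.res_fc2.forward(r, training)
        s = v + r  # additive shortcut around the dense block
        return self.out.forward(s, training)

    def backward(self, dout: np.ndarray) -> None:
        d_s = self.out.backward(dout)
        d_r = self.res_fc2.backward(d_s)
        d_r = self.res_bn.backward(d_r)
        d_r = self.res_act.backward(d_r)
        d_r = self.res_fc1.backward(d_r)
        d_v = d_s + d_r  # shortcut gradient
        d = self.fc1_bn.backward(d_v)
        d = self.fc1_act.backward(d)
        d = self.fc1.backward(d)
        d = self.gap.backward(d)
        d = self.bn2.backward(d)
        d = self.act2.backward(d)
        d = self.conv2.backward(d)
        d = self.drop.backward(d)
        d = self.bn1.backward(d)
        d = self.act1.backward(d)
        self.conv1.backward(d)

    def predict(self, maps: np.ndarray, batch: int = 8) -> np.ndarray:
        maps = np.asarray(maps, dtype=np.float32)
        if maps.ndim == 3:
            maps = maps[..., None]
        out = []
        for i in range(0, len(maps), batch):
            feats = self.unet.bottleneck_features(maps[i : i + batch])
            out.append(self.forward_features(feats, training=False))
        return np.concatenate(out)

    def head_digest(self) -> str:
        return nn.weights_digest(self.head_layers)


def build_regression(unet_model: UNet, cfg: RegTrainConfig) -> RegressionModel:
    """Attach a fresh regression head to a (frozen) U-Net."""
    return RegressionModel(unet_model, cfg)


def train_regression(
    model: RegressionModel, train, val, target_label: str, cfg: RegTrainConfig
) -> tuple[RegressionModel, list[dict]]:
    """Train one landmark regressor on frozen U-Net bottleneck features.

    ``train``/``val`` are sequences of (image, KeyPoint) pairs in
    model-input pixel space, all carrying ``target_label``. The U-Net is
    used inference-only (its weights are never touched); bottleneck feature
    maps are computed once and cached. Checkpointing and early stopping act
    on the validation Euclidean distance, restoring the best weights.
    """
    if len(train) == 0 or len(val) == 0:
        raise InputError("train and val datasets must be non-empty")
    for _, kp in list(train) + list(val):
        if kp.label != target_label:
            raise InputError(
                f"mixed target labels: expected {target_label!r}, got {kp.label!r}"
            )
    model.target_label = target_label

    def _feats_targets(dataset):
        xs = np.stack([np.asarray(img, dtype=np.float32) for img, _ in dataset])
        if xs.ndim == 3:
            xs = xs[..., None]
        feats = np.concatenate(
            [model.unet.bottleneck_features(xs[i : i + 8]) for i in range(0, len(xs), 8)]
        )
        t = np.array([[kp.x, kp.y] for _, kp in dataset], dtype=np.float32)
        return feats, t

    f_tr, t_tr = _feats_targets(train)
    f_va, t_va = _feats_targets(val)

    rng = np.random.default_rng(cfg.seed + 12)
    opt = nn.Adam(model.head_layers, lr=cfg.learning_rate)
    plateau = nn.ReduceLROnPlateau(
        opt, factor=cfg.lr_reduce_factor, patience=cfg.lr_patience, mode="min"
    )
    stopper = nn.EarlyStopping(
        model.head_layers, patience=cfg.early_stop_patience, mode="min",
        restore_best=cfg.restore_best,
    )
    history: list[dict] = []
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(f_tr))
        losses = []
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            pred = model.forward_features(f_tr[idx], training=True)
            loss, dpred = nn.huber_loss(pred, t_tr[idx], delta=cfg.huber_delta)
            model.backward(dpred)
            opt.step()
            losses.append(loss)
        pred_va = model.forward_features(f_va, training=False)
        val_dist = float(np.mean(np.linalg.norm(pred_va - t_va, axis=1)))
        reduced = plateau.on_epoch_end(val_dist)
        history.append(
            {
                "epoch": epoch,
                "loss": float(np.mean(losses)),
                "val_euclidean": val_dist,
                "lr": opt.lr,
                "lr_reduced": reduced,
            }
        )
        if stopper.on_epoch_end(val_dist, epoch):
            break
    stopper.restore()
    return model, history


def predict_point(model: RegressionModel, pmap: np.ndarray) -> KeyPoint:
    """Predict one landmark as a continuous (x, y) in model-input space."""
    pmap = np.asarray(pmap, dtype=np.float32)
    if pmap.ndim != 2:
        raise InputError("expected a single 2D model-input map")
    size = model.unet.cfg.input_size
    if pmap.shape != (size, size):
        raise InputError(f"expected a {size}x{size} map, got {pmap.shape}")
    xy = model.predict(pmap[None])[0]
    return KeyPoint(
        x=float(xy[0]), y=float(xy[1]), label=model.target_label or "met1_center"
    )
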