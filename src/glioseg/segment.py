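"""Segmentation ensemble: attention-gated U-Net and residual-encoder U-Net
trained with a hybrid Dice + binary-cross-entropy loss and fused by soft
voting.

The loss is ``L = alpha * L_BCE + (1 - alpha) * L_Dice`` where BCE is the
batch-mean pixel-wise cross-entropy and the Dice term is the soft Dice loss
``1 - (2 * sum(y * y_hat) + eps) / (sum(y) + sum(y_hat) + eps)`` pooled over
all pixels of the batch.  BCE weights per-pixel accuracy; the Dice term
targets region overlap and is what keeps optimization stable under the heavy
class imbalance of small lesions.

Decoder skip connections pass through additive attention gates: a per-position
sigmoid weight computed from a learned combination of the skip features and
the coarser gating signal multiplies the skip features, suppressing irrelevant
anatomy.  (This is distinct from the dot-product self-attention used at the
autoencoder bottleneck.)
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .detect import ClassProb, ROIMask, classify, gate, kmeans_latent, roi_from_clusters
from .gae import GAE, encode_image
from .nn import (Adam, BatchNorm2d, Conv2d, Module, Tensor, as_tensor, concat,
                 upsample_nearest2x)
from .preprocess import zscore_normalize
from .train import EarlyStopper, TrainConfig, minibatch_indices

__all__ = [
    "LossConfig", "UNetConfig", "EnsembleConfig", "ProbMap", "AttentionGate", "UNet",
    "build_attention_unet", "build_residual_unet", "bce_loss", "dice_loss",
    "hybrid_loss", "train_segmenter", "soft_vote", "predict_mask",
    "init_encoder_from_gae", "PipelineModels",
]

_BCE_CLIP = 1e-7


# ---------------------------------------------------------------------------
# configs / containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LossConfig:
    alpha: float = 0.5   # weight of the BCE term
    epsilon: float = 1e-6  # Dice smoothing constant

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigError("alpha must be in [0, 1]")
        if self.epsilon <= 0:
            raise ConfigError("epsilon must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class UNetConfig:
    in_channels: int = 1
    depth: int = 3            # number of 2x downsamplings
    base_channels: int = 8
    use_attention_gates: bool = True
    residual_encoder: bool = False
    batch_norm: bool = True

    def __post_init__(self):
        if self.depth < 1:
            raise ConfigError("depth must be >= 1")

    def channels(self) -> list[int]:
        return [self.base_channels * 2 ** i for i in range(self.depth + 1)]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class EnsembleConfig:
    weights: tuple[float, ...] = (0.5, 0.5)
    binarize_threshold: float = 0.5

    def __post_init__(self):
        if len(self.weights) < 1 or any(w < 0 for w in self.weights):
            raise ConfigError("need >= 1 non-negative vote weight")
        if sum(self.weights) <= 0:
            raise ConfigError("weights must not all be zero")

    def normalized_weights(self) -> np.ndarray:
        w = np.asarray(self.weights, dtype=np.float64)
        return w / w.sum()

    def to_dict(self) -> dict:
        return {"weights": list(self.weights),
                "binarize_threshold": self.binarize_threshold}


@dataclass
class ProbMap:
    probs: np.ndarray
    source_model: str = ""

    def __post_init__(self):
        if np.min(self.probs) < 0 or np.max(self.probs) > 1:
            raise ValueError("probabilities must lie in [0, 1]")

    def binarize(self, threshold: float) -> np.ndarray:
        return (self.probs >= threshold).astype(np.uint8)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------


class _ConvBNReLU(Module):
    def __init__(self, cin, cout, rng, stride=1, batch_norm=True):
        super().__init__()
        self.conv = Conv2d(cin, cout, 3, rng, stride=stride, padding=1)
        self.bn = BatchNorm2d(cout) if batch_norm else None

    def forward(self, x):
        x = self.conv(x)
        if self.bn is not None:
            x = self.bn(x)
        return x.relu()


class _DownBlock(Module):
    """Plain encoder stage: one stride-2 conv-BN-ReLU."""

    def __init__(self, cin, cout, rng, batch_norm=True):
        super().__init__()
        self.down = _ConvBNReLU(cin, cout, rng, stride=2, batch_norm=batch_norm)

    def forward(self, x):
        return self.down(x)


class _ResDownBlock(Module):
    """Residual encoder block with strided projection shortcut."""

    def __init__(self, cin, cout, rng, batch_norm=True):
        super().__init__()
        self.conv1 = Conv2d(cin, cout, 3, rng, stride=2, padding=1)
        self.bn1 = BatchNorm2d(cout) if batch_norm else None
        self.conv2 = Conv2d(cout, cout, 3, rng, stride=1, padding=1)
        self.bn2 = BatchNorm2d(cout) if batch_norm else None
        self.short = Conv2d(cin, cout, 1, rng, stride=2, bias=False)

    def forward(self, x):
        h = self.conv1(x)
        if self.bn1 is not None:
            h = self.bn1(h)
        h = self.conv2(h.relu())
        if self.bn2 is not None:
            h = self.bn2(h)
        return (self.short(x) + h).relu()


class AttentionGate(Module):
    """Additive attention gate on a skip connection.

    ``w = sigmoid(psi(relu(Wx * x + Wg * g + b)))`` per position, then the
    skip features are scaled by ``w``.  ``x`` (skip) and ``g`` (gating signal
    from the coarser decoder stage, already upsampled) must be spatially
    aligned.
    """

    def __init__(self, skip_channels: int, gating_channels: int, inter_channels: int, rng):
        super().__init__()
        self.wx = Conv2d(skip_channels, inter_channels, 1, rng, bias=False)
        self.wg = Conv2d(gating_channels, inter_channels, 1, rng, bias=True)
        self.psi = Conv2d(inter_channels, 1, 1, rng, bias=True)

    def weights(self, skip: Tensor, gating: Tensor) -> Tensor:
        if skip.shape[2:] != gating.shape[2:]:
            raise ValueError("skip and gating signal must be spatially aligned")
        pre = (self.wx(skip) + self.wg(gating)).relu()
        return self.psi(pre).sigmoid()  # (n, 1, h, w)

    def forward(self, skip: Tensor, gating: Tensor) -> Tensor:
        return skip * self.weights(skip, gating)


class UNet(Module):
    """Encoder-decoder with skip connections, optional attention gates and an
    optional residual encoder; sigmoid head produces a probability map."""

    def __init__(self, config: UNetConfig, init_seed: int):
        super().__init__()
        self.config = config
        self.init_seed = int(init_seed)
        rng = np.random.default_rng(np.random.SeedSequence(self.init_seed))
        chans = config.channels()  # scale i has chans[i] channels
        bn = config.batch_norm

        self.inc = _ConvBNReLU(config.in_channels, chans[0], rng, batch_norm=bn)
        down_cls = _ResDownBlock if config.residual_encoder else _DownBlock
        self.down_blocks = [down_cls(chans[i], chans[i + 1], rng, batch_norm=bn)
                            for i in range(config.depth)]
        self.gates = []
        self.dec_blocks = []
        for i in reversed(range(config.depth)):
            # the upsampled deeper feature (chans[i+1]) is the gating signal
            if config.use_attention_gates:
                self.gates.append(
                    AttentionGate(chans[i], chans[i + 1], max(chans[i] // 2, 1), rng))
            self.dec_blocks.append(
                _ConvBNReLU(chans[i] + chans[i + 1], chans[i], rng, batch_norm=bn))
        self.head = Conv2d(chans[0], 1, 1, rng)

    def _check_size(self, h: int, w: int) -> None:
        f = 2 ** self.config.depth
        if h < f or w < f or h % f or w % f:
            raise ConfigError(f"input {h}x{w} incompatible with depth {self.config.depth}")

    def forward(self, x: Tensor) -> Tensor:
        self._check_size(x.shape[2], x.shape[3])
        skips = [self.inc(x)]
        h = skips[0]
        for block in self.down_blocks:
            h = block(h)
            skips.append(h)
        for j, i in enumerate(reversed(range(self.config.depth))):
            h = upsample_nearest2x(h)
            skip = skips[i]
            if self.config.use_attention_gates:
                skip = self.gates[j](skip, h)
            h = self.dec_blocks[j](concat([skip, h], axis=1))
        return self.head(h).sigmoid()

    def predict_proba(self, image: np.ndarray, name: str = "") -> ProbMap:
        arr = np.asarray(image, dtype=np.float64)
        if arr.ndim == 2:
            arr = arr[None]
        self.eval()
        probs = self(Tensor(arr[None])).data[0, 0]
        return ProbMap(probs=np.clip(probs, 0.0, 1.0), source_model=name)


def build_attention_unet(config: UNetConfig, init_seed: int) -> UNet:
    if not config.use_attention_gates:
        config = dataclasses.replace(config, use_attention_gates=True)
    return UNet(config, init_seed)


def build_residual_unet(config: UNetConfig, init_seed: int) -> UNet:
    config = dataclasses.replace(config, residual_encoder=True)
    return UNet(config, init_seed)


def init_encoder_from_gae(unet: UNet, gae_model: GAE) -> int:
    """Copy shape-compatible encoder conv weights from a pretrained GAE.

    The GAE's stride-2 encoder convs line up with the U-Net's first-level conv
    and the strided convs of its down blocks when the channel schedules agree.
    Returns the number of conv kernels copied.
    """
    gae_convs = [stage.conv for stage in gae_model.encoder_stages]
    unet_convs = [unet.inc.conv]
    for block in unet.down_blocks:
        unet_convs.append(block.down.conv if hasattr(block, "down") else block.conv1)
    copied = 0
    for src, dst in zip(gae_convs, unet_convs):
        if src.weight.data.shape == dst.weight.data.shape:
            dst.weight.data = src.weight.data.copy()
            if src.bias is not None and dst.bias is not None:
                dst.bias.data = src.bias.data.copy()
            copied += 1
    return copied


# ---------------------------------------------------------------------------
# losses (accept numpy arrays -> float, or Tensors -> Tensor for training)
# ---------------------------------------------------------------------------


def _loss_io(y, y_hat):
    numpy_in = not isinstance(y_hat, Tensor)
    yt, pt = as_tensor(np.asarray(y, dtype=np.float64) if numpy_in else y), as_tensor(y_hat)
    if yt.shape != pt.shape:
        raise ValueError(f"shape mismatch: {yt.shape} vs {pt.shape}")
    return yt, pt, numpy_in


def bce_loss(y, y_hat):
    """Mean binary cross-entropy, predictions clipped away from {0, 1}."""
    yt, pt, numpy_in = _loss_io(y, y_hat)
    p = pt.clip(_BCE_CLIP, 1.0 - _BCE_CLIP)
    loss = -(yt * p.log() + (1.0 - yt) * (1.0 - p).log()).mean()
    return float(loss.data) if numpy_in else loss


def dice_loss(y, y_hat, epsilon: float = 1e-6):
    """Soft Dice loss pooled over every pixel of the batch."""
    yt, pt, numpy_in = _loss_io(y, y_hat)
    inter = (yt * pt).sum()
    denom = yt.sum() + pt.sum()
    loss = 1.0 - (2.0 * inter + epsilon) / (denom + epsilon)
    return float(loss.data) if numpy_in else loss


def hybrid_loss(y, y_hat, cfg: LossConfig):
    """``alpha * BCE + (1 - alpha) * Dice`` — exact affine combination."""
    b = bce_loss(y, y_hat)
    d = dice_loss(y, y_hat, cfg.epsilon)
    return cfg.alpha * b + (1.0 - cfg.alpha) * d


def _masked_hybrid_loss(y: Tensor, y_hat: Tensor, region: np.ndarray, cfg: LossConfig) -> Tensor:
    """Hybrid loss restricted to pixels of ``region`` (ROI union truth)."""
    r = Tensor(region.astype(np.float64))
    n = max(float(region.sum()), 1.0)
    p = y_hat.clip(_BCE_CLIP, 1.0 - _BCE_CLIP)
    bce = -((y * p.log() + (1.0 - y) * (1.0 - p).log()) * r).sum() * (1.0 / n)
    inter = (y * y_hat * r).sum()
    denom = (y * r).sum() + (y_hat * r).sum()
    dice = 1.0 - (2.0 * inter + cfg.epsilon) / (denom + cfg.epsilon)
    return cfg.alpha * bce + (1.0 - cfg.alpha) * dice


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

ROI_MODES = ("off", "mask_input_channel", "restrict_loss")


def _seg_inputs(images: np.ndarray, rois: np.ndarray | None, roi_mode: str) -> np.ndarray:
    x = np.asarray(images, dtype=np.float64)
    if x.ndim == 3:
        x = x[:, None]
    if roi_mode == "mask_input_channel":
        if rois is None:
            raise ConfigError("roi_mode=mask_input_channel requires ROI masks")
        x = np.concatenate([x, np.asarray(rois, dtype=np.float64)[:, None]], axis=1)
    return x


def train_segmenter(model: UNet, images: np.ndarray, masks: np.ndarray,
                    train_config: TrainConfig, loss_config: LossConfig,
                    roi_mode: str = "off",
                    rois: np.ndarray | None = None,
                    val_images: np.ndarray | None = None,
                    val_masks: np.ndarray | None = None,
                    val_rois: np.ndarray | None = None) -> tuple[UNet, list[dict]]:
    """Train one U-Net with the hybrid loss.

    ``roi_mode`` injects the coarse k-means ROI: as an extra input channel
    (``mask_input_channel``), as a loss restriction to ROI-or-truth pixels
    (``restrict_loss``), or not at all (``off``).  Early stopping monitors the
    validation loss with ``train_config.patience``; the best weights are
    restored.  History rows: epoch, train_loss, val_loss, train_dice,
    val_dice (Dice of the thresholded prediction at 0.5).
    """
    if roi_mode not in ROI_MODES:
        raise ConfigError(f"roi_mode must be one of {ROI_MODES}")
    has_val = val_images is not None and val_masks is not None
    x = _seg_inputs(images, rois, roi_mode)
    y = np.asarray(masks, dtype=np.float64)
    if has_val:
        xv = _seg_inputs(val_images, val_rois, roi_mode)
        yv = np.asarray(val_masks, dtype=np.float64)
    roi_train = np.asarray(rois, dtype=np.float64) if rois is not None else None
    roi_val = np.asarray(val_rois, dtype=np.float64) if val_rois is not None else None

    optimizer = Adam(model.parameters(), lr=train_config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence(train_config.seed, spawn_key=(33,)))
    stopper = EarlyStopper(train_config.patience) if has_val else None
    best_state = None
    history: list[dict] = []

    def batch_loss(xb: np.ndarray, yb: np.ndarray, rb: np.ndarray | None) -> Tensor:
        pred = model(Tensor(xb)).reshape(yb.shape)
        yt = Tensor(yb)
        if roi_mode == "restrict_loss":
            region = np.maximum(rb, yb) if rb is not None else yb
            return _masked_hybrid_loss(yt, pred, region, loss_config)
        return hybrid_loss(yt, pred, loss_config)

    def evaluate(xe, ye, re) -> tuple[float, float]:
        model.eval()
        losses, dices = [], []
        for s in range(0, len(xe), 16):
            xb, yb = xe[s:s + 16], ye[s:s + 16]
            rb = re[s:s + 16] if re is not None else None
            pred = model(Tensor(xb)).data.reshape(yb.shape)
            if roi_mode == "restrict_loss":
                region = np.maximum(rb, yb) if rb is not None else yb
                losses.append(float(_masked_hybrid_loss(
                    Tensor(yb), Tensor(pred), region, loss_config).data))
            else:
                losses.append(hybrid_loss(yb, pred, loss_config))
            hard = (pred >= 0.5).astype(float)
            dices.append(float((2 * (hard * yb).sum() + 1e-9)
                               / (hard.sum() + yb.sum() + 1e-9)))
        return float(np.mean(losses)), float(np.mean(dices))

    for epoch in range(train_config.max_epochs):
        model.train()
        losses = []
        for idx in minibatch_indices(len(x), train_config.batch_size, rng):
            rb = roi_train[idx] if roi_train is not None else None
            loss = batch_loss(x[idx], y[idx], rb)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(loss.item())
        # train metrics on a fixed subset: cheap and stable across epochs
        k = min(len(x), 32)
        _, tr_dice = evaluate(x[:k], y[:k], roi_train[:k] if roi_train is not None else None)
        row = {"epoch": epoch, "train_loss": float(np.mean(losses)), "train_dice": tr_dice}
        if has_val:
            row["val_loss"], row["val_dice"] = evaluate(xv, yv, roi_val)
        history.append(row)
        if stopper is not None:
            if row["val_loss"] <= stopper.best:
                best_state = model.state_dict()
            if stopper.update(row["val_loss"], epoch):
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return model, history


# ---------------------------------------------------------------------------
# ensembling and end-to-end prediction
# ---------------------------------------------------------------------------


def soft_vote(maps: list[ProbMap], cfg: EnsembleConfig) -> ProbMap:
    """Weighted mean of member probability maps."""
    if len(maps) != len(cfg.weights):
        raise ValueError("number of maps must match number of weights")
    shapes = {m.probs.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError("member probability maps must share a shape")
    w = cfg.normalized_weights()
    fused = sum(wi * m.probs for wi, m in zip(w, maps))
    return ProbMap(probs=np.clip(fused, 0.0, 1.0), source_model="soft_vote")


@dataclass
class PipelineModels:
    """Trained models for every enabled pipeline stage."""

    segmenters: list[UNet]
    ensemble: EnsembleConfig
    gae: GAE | None = None
    classifier: object | None = None
    gate_tau: float = 0.5
    use_gate: bool = False
    roi_mode: str = "off"
    kmeans_k: int = 2
    kmeans_seed: int = 42
    normalize: bool = True


def predict_mask(models: PipelineModels, image: np.ndarray
                 ) -> tuple[np.ndarray, ProbMap, ClassProb | None, ROIMask | None]:
    """Run the full prediction path on one raw image.

    preprocess -> encode -> classify -> gate -> (if segmenting) latent k-means
    ROI -> ensemble forward -> soft vote -> threshold.  A gate skip returns an
    all-zero mask.
    """
    if not models.segmenters:
        raise ConfigError("no trained segmentation model available")
    img = np.asarray(image, dtype=np.float64)
    if models.normalize:
        img, _ = zscore_normalize(img)

    class_prob = None
    if models.use_gate:
        if models.classifier is None:
            raise ConfigError("gating enabled but no classifier model")
        cfg = models.classifier.config
        if cfg.input_kind == "latent":
            if models.gae is None:
                raise ConfigError("latent classifier input requires a GAE")
            class_prob = classify(models.classifier, encode_image(models.gae, img))
        else:
            class_prob = classify(models.classifier, img)
        if gate(class_prob, models.gate_tau) == "skip":
            zeros = np.zeros(img.shape[-2:], dtype=np.uint8)
            return zeros, ProbMap(np.zeros(img.shape[-2:]), "gate_skip"), class_prob, None

    roi = None
    if models.roi_mode != "off":
        if models.gae is None:
            raise ConfigError("ROI generation requires a GAE")
        latent = encode_image(models.gae, img)
        clusters = kmeans_latent(latent, k=models.kmeans_k, seed=models.kmeans_seed)
        roi = roi_from_clusters(clusters, latent)

    member_maps = []
    for i, member in enumerate(models.segmenters):
        if models.roi_mode == "mask_input_channel":
            x = np.stack([img, roi.mask.astype(np.float64)])
        else:
            x = img
        member_maps.append(member.predict_proba(x, name=f"member{i}"))
    fused = soft_vote(member_maps, models.ensemble) if len(member_maps) > 1 else member_maps[0]
    mask = fused.binarize(models.ensemble.binarize_threshold)
    return mask, fused, class_prob, roi
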