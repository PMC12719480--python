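"""Generative autoencoder (GAE) with scaled dot-product self-attention at the
bottleneck.

The encoder is a stack of stride-2 conv / batch-norm / ReLU stages, each
halving resolution; the decoder mirrors it with nearest-neighbour upsampling
followed by convolution.  At the bottleneck the ``h' x w'`` spatial positions
are treated as a token sequence and refined by single-head scaled dot-product
self-attention, ``Attention(Q, K, V) = softmax(Q K^T / sqrt(d_k)) V``, with
learned 1x1 (position-wise) projections for Q, K and V and a residual
connection.  Training is unsupervised mean-squared-error reconstruction; the
spatial latent map is exposed for downstream classification and k-means ROI
clustering.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .nn import Adam, BatchNorm2d, Conv2d, Linear, Module, Tensor, as_tensor, upsample_nearest2x
from .train import EarlyStopper, TrainConfig, minibatch_indices

__all__ = ["GAEConfig", "LatentMap", "GAE", "build_gae", "scaled_dot_attention",
           "pretrain_gae", "encode_image", "reconstruct_image"]


@dataclass(frozen=True)
class GAEConfig:
    in_channels: int = 1
    encoder_depth: int = 4
    base_channels: int = 16
    latent_channels: int = 64
    attention_dim: int = 32
    batch_norm: bool = True

    def __post_init__(self):
        if self.encoder_depth < 1:
            raise ConfigError("encoder_depth must be >= 1")
        if not (self.latent_channels >= self.attention_dim >= 1):
            raise ConfigError("need latent_channels >= attention_dim >= 1")

    def channel_schedule(self) -> list[int]:
        chans = [self.base_channels * 2 ** i for i in range(self.encoder_depth - 1)]
        return chans + [self.latent_channels]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class LatentMap:
    """Spatial grid of bottleneck feature vectors for one image."""

    grid: np.ndarray  # (h', w', d)
    source_shape: tuple[int, ...]
    downsample_factor: int

    @property
    def n_positions(self) -> int:
        return self.grid.shape[0] * self.grid.shape[1]

    @property
    def dim(self) -> int:
        return self.grid.shape[2]


def _softmax_last(x: Tensor) -> Tensor:
    m = Tensor(x.data.max(axis=-1, keepdims=True))  # detached max for stability
    e = (x - m).exp()
    return e / e.sum(axis=-1, keepdims=True)


def scaled_dot_attention(q, k, v, d_k: int | None = None):
    """``softmax(Q K^T / sqrt(d_k)) V`` over rows.

    Accepts numpy arrays (returns an ndarray) or Tensors (returns a Tensor and
    participates in autodiff).  Q and K must share their trailing dimension;
    K and V must share their row count.  ``d_k`` defaults to Q's trailing dim.
    """
    numpy_in = not isinstance(q, Tensor)
    qt, kt, vt = as_tensor(q), as_tensor(k), as_tensor(v)
    if qt.shape[-1] != kt.shape[-1]:
        raise ValueError("Q and K must have the same feature dimension")
    if kt.shape[-2] != vt.shape[-2]:
        raise ValueError("K and V must have the same number of rows")
    if d_k is None:
        d_k = qt.shape[-1]
    scores = (qt @ kt.swapaxes(-1, -2)) * (1.0 / np.sqrt(float(d_k)))
    out = _softmax_last(scores) @ vt
    return out.data if numpy_in else out


class SelfAttention2d(Module):
    """Single-head self-attention over the flattened spatial positions of an
    NCHW feature map, with a residual connection."""

    def __init__(self, channels: int, attention_dim: int, rng: np.random.Generator):
        super().__init__()
        self.d_k = attention_dim
        self.q_proj = Linear(channels, attention_dim, rng, bias=False)
        self.k_proj = Linear(channels, attention_dim, rng, bias=False)
        self.v_proj = Linear(channels, channels, rng, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        tokens = x.reshape(n, c, h * w).swapaxes(1, 2)  # (n, hw, c)
        attended = scaled_dot_attention(
            self.q_proj(tokens), self.k_proj(tokens), self.v_proj(tokens), self.d_k
        )
        out = tokens + attended
        return out.swapaxes(1, 2).reshape(n, c, h, w)


class _ConvBlock(Module):
    def __init__(self, cin: int, cout: int, rng, stride: int, batch_norm: bool):
        super().__init__()
        self.conv = Conv2d(cin, cout, 3, rng, stride=stride, padding=1)
        self.bn = BatchNorm2d(cout) if batch_norm else None

    def forward(self, x: Tensor) -> Tensor:
        x = self.conv(x)
        if self.bn is not None:
            x = self.bn(x)
        return x.relu()


class GAE(Module):
    def __init__(self, config: GAEConfig, init_seed: int):
        super().__init__()
        self.config = config
        self.init_seed = int(init_seed)
        rng = np.random.default_rng(np.random.SeedSequence(self.init_seed))
        chans = config.channel_schedule()
        enc_in = [config.in_channels] + chans[:-1]
        self.encoder_stages = [
            _ConvBlock(ci, co, rng, stride=2, batch_norm=config.batch_norm)
            for ci, co in zip(enc_in, chans)
        ]
        self.attention = SelfAttention2d(config.latent_channels, config.attention_dim, rng)
        dec_out = list(reversed(enc_in))  # mirror
        dec_in = list(reversed(chans))
        self.decoder_stages = []
        for i, (ci, co) in enumerate(zip(dec_in, dec_out)):
            last = i == len(dec_in) - 1
            if last:
                self.decoder_stages.append(Conv2d(ci, co, 3, rng, stride=1, padding=1))
            else:
                self.decoder_stages.append(
                    _ConvBlock(ci, co, rng, stride=1, batch_norm=config.batch_norm))

    def _check_size(self, h: int, w: int) -> None:
        f = 2 ** self.config.encoder_depth
        if h < f or w < f or h % f or w % f:
            raise ConfigError(
                f"image size {h}x{w} incompatible with encoder_depth "
                f"{self.config.encoder_depth} (needs multiples of {f})")

    def encode(self, x: Tensor) -> Tensor:
        self._check_size(x.shape[2], x.shape[3])
        for stage in self.encoder_stages:
            x = stage(x)
        return self.attention(x)

    def decode(self, z: Tensor) -> Tensor:
        for i, stage in enumerate(self.decoder_stages):
            z = upsample_nearest2x(z)
            z = stage(z)
        return z

    def forward(self, x: Tensor) -> Tensor:
        return self.decode(self.encode(x))


def build_gae(config: GAEConfig, init_seed: int, image_size: int | None = None) -> GAE:
    """Construct a GAE; identical (config, seed) give identical parameters."""
    model = GAE(config, init_seed)
    if image_size is not None:
        model._check_size(image_size, image_size)
    return model


def _as_batch(images: np.ndarray) -> np.ndarray:
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 3:  # (N, H, W) -> single channel
        images = images[:, None, :, :]
    if images.ndim != 4:
        raise ValueError("expected images of shape (N, H, W) or (N, C, H, W)")
    return images


def reconstruction_mse(model: GAE, images: np.ndarray, batch_size: int = 16) -> float:
    """Mean squared reconstruction error over a dataset (eval mode)."""
    images = _as_batch(images)
    model.eval()
    total, count = 0.0, 0
    for start in range(0, len(images), batch_size):
        xb = images[start:start + batch_size]
        recon = model(Tensor(xb)).data
        total += float(((recon - xb) ** 2).sum())
        count += xb.size
    return total / count


def pretrain_gae(model: GAE, images: np.ndarray, train_config: TrainConfig,
                 val_images: np.ndarray | None = None) -> tuple[GAE, list[dict]]:
    """Unsupervised reconstruction pre-training (MSE, Adam).

    Returns the trained model and a history with one row per epoch run
    (``epoch``, ``train_loss`` and, when a validation set is given,
    ``val_loss``).  With a validation set, early stopping monitors validation
    reconstruction loss and the best parameters are restored.
    """
    images = _as_batch(images)
    if len(images) == 0:
        raise ValueError("need at least one training image")
    val = _as_batch(val_images) if val_images is not None else None

    optimizer = Adam(model.parameters(), lr=train_config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence(train_config.seed, spawn_key=(11,)))
    stopper = EarlyStopper(train_config.patience) if val is not None else None
    best_state = None
    history: list[dict] = []

    for epoch in range(train_config.max_epochs):
        model.train()
        losses = []
        for idx in minibatch_indices(len(images), train_config.batch_size, rng):
            xb = Tensor(images[idx])
            recon = model(xb)
            loss = ((recon - xb) ** 2).mean()
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(loss.item())
        row = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if val is not None:
            row["val_loss"] = reconstruction_mse(model, val)
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


def _single_image_batch(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        return image[None, None]
    if image.ndim == 3:  # (C, H, W)
        return image[None]
    raise ValueError("expected a single 2-D image, optionally with channels")


def encode_image(model: GAE, image: np.ndarray) -> LatentMap:
    """Deterministic latent map of one image (eval mode, running BN stats)."""
    batch = _single_image_batch(image)
    model.eval()
    z = model.encode(Tensor(batch)).data[0]  # (d, h', w')
    return LatentMap(grid=np.ascontiguousarray(z.transpose(1, 2, 0)),
                     source_shape=batch.shape[2:],
                     downsample_factor=2 ** model.config.encoder_depth)


def reconstruct_image(model: GAE, image: np.ndarray) -> np.ndarray:
    batch = _single_image_batch(image)
    model.eval()
    recon = model(Tensor(batch)).data[0]
    return recon[0] if np.asarray(image).ndim == 2 else recon
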