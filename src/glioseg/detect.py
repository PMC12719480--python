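"""Tumor-presence detection and coarse ROI generation.

A small residual CNN produces two-class logits (tumor / non-tumor) turned into
probabilities with a softmax; a probability gate decides whether segmentation
runs at all.  For positive cases, the spatial latent map from the autoencoder
is clustered with k-means (Lloyd's algorithm, k-means++ seeding, deterministic
restarts) and the tumor-like cluster — the minority cluster with the highest
mean feature norm — is upsampled to image resolution as a coarse region of
interest.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, StratificationError
from .gae import LatentMap
from .nn import Adam, BatchNorm2d, Conv2d, Linear, Module, Tensor
from .train import EarlyStopper, TrainConfig, minibatch_indices

__all__ = [
    "ClassifierConfig", "ClassProb", "ClusterResult", "ROIMask",
    "build_classifier", "classify", "train_classifier",
    "kmeans_latent", "roi_from_clusters", "gate",
]


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassifierConfig:
    """Reduced residual stack: stem conv + ``n_blocks`` residual blocks.

    ``input_kind`` selects what the classifier sees: the preprocessed image
    (default) or the autoencoder latent map.
    """

    in_channels: int = 1
    base_channels: int = 8
    n_blocks: int = 2
    n_classes: int = 2
    zero_init_residual: bool = False
    input_kind: str = "image"

    def __post_init__(self):
        if self.n_blocks < 1 or self.base_channels < 1:
            raise ConfigError("n_blocks and base_channels must be >= 1")
        if self.input_kind not in ("image", "latent"):
            raise ConfigError("input_kind must be 'image' or 'latent'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ClassProb:
    probs: np.ndarray
    logits: np.ndarray

    @property
    def predicted(self) -> int:
        return int(np.argmax(self.probs))

    @property
    def tumor_probability(self) -> float:
        return float(self.probs[1])


class _ResBlock(Module):
    def __init__(self, cin: int, cout: int, rng, stride: int, zero_init: bool):
        super().__init__()
        self.conv1 = Conv2d(cin, cout, 3, rng, stride=stride, padding=1)
        self.bn1 = BatchNorm2d(cout)
        self.conv2 = Conv2d(cout, cout, 3, rng, stride=1, padding=1)
        self.bn2 = BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.short = Conv2d(cin, cout, 1, rng, stride=stride, bias=False)
        else:
            self.short = None
        # learnable scalar gain on the residual branch; 0 makes the block an
        # identity at initialization
        self.scale = Tensor(np.array(0.0 if zero_init else 1.0), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        branch = self.bn2(self.conv2(self.bn1(self.conv1(x)).relu()))
        shortcut = self.short(x) if self.short is not None else x
        return (shortcut + branch * self.scale).relu()


class Classifier(Module):
    def __init__(self, config: ClassifierConfig, init_seed: int):
        super().__init__()
        self.config = config
        self.init_seed = int(init_seed)
        rng = np.random.default_rng(np.random.SeedSequence(self.init_seed))
        c = config.base_channels
        self.stem = Conv2d(config.in_channels, c, 3, rng, stride=1, padding=1)
        self.stem_bn = BatchNorm2d(c)
        blocks = []
        cin = c
        for i in range(config.n_blocks):
            cout = c * 2 ** i
            stride = 1 if i == 0 else 2
            blocks.append(_ResBlock(cin, cout, rng, stride, config.zero_init_residual))
            cin = cout
        self.blocks = blocks
        self.head = Linear(cin, config.n_classes, rng)

    def stem_forward(self, x: Tensor) -> Tensor:
        return self.stem_bn(self.stem(x)).relu()

    def forward_features(self, x: Tensor) -> Tensor:
        x = self.stem_forward(x)
        for block in self.blocks:
            x = block(x)
        return x

    def forward(self, x: Tensor) -> Tensor:
        feats = self.forward_features(x)
        pooled = feats.mean(axis=(2, 3))  # global average pool -> (n, c)
        return self.head(pooled)


def build_classifier(config: ClassifierConfig, init_seed: int) -> Classifier:
    return Classifier(config, init_seed)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _classifier_input(model: Classifier, x) -> np.ndarray:
    if isinstance(x, LatentMap):
        arr = x.grid.transpose(2, 0, 1)
    else:
        arr = np.asarray(x, dtype=np.float64)
        if arr.ndim == 2:
            arr = arr[None]
    return arr[None]  # batch of one


def classify(model: Classifier, x) -> ClassProb:
    """Two-class softmax probabilities for an image or a LatentMap."""
    model.eval()
    logits = model(Tensor(_classifier_input(model, x))).data[0]
    if not np.all(np.isfinite(logits)):
        raise FloatingPointError("non-finite classifier logits")
    return ClassProb(probs=_softmax(logits), logits=logits)


def train_classifier(model: Classifier, inputs: np.ndarray, labels: np.ndarray,
                     train_config: TrainConfig,
                     val_inputs: np.ndarray | None = None,
                     val_labels: np.ndarray | None = None
                     ) -> tuple[Classifier, list[dict]]:
    """Cross-entropy training with Adam and early stopping on validation loss.

    ``inputs`` is (N, C, H, W) (or (N, H, W)); ``labels`` is an int vector
    (0 = non-tumor, 1 = tumor).  History rows carry per-epoch train/val loss
    and accuracy.
    """
    inputs = np.asarray(inputs, dtype=np.float64)
    if inputs.ndim == 3:
        inputs = inputs[:, None]
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise StratificationError("training set contains a single class")
    has_val = val_inputs is not None and val_labels is not None
    if has_val:
        val_inputs = np.asarray(val_inputs, dtype=np.float64)
        if val_inputs.ndim == 3:
            val_inputs = val_inputs[:, None]
        val_labels = np.asarray(val_labels, dtype=int)

    optimizer = Adam(model.parameters(), lr=train_config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence(train_config.seed, spawn_key=(22,)))
    stopper = EarlyStopper(train_config.patience) if has_val else None
    best_state = None
    history: list[dict] = []

    def xent(logits: Tensor, y: np.ndarray) -> Tensor:
        m = Tensor(logits.data.max(axis=1, keepdims=True))
        lse = ((logits - m).exp().sum(axis=1, keepdims=True)).log() + m
        onehot = np.eye(model.config.n_classes)[y]
        picked = (logits * Tensor(onehot)).sum(axis=1, keepdims=True)
        return (lse - picked).mean()

    def evaluate(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        model.eval()
        logits = np.concatenate([
            model(Tensor(x[s:s + 32])).data for s in range(0, len(x), 32)
        ])
        probs = _softmax(logits)
        loss = float(-np.mean(np.log(np.clip(probs[np.arange(len(y)), y], 1e-12, None))))
        acc = float(np.mean(np.argmax(probs, axis=1) == y))
        return loss, acc

    for epoch in range(train_config.max_epochs):
        model.train()
        losses = []
        for idx in minibatch_indices(len(inputs), train_config.batch_size, rng):
            logits = model(Tensor(inputs[idx]))
            loss = xent(logits, labels[idx])
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(loss.item())
        k = min(len(inputs), 64)
        _, tr_acc = evaluate(inputs[:k], labels[:k])
        row = {"epoch": epoch, "train_loss": float(np.mean(losses)), "train_acc": tr_acc}
        if has_val:
            row["val_loss"], row["val_acc"] = evaluate(val_inputs, val_labels)
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
# latent k-means and ROI
# ---------------------------------------------------------------------------


@dataclass
class ClusterResult:
    assignments: np.ndarray       # (h', w') int cluster index
    centroids: np.ndarray         # (k, d)
    inertia: float
    k: int
    seed: int
    inertia_history: list[float] = field(default_factory=list)

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.assignments.ravel(), minlength=self.k)


def _kmeans_pp_init(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = len(points)
    centroids = np.empty((k, points.shape[1]))
    centroids[0] = points[rng.integers(n)]
    d2 = ((points - centroids[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            centroids[j] = points[rng.integers(n)]
        else:
            centroids[j] = points[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, ((points - centroids[j]) ** 2).sum(axis=1))
    return centroids


def _lloyd(points: np.ndarray, centroids: np.ndarray, max_iter: int
           ) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    k = len(centroids)
    history: list[float] = []
    assign = None
    for _ in range(max_iter):
        d2 = ((points[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_assign = d2.argmin(axis=1)  # argmin breaks ties toward lowest index
        inertia = float(d2[np.arange(len(points)), new_assign].sum())
        history.append(inertia)
        if assign is not None and np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for j in range(k):
            members = points[assign == j]
            if len(members):
                centroids[j] = members.mean(axis=0)
            else:  # re-seed an empty cluster from the farthest point
                far = d2.min(axis=1).argmax()
                centroids[j] = points[far]
    d2 = ((points[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    assign = d2.argmin(axis=1)
    inertia = float(d2[np.arange(len(points)), assign].sum())
    return assign, centroids, inertia, history


def kmeans_latent(latent: LatentMap | np.ndarray, k: int, seed: int,
                  n_init: int = 10, max_iter: int = 100) -> ClusterResult:
    """Lloyd's k-means with k-means++ seeding over latent grid positions.

    Runs ``n_init`` deterministic restarts (seeded from ``seed``) and keeps
    the lowest-inertia solution.  Ties in assignment go to the lowest cluster
    index; empty clusters are re-seeded from the farthest point.
    """
    if isinstance(latent, LatentMap):
        grid_shape = latent.grid.shape[:2]
        points = latent.grid.reshape(-1, latent.dim).astype(np.float64)
    else:
        arr = np.asarray(latent, dtype=np.float64)
        if arr.ndim == 3:
            grid_shape = arr.shape[:2]
            points = arr.reshape(-1, arr.shape[2])
        else:
            grid_shape = (len(arr),)
            points = arr.reshape(len(arr), -1)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(points):
        raise ValueError(f"k={k} exceeds the number of positions ({len(points)})")

    best = None
    for restart in range(n_init):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(restart,)))
        centroids = _kmeans_pp_init(points, k, rng)
        assign, cents, inertia, hist = _lloyd(points, centroids, max_iter)
        if best is None or inertia < best[2]:
            best = (assign, cents, inertia, hist)
    assign, cents, inertia, hist = best
    return ClusterResult(assignments=assign.reshape(grid_shape), centroids=cents,
                         inertia=inertia, k=k, seed=seed, inertia_history=hist)


@dataclass
class ROIMask:
    mask: np.ndarray
    source: str = "latent_kmeans"


def roi_from_clusters(cluster: ClusterResult, latent: LatentMap) -> ROIMask:
    """Upsample the tumor-like cluster to image resolution.

    Tumor-cluster rule: exclude the largest cluster (assumed background), then
    among the remaining clusters pick the one whose member feature vectors
    have the highest mean L2 norm.  A degenerate single-occupied-cluster
    result yields an empty ROI with a warning.
    """
    sizes = cluster.cluster_sizes()
    occupied = np.flatnonzero(sizes > 0)
    if len(occupied) < 2:
        warnings.warn("degenerate clustering (single cluster): empty ROI")
        return ROIMask(mask=np.zeros(latent.source_shape, dtype=np.uint8), source="none")
    largest = occupied[np.argmax(sizes[occupied])]
    candidates = [j for j in occupied if j != largest]
    feats = latent.grid.reshape(-1, latent.dim)
    norms = np.linalg.norm(feats, axis=1)
    flat_assign = cluster.assignments.ravel()
    mean_norm = [norms[flat_assign == j].mean() for j in candidates]
    tumor_cluster = candidates[int(np.argmax(mean_norm))]

    low = (cluster.assignments == tumor_cluster).astype(np.uint8)
    f = latent.downsample_factor
    mask = low.repeat(f, axis=0).repeat(f, axis=1)
    h, w = latent.source_shape[-2:]
    return ROIMask(mask=mask[:h, :w], source="latent_kmeans")


def gate(class_prob: ClassProb, tau: float) -> str:
    """Decide whether to run segmentation: 'segment' iff P(tumor) >= tau."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must be in [0, 1]")
    return "segment" if class_prob.tumor_probability >= tau else "skip"
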