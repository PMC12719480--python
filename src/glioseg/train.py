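"""Shared training plumbing: config, minibatching, early stopping, checkpoints.

Defaults follow the training recipe used throughout the pipeline: Adam with
learning rate 3e-4, batch size 8, up to 20 epochs, early stopping on
validation loss, and a fixed seed of 42 applied to shuffling and
initialization.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .nn import Module

__all__ = ["TrainConfig", "EarlyStopper", "minibatch_indices",
           "save_checkpoint", "load_checkpoint_state"]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 3e-4
    batch_size: int = 8
    max_epochs: int = 20
    patience: int = 3
    seed: int = 42

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")
        if self.patience < 1:
            raise ConfigError("patience must be >= 1")
        if self.max_epochs < 0:
            raise ConfigError("max_epochs must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class EarlyStopper:
    """Stop when the monitored loss fails to improve for ``patience`` epochs.

    ``update`` returns True when training should stop.  The best value and the
    epoch it occurred at are retained so callers can restore best weights.
    """

    def __init__(self, patience: int, min_delta: float = 0.0):
        if patience < 1:
            raise ConfigError("patience must be >= 1")
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.best_epoch = -1
        self.stale = 0

    def update(self, value: float, epoch: int) -> bool:
        if value < self.best - self.min_delta:
            self.best = value
            self.best_epoch = epoch
            self.stale = 0
            return False
        self.stale += 1
        return self.stale >= self.patience


def minibatch_indices(n: int, batch_size: int, rng: np.random.Generator):
    """Yield shuffled index batches covering range(n)."""
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def save_checkpoint(path: str | Path, model: Module, config_dict: dict, init_seed: int) -> None:
    """Single-file checkpoint: parameters + buffers + config + seed."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = json.dumps({"config": config_dict, "init_seed": int(init_seed)})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **model.state_dict())


def load_checkpoint_state(path: str | Path) -> tuple[dict, int, dict[str, np.ndarray]]:
    """Return (config_dict, init_seed, state_dict) from a checkpoint file."""
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    return meta["config"], int(meta["init_seed"]), state
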