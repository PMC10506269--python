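"""SGD training loop with validation-accuracy early stopping.

The monitor is top-1 accuracy on the validation split.  Improvement means
strictly greater than the best value seen so far; after ``patience`` epochs
without improvement training stops and the weights checkpointed at the best
epoch are restored (not the last-epoch weights).
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .evaluation import top_k_accuracy
from .model import Model, bce_loss

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "TrainHistory", "epoch_accuracy", "train"]


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.01
    momentum: float = 0.9
    batch_size: int = 64
    max_epochs: int = 200
    patience: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be < max_epochs")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")


@dataclasses.dataclass
class TrainHistory:
    """Per-epoch curves plus where training peaked and stopped (1-indexed)."""

    train_loss: list[float] = dataclasses.field(default_factory=list)
    train_accuracy: list[float] = dataclasses.field(default_factory=list)
    val_loss: list[float] = dataclasses.field(default_factory=list)
    val_accuracy: list[float] = dataclasses.field(default_factory=list)
    best_epoch: int = 0
    stopped_epoch: int = 0

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("epoch\ttrain_loss\ttrain_accuracy\tval_loss\tval_accuracy\n")
            rows = zip(self.train_loss, self.train_accuracy,
                       self.val_loss, self.val_accuracy)
            for e, (tl, ta, vl, va) in enumerate(rows, start=1):
                fh.write(f"{e}\t{tl:.8f}\t{ta:.8f}\t{vl:.8f}\t{va:.8f}\n")


def epoch_accuracy(scores: np.ndarray, y: np.ndarray) -> float:
    """The training monitor: top-1 accuracy of the score matrix."""
    return top_k_accuracy(scores, y, k=1)


def _mean_bce(pred: np.ndarray, y: np.ndarray) -> float:
    """Per-sample mean of the summed-BCE objective (reported in histories)."""
    return bce_loss(pred, y) / pred.shape[0]


def train(
    model: Model,
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray],
    cfg: TrainConfig,
    monitor_fn: Callable[[Model, np.ndarray, np.ndarray], float] | None = None,
) -> tuple[Model, TrainHistory]:
    """Mini-batch SGD with momentum, returning the best-epoch model.

    ``monitor_fn(model, x_val, y_val)`` overrides the early-stopping monitor
    (default: validation top-1 accuracy); used to test stopping semantics.
    """
    x_train, y_train = np.asarray(train_data[0], dtype=np.float64), np.asarray(train_data[1])
    x_val, y_val = np.asarray(val_data[0], dtype=np.float64), np.asarray(val_data[1])
    if x_train.shape[0] == 0:
        raise ValueError("empty training set")
    if x_val.shape[0] == 0:
        raise ValueError("empty validation set: early-stopping monitor undefined")
    if x_train.shape[0] != y_train.shape[0] or x_val.shape[0] != y_val.shape[0]:
        raise ValueError("inputs and labels disagree on sample count")

    n = x_train.shape[0]
    rng = np.random.default_rng(cfg.seed)
    velocity = [np.zeros_like(p) for p in model.params]
    history = TrainHistory()
    best_value = -np.inf
    best_weights = model.get_weights()
    best_epoch = 0

    for epoch in range(1, cfg.max_epochs + 1):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        # training-mode scores, reused for the epoch's train accuracy
        train_scores = np.empty_like(y_train, dtype=np.float64)
        for start in range(0, n, cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            model.zero_grad()
            probs = model.forward(xb, train=True, rng=rng)
            train_scores[idx] = probs
            epoch_loss += bce_loss(probs, yb)
            # d(mean-BCE)/d(logits) = (p - y) / B, fused with the sigmoid
            model.backward_from_logits((probs - yb) / xb.shape[0])
            for p, g, v in zip(model.params, model.grads, velocity):
                v *= cfg.momentum
                v -= cfg.learning_rate * g
                p += v

        val_scores = model.predict(x_val, batch_size=cfg.batch_size)
        history.train_loss.append(epoch_loss / n)
        history.train_accuracy.append(epoch_accuracy(train_scores, y_train))
        history.val_loss.append(_mean_bce(val_scores, y_val))
        history.val_accuracy.append(epoch_accuracy(val_scores, y_val))

        if monitor_fn is not None:
            monitor = monitor_fn(model, x_val, y_val)
        else:
            monitor = history.val_accuracy[-1]
        if monitor > best_value:  # strict improvement resets patience
            best_value = monitor
            best_epoch = epoch
            best_weights = model.get_weights()
        logger.info(
            "epoch %d: train_loss=%.4f val_acc=%.4f monitor=%.4f (best %.4f @ %d)",
            epoch, history.train_loss[-1], history.val_accuracy[-1],
            monitor, best_value, best_epoch,
        )
        if epoch - best_epoch >= cfg.patience:
            logger.info("early stopping at epoch %d (no improvement since %d)",
                        epoch, best_epoch)
            break

    history.best_epoch = best_epoch
    history.stopped_epoch = epoch
    model.set_weights(best_weights)
    return model, history
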