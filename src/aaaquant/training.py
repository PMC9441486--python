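"""Optimization of the segmentation network.

The loss is the squared Jaccard distance on softmax probabilities:

    L = 1 - I / U,   I = sum(p * g),   U = sum(p**2) + sum(g**2) - I

summed over classes and non-ignored pixels (one global ratio per
batch).  Pixels labeled "ignore" are masked out of both numerator and
denominator, so they contribute exactly zero gradient — the network is
free to decide what those uncertain border pixels are.

Training uses Adam; after every epoch the loss, Jaccard similarity
index and F1 score are recorded for the training and validation sets,
and the parameter set with the lowest validation loss is kept.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .augment import AugmentationPlan, NormalizationStats, apply_augmentation, normalize
from .classes import CLASS_INDEX, N_CLASSES
from .network import UNet, Param
from .tiling import TileRecord

__all__ = [
    "squared_jaccard_loss",
    "squared_jaccard_grad",
    "TrainConfig",
    "TrainingState",
    "TrainingDiverged",
    "Adam",
    "train",
    "predict_tiles",
]


class TrainingDiverged(RuntimeError):
    pass


def _masked(pred: np.ndarray, target_onehot: np.ndarray,
            mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, float]:
    if not mask.any():
        raise ValueError("all pixels are ignored; loss is undefined")
    m = mask[:, None, :, :]
    p = pred * m
    g = target_onehot * m
    inter = float((p * g).sum())
    union = float((p * p).sum() + (g * g).sum() - inter)
    return p, g, inter, union


def squared_jaccard_loss(pred: np.ndarray, target_onehot: np.ndarray,
                         mask: np.ndarray) -> float:
    """Squared Jaccard distance in [0, 1] over non-ignored pixels.

    ``pred`` and ``target_onehot`` are (N, C, H, W); ``mask`` is
    (N, H, W), True where the pixel counts.
    """
    _, _, inter, union = _masked(pred, target_onehot, mask)
    if union == 0.0:
        return 0.0
    return 1.0 - inter / union


def squared_jaccard_grad(pred: np.ndarray, target_onehot: np.ndarray,
                         mask: np.ndarray) -> tuple[float, np.ndarray]:
    """Loss value and its gradient w.r.t. ``pred``."""
    p, g, inter, union = _masked(pred, target_onehot, mask)
    if union == 0.0:
        return 0.0, np.zeros_like(pred)
    loss = 1.0 - inter / union
    # d(1 - I/U)/dp = (I * dU - U * dI) / U^2, dI = g, dU = 2p - g
    grad = (inter * (2.0 * p - g) - union * g) / (union * union)
    grad *= mask[:, None, :, :]
    return loss, grad


def one_hot(labels: np.ndarray, n_classes: int = N_CLASSES) -> np.ndarray:
    """(N, H, W) int labels -> (N, C, H, W) float one-hot."""
    out = np.zeros((labels.shape[0], n_classes, *labels.shape[1:]))
    for c in range(n_classes):
        out[:, c] = labels == c
    return out


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 20
    learning_rate: float = 1e-4
    batch_size: int = 8
    augment: bool = True
    augment_p: float = 0.5
    seed: int = 0
    ignore_index: int = CLASS_INDEX["ignore"]
    #: optional early stop once the validation Jaccard reaches this value
    stop_at_val_jaccard: float | None = None


@dataclass
class TrainingState:
    """Per-epoch metric curves and the best-epoch bookkeeping."""

    history: list[dict] = field(default_factory=list)
    best_epoch: int = 0  # 1-based epoch index with minimal validation loss
    best_val_loss: float = np.inf
    seed: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.history)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad * p.grad
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _hard_metrics(cm: np.ndarray, ignore_index: int) -> tuple[float, float]:
    """Support-weighted Jaccard and F1 from a confusion matrix, excl. ignore."""
    keep = [c for c in range(cm.shape[0]) if c != ignore_index]
    tp = cm.diagonal().astype(float)
    support = cm.sum(axis=1).astype(float)
    predicted = cm.sum(axis=0).astype(float)
    j_num = f_num = wsum = 0.0
    for c in keep:
        if support[c] == 0:
            continue
        fp = predicted[c] - tp[c]
        fn = support[c] - tp[c]
        denom_j = tp[c] + fp + fn
        jac = tp[c] / denom_j if denom_j else 0.0
        f1 = 2 * tp[c] / (2 * tp[c] + fp + fn) if (2 * tp[c] + fp + fn) else 0.0
        j_num += support[c] * jac
        f_num += support[c] * f1
        wsum += support[c]
    if wsum == 0:
        return 0.0, 0.0
    return j_num / wsum, f_num / wsum


def _prep_batch(records: list[TileRecord], stats: NormalizationStats | None,
                ignore_index: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    xs, labels = [], []
    for r in records:
        x = normalize(r.input_tile, stats) if stats else np.asarray(r.input_tile, float)
        xs.append(np.transpose(x, (2, 0, 1)))
        labels.append(np.asarray(r.target_tile))
    x = np.stack(xs)
    y = np.stack(labels)
    mask = y != ignore_index
    return x, y, mask


def _evaluate(model: UNet, records: list[TileRecord], stats: NormalizationStats | None,
              cfg: TrainConfig) -> dict:
    model.set_train(False)
    n_classes = model.cfg.n_classes
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    losses, weights = [], []
    for i in range(0, len(records), cfg.batch_size):
        batch = records[i : i + cfg.batch_size]
        x, y, mask = _prep_batch(batch, stats, cfg.ignore_index)
        probs = model.forward(x)
        losses.append(squared_jaccard_loss(probs, one_hot(y, n_classes), mask))
        weights.append(len(batch))
        pred = probs.argmax(axis=1)
        valid = mask.ravel()
        cm += np.bincount(
            y.ravel()[valid] * n_classes + pred.ravel()[valid],
            minlength=n_classes * n_classes,
        ).reshape(n_classes, n_classes)
    jac, f1 = _hard_metrics(cm, cfg.ignore_index)
    loss = float(np.average(losses, weights=weights))
    return {"loss": loss, "jaccard": jac, "f1": f1}


def train(
    model: UNet,
    train_records: list[TileRecord],
    val_records: list[TileRecord],
    cfg: TrainConfig,
    stats: NormalizationStats | None = None,
    checkpoint_path: str | Path | None = None,
) -> TrainingState:
    """Run the optimization loop and restore the best validation weights.

    Returns the :class:`TrainingState` with one history row per epoch
    (train/val loss, Jaccard, F1).  The model is left holding the
    parameters of the epoch with minimal validation loss; if
    ``checkpoint_path`` is given that state is also saved to disk.
    """
    if not train_records or not val_records:
        raise ValueError("training and validation sets must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    optimizer = Adam(model.params(), lr=cfg.learning_rate)
    state = TrainingState(seed=cfg.seed)
    best_weights = None
    n_classes = model.cfg.n_classes

    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(len(train_records))
        model.set_train(True)
        epoch_losses = []
        for i in range(0, len(order), cfg.batch_size):
            batch = [train_records[j] for j in order[i : i + cfg.batch_size]]
            if cfg.augment:
                batch = [
                    apply_augmentation(r, AugmentationPlan.sample(rng, cfg.augment_p))
                    for r in batch
                ]
            x, y, mask = _prep_batch(batch, stats, cfg.ignore_index)
            if not mask.any():
                continue
            probs = model.forward(x)
            loss, grad = squared_jaccard_grad(probs, one_hot(y, n_classes), mask)
            if not np.isfinite(loss):
                raise TrainingDiverged(
                    f"loss became non-finite at epoch {epoch} "
                    f"(lr={cfg.learning_rate}, batch={cfg.batch_size})"
                )
            model.zero_grad()
            model.backward(grad)
            optimizer.step()
            epoch_losses.append(loss)

        train_metrics = _evaluate(model, train_records, stats, cfg)
        val_metrics = _evaluate(model, val_records, stats, cfg)
        state.history.append(
            {
                "epoch": epoch,
                "train_loss": train_metrics["loss"],
                "val_loss": val_metrics["loss"],
                "train_jaccard": train_metrics["jaccard"],
                "val_jaccard": val_metrics["jaccard"],
                "train_f1": train_metrics["f1"],
                "val_f1": val_metrics["f1"],
            }
        )
        if val_metrics["loss"] < state.best_val_loss:
            state.best_val_loss = val_metrics["loss"]
            state.best_epoch = epoch
            best_weights = copy.deepcopy(model.state_dict())
        if (cfg.stop_at_val_jaccard is not None
                and val_metrics["jaccard"] >= cfg.stop_at_val_jaccard):
            break

    if best_weights is not None:
        model.load_state_dict(best_weights)
        if checkpoint_path is not None:
            model.save(checkpoint_path)
    return state


def predict_tiles(model: UNet, tiles: list[tuple[tuple[int, int], np.ndarray]],
                  stats: NormalizationStats | None = None,
                  batch_size: int = 8) -> list[tuple[tuple[int, int], np.ndarray]]:
    """Inference on (origin, rgb tile) pairs -> (origin, prob map HWC)."""
    model.set_train(False)
    out = []
    for i in range(0, len(tiles), batch_size):
        chunk = tiles[i : i + batch_size]
        xs = []
        for _, tile in chunk:
            x = normalize(tile, stats) if stats else np.asarray(tile, float)
            xs.append(np.transpose(x, (2, 0, 1)))
        probs = model.forward(np.stack(xs))
        for (origin, _), p in zip(chunk, probs):
            out.append((origin, np.transpose(p, (1, 2, 0))))
    return out
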