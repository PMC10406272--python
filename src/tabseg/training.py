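"""Probability-map regression training: MSE loss, Adam, early stopping, and
a best-validation checkpoint policy."""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .nn.optim import Adam
from .nn.tensor import Tensor, no_grad
from .model_zoo import SegmentationModel
from .phantom import PhantomDataset
from .preprocess import normalize_minus1_1

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "TrainHistory", "ArrayDataset", "mse_loss", "train",
           "arrays_from_phantoms"]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 350
    batch_size: int = 3
    lr: float = 1e-5
    weight_decay: float = 1e-6
    patience: int = 25
    seed: int = 0
    checkpoint_policy: str = "best_val"

    def validate(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.checkpoint_policy != "best_val":
            raise ValueError("only the best-validation checkpoint policy is supported")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1  # 0-based index into the loss lists

    @property
    def best_val_loss(self) -> float:
        return self.val_loss[self.best_epoch]


@dataclass
class ArrayDataset:
    """In-memory training arrays: inputs (n, 1, D, D, D), targets (n, 3, D, D, D)."""

    train_x: np.ndarray
    train_y: np.ndarray
    val_x: np.ndarray
    val_y: np.ndarray

    def validate(self) -> None:
        if len(self.train_x) == 0 or len(self.val_x) == 0:
            raise ValueError("train and validation splits must be nonempty")
        if self.train_x.shape[1:] != self.val_x.shape[1:]:
            raise ValueError("train/val input shapes differ")
        if self.train_x.shape[0] != self.train_y.shape[0]:
            raise ValueError("input/target counts differ")


def arrays_from_phantoms(dataset: PhantomDataset, normalize: bool = True) -> ArrayDataset:
    """Stack phantom subjects into training arrays, normalizing each volume
    to [-1, 1] as the training contract requires."""

    def collect(split):
        xs, ys = [], []
        for sub in dataset.members(split):
            vol = normalize_minus1_1(sub.volume) if normalize else sub.volume
            xs.append(vol.values[None])
            ys.append(sub.probmap.values)
        return np.asarray(xs, np.float32), np.asarray(ys, np.float32)

    tx, ty = collect("train")
    vx, vy = collect("val")
    return ArrayDataset(tx, ty, vx, vy)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean over all channels and voxels of the squared difference."""
    pred = np.asarray(pred)
    target = np.asarray(target)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    return float(np.mean((pred.astype(np.float64) - target.astype(np.float64)) ** 2))


def _tensor_mse(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred - Tensor(target)
    return (diff * diff).mean()


def _validation_loss(model: SegmentationModel, dataset: ArrayDataset, batch: int) -> float:
    model.eval()
    total, count = 0.0, 0
    with no_grad():
        for i in range(0, len(dataset.val_x), batch):
            xb = dataset.val_x[i : i + batch]
            yb = dataset.val_y[i : i + batch]
            probs = model.forward(Tensor(xb))
            total += mse_loss(probs.data, yb) * len(xb)
            count += len(xb)
    model.train()
    return total / count


def train(
    model: SegmentationModel,
    dataset: ArrayDataset | PhantomDataset,
    cfg: TrainConfig,
) -> tuple[SegmentationModel, TrainHistory]:
    """Adam-driven regression training with early stopping.

    Stops after ``patience`` epochs without validation improvement or at
    ``epochs``; the weights of the best-validation epoch are restored before
    returning. Fully seeded: data order and dropout derive from ``cfg.seed``.
    """
    cfg.validate()
    if isinstance(dataset, PhantomDataset):
        dataset = arrays_from_phantoms(dataset)
    dataset.validate()
    rng = np.random.default_rng(cfg.seed)
    # reseed every dropout module so runs are reproducible end to end
    for mod in _iter_modules(model):
        if hasattr(mod, "rng") and hasattr(mod, "p"):
            mod.rng = np.random.default_rng(rng.integers(2 ** 63))

    optimizer = Adam(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    history = TrainHistory()
    best_state = None
    best_val = np.inf
    stale = 0
    n_train = len(dataset.train_x)
    model.train()
    for epoch in range(cfg.epochs):
        order = rng.permutation(n_train)
        total, count = 0.0, 0
        for i in range(0, n_train, cfg.batch_size):
            sel = order[i : i + cfg.batch_size]
            xb = dataset.train_x[sel]
            yb = dataset.train_y[sel]
            optimizer.zero_grad()
            probs = model.forward(Tensor(xb))
            loss = _tensor_mse(probs, yb)
            val = loss.item()
            if not np.isfinite(val):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}: {val}")
            loss.backward()
            optimizer.step()
            total += val * len(sel)
            count += len(sel)
        train_loss = total / count
        val_loss = _validation_loss(model, dataset, cfg.batch_size)
        if not np.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        history.train_loss.append(train_loss)
        history.val_loss.append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            history.best_epoch = epoch
            best_state = model.state_dict()
            stale = 0
        else:
            stale += 1
        logger.info(
            "epoch=%d train_loss=%.6f val_loss=%.6f best_epoch=%d",
            epoch, train_loss, val_loss, history.best_epoch,
        )
        if stale >= cfg.patience:
            break
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return model, history


def _iter_modules(module):
    yield module
    for child in module._children.values():
        yield from _iter_modules(child)
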