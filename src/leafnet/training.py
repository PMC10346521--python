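"""Training protocol: cross-entropy minimization with a plateau schedule.

The protocol mirrors the study design: batch size 32, 30 epochs,
categorical cross-entropy, and reduce-on-plateau — if validation loss
fails to improve for five consecutive epochs the learning rate is
halved.  The optimizer grid sweeps {SGD, RMSprop, Adam} against initial
learning rates {5e-3, 5e-4, 5e-5} and summarizes each cell by its
final-five-epoch mean validation accuracy and loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import autodiff as ad
from .datapipe import Dataset
from .utils import derive_seed

OPTIMIZERS = ("adam", "rmsprop", "sgd")
GRID_LEARNING_RATES = (5e-3, 5e-4, 5e-5)


@dataclass
class TrainConfig:
    batch_size: int = 32
    epochs: int = 30
    optimizer: str = "adam"
    learning_rate: float = 5e-4
    plateau_patience: int = 5
    plateau_factor: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.0 < self.plateau_factor < 1.0:
            raise ValueError("plateau_factor must lie in (0, 1)")
        if self.optimizer not in OPTIMIZERS:
            raise ValueError(f"optimizer must be one of {OPTIMIZERS}")


@dataclass
class TrainHistory:
    """Per-epoch trajectory of one training run."""

    train_loss: list = field(default_factory=list)
    train_acc: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_acc: list = field(default_factory=list)
    lr: list = field(default_factory=list)
    n_steps: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.train_loss) + 1),
                "train_loss": self.train_loss,
                "train_acc": self.train_acc,
                "val_loss": self.val_loss,
                "val_acc": self.val_acc,
                "lr": self.lr,
            }
        )


# -- optimizers -----------------------------------------------------------

class _Optimizer:
    def __init__(self, params, lr):
        self.params = list(params)
        self.lr = float(lr)

    def step(self):
        raise NotImplementedError

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


class SGD(_Optimizer):
    """Plain stochastic gradient descent (no momentum)."""

    def step(self):
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad


class RMSprop(_Optimizer):
    def __init__(self, params, lr, rho=0.9, eps=1e-7):
        super().__init__(params, lr)
        self.rho, self.eps = rho, eps
        self.sq = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, s in zip(self.params, self.sq):
            if p.grad is None:
                continue
            s *= self.rho
            s += (1 - self.rho) * p.grad**2
            p.data -= self.lr * p.grad / (np.sqrt(s) + self.eps)


class Adam(_Optimizer):
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-7):
        super().__init__(params, lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1c = 1 - self.beta1**self.t
        b2c = 1 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.data -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


_OPTIMIZER_CLASSES = {"sgd": SGD, "rmsprop": RMSprop, "adam": Adam}


def make_optimizer(name: str, params, lr: float) -> _Optimizer:
    return _OPTIMIZER_CLASSES[name](params, lr)


# -- plateau schedule -----------------------------------------------------

def plateau_update(state, val_loss, patience: int = 5, factor: float = 0.5):
    """One reduce-on-plateau transition.

    ``state`` is (best_val_loss, epochs_since_improvement, lr).  A strict
    improvement (val_loss < best) resets the counter; once ``patience``
    consecutive non-improving epochs accumulate, the learning rate is
    multiplied by ``factor`` and the counter resets (the best loss is
    kept, so a further full patience window is needed for another cut).
    """
    best, since, lr = state
    if val_loss < best:
        return (val_loss, 0, lr)
    since += 1
    if since >= patience:
        return (best, 0, lr * factor)
    return (best, since, lr)


# -- evaluation helpers ---------------------------------------------------

def _evaluate(model, images: np.ndarray, labels: np.ndarray, batch_size: int):
    """Mean cross-entropy and accuracy in inference mode."""
    losses, correct = [], 0
    with ad.no_grad():
        for s in range(0, len(images), batch_size):
            xb, yb = images[s : s + batch_size], labels[s : s + batch_size]
            logits = model.forward(xb, training=False).data
            p = ad.softmax(logits)
            eps = np.finfo(p.dtype).tiny
            losses.append(-np.log(p[np.arange(len(yb)), yb] + eps).sum())
            correct += int((logits.argmax(axis=1) == yb).sum())
    return float(np.sum(losses) / len(images)), correct / len(images)


def train(model, train_ds: Dataset, val_ds: Dataset, cfg: TrainConfig):
    """Fit ``model`` in place; returns (model, TrainHistory).

    Data order is deterministic given cfg.seed.  Aborts with a
    diagnostic if the loss turns non-finite.
    """
    if len(train_ds) == 0 or len(val_ds) == 0:
        raise ValueError("training and validation datasets must be non-empty")
    x_train = train_ds.stacked()
    y_train = train_ds.labels
    x_val = val_ds.stacked()
    y_val = val_ds.labels

    optimizer = make_optimizer(cfg.optimizer, model.parameters(), cfg.learning_rate)
    state = (np.inf, 0, cfg.learning_rate)
    history = TrainHistory()
    rng = np.random.default_rng(derive_seed(cfg.seed, "batches"))

    for epoch in range(cfg.epochs):
        optimizer.lr = state[2]
        history.lr.append(optimizer.lr)
        order = rng.permutation(len(x_train))
        losses, correct = [], 0
        for s in range(0, len(order), cfg.batch_size):
            sel = order[s : s + cfg.batch_size]
            xb, yb = x_train[sel], y_train[sel]
            model.zero_grad()
            logits = model.forward(xb, training=True)
            loss = ad.softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch + 1}, step {history.n_steps + 1}; "
                    "lower the learning rate or inspect the input data"
                )
            loss.backward()
            optimizer.step()
            history.n_steps += 1
            losses.append(float(loss.data) * len(yb))
            correct += int((logits.data.argmax(axis=1) == yb).sum())
        history.train_loss.append(float(np.sum(losses) / len(x_train)))
        history.train_acc.append(correct / len(x_train))
        vl, va = _evaluate(model, x_val, y_val, cfg.batch_size)
        history.val_loss.append(vl)
        history.val_acc.append(va)
        state = plateau_update(state, vl, cfg.plateau_patience, cfg.plateau_factor)
    return model, history


def optimizer_grid(model_builder, train_ds: Dataset, val_ds: Dataset,
                   optimizers=OPTIMIZERS, learning_rates=GRID_LEARNING_RATES,
                   base_cfg: TrainConfig | None = None):
    """Sweep optimizers x learning rates; returns (table, histories).

    One fresh model per cell (via ``model_builder()``).  The table holds
    the final-five-epoch mean validation accuracy/loss per cell; a
    failing cell is recorded with its error and does not abort the grid.
    """
    if not optimizers or not learning_rates:
        raise ValueError("optimizer grid must be non-empty")
    base = base_cfg or TrainConfig()
    rows, histories = [], {}
    for opt in optimizers:
        for lr in learning_rates:
            cfg = TrainConfig(
                batch_size=base.batch_size, epochs=base.epochs, optimizer=opt,
                learning_rate=lr, plateau_patience=base.plateau_patience,
                plateau_factor=base.plateau_factor, seed=base.seed,
            )
            row = {"optimizer": opt, "learning_rate": lr}
            try:
                _, hist = train(model_builder(), train_ds, val_ds, cfg)
                histories[(opt, lr)] = hist
                k = min(5, len(hist.val_acc))
                row.update(
                    final5_val_acc=float(np.mean(hist.val_acc[-k:])),
                    final5_val_loss=float(np.mean(hist.val_loss[-k:])),
                    error="",
                )
            except Exception as exc:  # noqa: BLE001 — per-cell isolation
                row.update(final5_val_acc=np.nan, final5_val_loss=np.nan, error=str(exc))
            rows.append(row)
    return pd.DataFrame(rows), histories
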