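"""Model containers, RMSProp, and the shared training loop.

The training protocol used by every network in this package: RMSProp on a
class-weighted binary cross-entropy, central-apnea = positive class, with
Matthews-correlation-coefficient (MCC) early stopping on a validation split
and best-weights restoration.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .layers import Dropout, Layer

__all__ = [
    "Sequential",
    "TwoBranchModel",
    "RMSProp",
    "TrainConfig",
    "TrainedModel",
    "train_model",
    "weighted_bce",
    "mcc_score",
]


class Sequential:
    """Ordered stack of layers with explicit forward/backward."""

    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)
        self.frozen = False

    def initialize(self, rng: np.random.Generator) -> None:
        for layer in self.layers:
            layer.initialize(rng)
            if isinstance(layer, Dropout):
                layer.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self) -> list[np.ndarray]:
        if self.frozen:
            return []
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        if self.frozen:
            return []
        return [g for layer in self.layers for g in layer.grads()]

    def state(self) -> list[np.ndarray]:
        return [s for layer in self.layers for s in layer.state()]

    def predict_proba(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        out = [
            self.forward(x[i : i + batch_size], train=False)
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(out, axis=0).ravel()


class TwoBranchModel:
    """Late fusion of two branch stacks into a fully connected head.

    Inputs are pairs ``(x_a, x_b)``; each branch embeds its stream, the
    embeddings are concatenated and mapped to one probability by the head.
    Either branch can be frozen (excluded from the optimizer and gradient
    accumulation) via ``branch_a.frozen`` / ``branch_b.frozen``.
    """

    def __init__(self, branch_a: Sequential, branch_b: Sequential, head: Sequential):
        self.branch_a = branch_a
        self.branch_b = branch_b
        self.head = head
        self.frozen = False

    def initialize(self, rng: np.random.Generator) -> None:
        self.branch_a.initialize(rng)
        self.branch_b.initialize(rng)
        self.head.initialize(rng)

    def forward(self, x, train: bool = False) -> np.ndarray:
        xa, xb = x
        ea = self.branch_a.forward(xa, train=train)
        eb = self.branch_b.forward(xb, train=train)
        self._split = ea.shape[1]
        return self.head.forward(np.concatenate([ea, eb], axis=1), train=train)

    def backward(self, dy: np.ndarray) -> None:
        dcat = self.head.backward(dy)
        da, db = dcat[:, : self._split], dcat[:, self._split :]
        if not self.branch_a.frozen:
            self.branch_a.backward(da)
        if not self.branch_b.frozen:
            self.branch_b.backward(db)

    def params(self) -> list[np.ndarray]:
        return self.branch_a.params() + self.branch_b.params() + self.head.params()

    def grads(self) -> list[np.ndarray]:
        return self.branch_a.grads() + self.branch_b.grads() + self.head.grads()

    def state(self) -> list[np.ndarray]:
        return self.branch_a.state() + self.branch_b.state() + self.head.state()

    def predict_proba(self, x, batch_size: int = 32) -> np.ndarray:
        xa, xb = x
        out = [
            self.forward((xa[i : i + batch_size], xb[i : i + batch_size]), train=False)
            for i in range(0, len(xa), batch_size)
        ]
        return np.concatenate(out, axis=0).ravel()


class RMSProp:
    """RMSProp with the conventional squared-gradient moving average."""

    def __init__(self, lr: float = 0.001, rho: float = 0.9, eps: float = 1e-8):
        self.lr, self.rho, self.eps = float(lr), float(rho), float(eps)
        self._cache: list[np.ndarray] | None = None

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if self._cache is None:
            self._cache = [np.zeros_like(p) for p in params]
        for p, g, c in zip(params, grads, self._cache):
            c *= self.rho
            c += (1.0 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(c) + self.eps)


def weighted_bce(p: np.ndarray, y: np.ndarray, weights: np.ndarray) -> tuple[float, np.ndarray]:
    """Class-weighted binary cross-entropy and its gradient w.r.t. ``p``.

    ``weights`` maps label -> weight; the mean is taken over the batch.
    """
    p = np.clip(p.ravel(), 1e-7, 1.0 - 1e-7)
    y = y.ravel().astype(np.float32)
    w = weights[y.astype(int)]
    n = len(y)
    loss = float(-(w * (y * np.log(p) + (1 - y) * np.log(1 - p))).mean())
    dp = (w * (p - y) / (p * (1 - p))) / n
    return loss, dp.astype(np.float32).reshape(-1, 1)


def mcc_score(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Matthews correlation coefficient of binary labels; 0 when undefined."""
    y_true = np.asarray(y_true).astype(int).ravel()
    y_pred = np.asarray(y_pred).astype(int).ravel()
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


@dataclass
class TrainConfig:
    """Training hyperparameters (defaults follow the study protocol)."""

    learning_rate: float = 0.001
    max_epochs: int = 1000
    batch_size: int = 32
    patience: int = 50
    seed: int = 0
    rho: float = 0.9
    eps: float = 1e-8

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")


@dataclass
class TrainedModel:
    model: object
    config: TrainConfig
    history: dict = field(default_factory=dict)
    best_epoch: int = 0
    class_weights: np.ndarray | None = None


def class_weights_from_labels(y: np.ndarray) -> np.ndarray:
    """Inverse-class-frequency weights normalized to mean 1.

    ``w_c = n / (2 n_c)`` so the rarer class is up-weighted; the weight
    *ratio* equals the inverse frequency ratio.
    """
    y = np.asarray(y).astype(int).ravel()
    n = len(y)
    counts = np.array([np.sum(y == 0), np.sum(y == 1)], dtype=float)
    if (counts == 0).any():
        raise ValueError("both classes must be present to derive class weights")
    return (n / (2.0 * counts)).astype(np.float32)


def _batches(x, idx):
    if isinstance(x, tuple):
        return tuple(xi[idx] for xi in x)
    return x[idx]


def train_model(model, x_train, y_train, x_val, y_val, config: TrainConfig) -> TrainedModel:
    """Shared training loop with MCC early stopping.

    ``x_train``/``x_val`` are arrays ``(N, H, W, T, C)`` or tuples of two
    such arrays for two-branch models.  Labels are {0, 1} with 1 = central
    apnea.  Deterministic given ``config.seed``.
    """
    y_train = np.asarray(y_train).astype(int).ravel()
    y_val = np.asarray(y_val).astype(int).ravel()
    for name, y in (("train", y_train), ("validation", y_val)):
        if len(np.unique(y)) < 2:
            raise ValueError(f"{name} labels contain a single class")
    weights = class_weights_from_labels(y_train)
    rng = np.random.default_rng(config.seed)
    model.initialize(rng)
    opt = RMSProp(lr=config.learning_rate, rho=config.rho, eps=config.eps)

    n = len(y_train)
    history = {"loss": [], "val_mcc": []}
    best_mcc, best_epoch, best_state = -np.inf, -1, None
    since_improve = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = _batches(x_train, idx)
            yb = y_train[idx]
            p = model.forward(xb, train=True)
            loss, dp = weighted_bce(p, yb, weights)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            model.backward(dp)
            opt.step(model.params(), model.grads())
            epoch_loss += loss
            n_batches += 1
        history["loss"].append(epoch_loss / max(n_batches, 1))

        val_p = model.predict_proba(x_val, batch_size=config.batch_size)
        val_mcc = mcc_score(y_val, val_p > 0.5)
        history["val_mcc"].append(val_mcc)
        if val_mcc > best_mcc:
            best_mcc, best_epoch = val_mcc, epoch
            best_state = [s.copy() for s in model.state()]
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= config.patience:
                break

    if best_state is not None:
        for dst, src in zip(model.state(), best_state):
            dst[...] = src
    return TrainedModel(
        model=model,
        config=config,
        history=history,
        best_epoch=best_epoch,
        class_weights=weights,
    )
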