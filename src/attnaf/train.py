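"""Cross-entropy loss, minibatch SGD and the training loop.

Training minimizes the softmax cross-entropy ``-log softmax(o)[y]`` by
minibatch stochastic gradient descent, ``theta <- theta - eta * grad``
(optionally with classical momentum).  Defaults follow the reference
training regime for these networks: learning rate 1e-4, minibatch size 100,
25 epochs.  Momentum defaults to 0.9, the stock setting of the MATLAB-style
'sgdm' solver this regime originates from.  The last short minibatch of an
epoch is used, not dropped.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import RRWindow, ValidationError, windows_to_arrays
from .model_zoo import ModelConfig, TrainedModel, build_model


@dataclass
class TrainConfig:
    """Optimization hyperparameters."""

    learning_rate: float = 1e-4
    batch_size: int = 100
    epochs: int = 25
    momentum: float = 0.9
    seed: int = 0
    shuffle_each_epoch: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")
        if self.epochs < 0:
            raise ValidationError("epochs must be >= 0")
        if not 0 <= self.momentum < 1:
            raise ValidationError("momentum must be in [0, 1)")


@dataclass
class TrainHistory:
    """Per-minibatch and per-epoch loss trace."""

    batch_losses: list[float] = field(default_factory=list)
    epoch_losses: list[float] = field(default_factory=list)
    final_epoch: int = 0

    def to_dict(self) -> dict:
        return {"batch_losses": self.batch_losses, "epoch_losses": self.epoch_losses,
                "final_epoch": self.final_epoch}


def log_softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))


def cross_entropy(o: np.ndarray, y) -> float:
    """``-log softmax(o)[y]``, numerically stable via log-sum-exp.

    ``o`` may be one logit vector with an integer ``y``, or a batch
    ``(N, K)`` with labels ``(N,)`` — the batch mean is returned.
    """
    o = np.asarray(o, dtype=np.float64)
    if not np.all(np.isfinite(o)):
        raise ValidationError("non-finite logits")
    ls = log_softmax(o)
    if o.ndim == 1:
        return float(-ls[int(y)])
    y = np.asarray(y, dtype=np.int64)
    return float(-ls[np.arange(len(y)), y].mean())


def cross_entropy_grad(o: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Gradient of the batch-mean cross-entropy w.r.t. the logits."""
    p = np.exp(log_softmax(o))
    g = p.copy()
    g[np.arange(len(y)), y] -= 1.0
    return g / len(y)


def sgd_update(theta: np.ndarray, grad: np.ndarray, learning_rate: float,
               momentum: float = 0.0, velocity: np.ndarray | None = None
               ) -> tuple[np.ndarray, np.ndarray]:
    """One SGD step, returned as a copy: ``theta' = theta - eta * v`` with
    ``v = momentum * v_prev + grad``.  Returns ``(theta', v)``."""
    theta = np.asarray(theta, dtype=np.float64)
    grad = np.asarray(grad, dtype=np.float64)
    if theta.shape != grad.shape:
        raise ValidationError(f"gradient shape {grad.shape} != parameter shape {theta.shape}")
    if velocity is None:
        velocity = np.zeros_like(theta)
    v = momentum * velocity + grad
    return theta - learning_rate * v, v


class _SGD:
    """In-place momentum SGD over a model's layer parameters."""

    def __init__(self, model: TrainedModel, cfg: TrainConfig):
        self.cfg = cfg
        self.vel: dict[tuple[int, str], np.ndarray] = {}
        self.model = model

    def step(self) -> None:
        for i, layer in enumerate(self.model.layers):
            params, grads = layer.params(), layer.grads()
            for name, p in params.items():
                key = (i, name)
                v = self.vel.get(key)
                if v is None:
                    v = np.zeros_like(p)
                v *= self.cfg.momentum
                v += grads[name]
                p -= self.cfg.learning_rate * v
                self.vel[key] = v


def fit(model: TrainedModel, train_windows: list[RRWindow], cfg: TrainConfig | None = None
        ) -> tuple[TrainedModel, TrainHistory]:
    """Train ``model`` in place by epochs of shuffled minibatch SGD.

    Dropout is active only here; the same seed (and thread count) gives a
    bit-identical result.  Returns the model and its loss history.
    """
    if cfg is None:
        cfg = TrainConfig()
    if not train_windows:
        raise ValidationError("empty training set")
    X, y = windows_to_arrays(train_windows)
    rng = np.random.default_rng(cfg.seed)
    history = TrainHistory()
    optimizer = _SGD(model, cfg)
    n = len(y)
    order = np.arange(n)
    for epoch in range(cfg.epochs):
        if cfg.shuffle_each_epoch or epoch == 0:
            order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = model.forward(X[idx], training=True)
            loss = cross_entropy(logits, y[idx])
            model.backward(cross_entropy_grad(logits, y[idx]))
            optimizer.step()
            history.batch_losses.append(loss)
            epoch_losses.append(loss)
        history.epoch_losses.append(float(np.mean(epoch_losses)))
        history.final_epoch = epoch + 1
    model.history = history
    return model, history


def train_model(model_cfg: ModelConfig, train_windows: list[RRWindow],
                train_cfg: TrainConfig | None = None, seed: int | None = None
                ) -> tuple[TrainedModel, TrainHistory]:
    """Build a fresh network from ``model_cfg`` and fit it."""
    if train_cfg is None:
        train_cfg = TrainConfig()
    if seed is None:
        seed = train_cfg.seed
    model = build_model(model_cfg, seed=seed)
    return fit(model, train_windows, train_cfg)


def kfold_indices(n: int, k: int, seed: int = 0) -> list[np.ndarray]:
    """Seeded partition of ``range(n)`` into ``k`` folds with sizes differing by <= 1."""
    if k < 2:
        raise ValidationError("k must be >= 2")
    if n < k:
        raise ValidationError(f"cannot make {k} folds from {n} samples")
    perm = np.random.default_rng(seed).permutation(n)
    base, extra = divmod(n, k)
    folds, start = [], 0
    for i in range(k):
        size = base + (1 if i < extra else 0)
        folds.append(np.sort(perm[start : start + size]))
        start += size
    return folds


def kfold_cv(model_cfg: ModelConfig, train_cfg: TrainConfig, windows: list[RRWindow],
             k: int = 5, seed: int = 0) -> tuple[list[float], float]:
    """k-fold cross-validation accuracy: each fold serves once as validation.

    Returns the per-fold accuracies and their mean (as fractions in [0, 1]).
    """
    folds = kfold_indices(len(windows), k, seed)
    X, y = windows_to_arrays(windows)
    accs: list[float] = []
    for i, val_idx in enumerate(folds):
        mask = np.zeros(len(windows), dtype=bool)
        mask[val_idx] = True
        train_subset = [w for w, m in zip(windows, mask) if not m]
        fold_cfg = TrainConfig(learning_rate=train_cfg.learning_rate, batch_size=train_cfg.batch_size,
                               epochs=train_cfg.epochs, momentum=train_cfg.momentum,
                               seed=train_cfg.seed + i, shuffle_each_epoch=train_cfg.shuffle_each_epoch)
        model, _ = train_model(model_cfg, train_subset, fold_cfg)
        preds = model.predict(X[mask])
        accs.append(float((preds == y[mask]).mean()))
    return accs, float(np.mean(accs))
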