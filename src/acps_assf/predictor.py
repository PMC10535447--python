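"""Fully connected peptide classifier with dropout-enabled stochastic inference.

The network is a five-layer perceptron over the 400-dimensional descriptor
vector — layer shapes (400, 256), (256, 64), (64, 32), (32, 8), (8, 2) with
ReLU activations — trained with mini-batch SGD on the cross-entropy loss.
Dropout (rate 0.3) is applied after the first and second hidden layers, both
during training and, crucially, at inference time when Monte-Carlo dropout
passes are requested: keeping dropout active and running T stochastic forward
passes turns the point predictor into an approximate posterior sampler, from
which the selection framework derives per-sample confidence (mean probability)
and uncertainty (standard deviation).

Everything here is plain NumPy and fully seeded: two models initialized and
trained with the same seeds on the same data have bit-identical parameters.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_LAYER_WIDTHS = (400, 256, 64, 32, 8, 2)
#: Hidden layers (1-based) followed by dropout.
DROPOUT_AFTER_LAYERS = (1, 2)


@dataclasses.dataclass
class ModelConfig:
    layer_widths: tuple[int, ...] = DEFAULT_LAYER_WIDTHS
    dropout_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.layer_widths) < 2 or self.layer_widths[-1] != 2:
            raise ValueError("network must end in a 2-way output layer")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")


@dataclasses.dataclass
class TrainConfig:
    epochs: int = 50
    batch_size: int = 32
    initial_lr: float = 0.001
    lr_decay: float = 0.5          # multiplier applied every lr_step_epochs
    lr_step_epochs: int = 20
    momentum: float = 0.9          # classical SGD momentum; 0 disables
    standardize: bool = True       # z-scoring fitted on the training data
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be positive")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")


@dataclasses.dataclass
class MLPModel:
    """Parameter state of the classifier (weights, biases, optional z-scaler)."""

    config: ModelConfig
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    trained: bool = False
    feat_mean: np.ndarray | None = None
    feat_std: np.ndarray | None = None

    @property
    def n_parameters(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.weights, self.biases))

    def save(self, path: str | Path) -> None:
        arrays = {f"w{i}": w for i, w in enumerate(self.weights)}
        arrays |= {f"b{i}": b for i, b in enumerate(self.biases)}
        if self.feat_mean is not None:
            arrays["feat_mean"] = self.feat_mean
            arrays["feat_std"] = self.feat_std
        arrays["meta"] = np.array(
            [self.config.dropout_rate, self.config.seed, int(self.trained)]
        )
        arrays["widths"] = np.array(self.config.layer_widths)
        np.savez(Path(path), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "MLPModel":
        data = np.load(Path(path))
        widths = tuple(int(w) for w in data["widths"])
        n_layers = len(widths) - 1
        meta = data["meta"]
        model = cls(
            config=ModelConfig(widths, float(meta[0]), int(meta[1])),
            weights=[data[f"w{i}"] for i in range(n_layers)],
            biases=[data[f"b{i}"] for i in range(n_layers)],
            trained=bool(meta[2]),
        )
        if "feat_mean" in data:
            model.feat_mean = data["feat_mean"]
            model.feat_std = data["feat_std"]
        return model


def init_model(config: ModelConfig) -> MLPModel:
    """Initialize parameters; seeded and deterministic.

    Weights use fan-in-scaled normal draws with the ReLU gain
    (std = sqrt(2 / fan_in), the He scheme); biases start at zero.  The
    network is narrow and five layers deep, so a ReLU-gain initialization is
    needed for gradients to survive to the first layer at small learning
    rates.
    """
    rng = np.random.default_rng(config.seed)
    weights, biases = [], []
    for fan_in, fan_out in zip(config.layer_widths, config.layer_widths[1:]):
        std = np.sqrt(2.0 / fan_in)
        weights.append(rng.normal(0.0, std, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return MLPModel(config=config, weights=weights, biases=biases)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward(
    model: MLPModel,
    X: np.ndarray,
    dropout_rng: np.random.Generator | None,
) -> tuple[np.ndarray, list]:
    """Forward pass; a non-None *dropout_rng* samples fresh inverted-dropout
    masks after the designated hidden layers.  Returns (probs, cache)."""
    p = model.config.dropout_rate
    n_layers = len(model.weights)
    a = X
    cache = [(a, None)]
    for i, (w, b) in enumerate(zip(model.weights, model.biases), start=1):
        z = a @ w + b
        if i == n_layers:
            return _softmax(z), cache
        a = np.maximum(z, 0.0)
        mask = None
        if i in DROPOUT_AFTER_LAYERS and dropout_rng is not None and p > 0.0:
            mask = (dropout_rng.random(a.shape) >= p) / (1.0 - p)
            a = a * mask
        cache.append((a, mask))
    raise AssertionError("unreachable")


def _apply_scaler(model: MLPModel, X: np.ndarray) -> np.ndarray:
    if model.feat_mean is None:
        return X
    return (X - model.feat_mean) / model.feat_std


def train_model(
    model: MLPModel,
    X: np.ndarray,
    y: np.ndarray,
    tcfg: TrainConfig,
) -> MLPModel:
    """Train in place with mini-batch SGD on cross-entropy; returns the model.

    Dropout is active during training; data are reshuffled every epoch with
    the config seed; the learning rate steps down by ``lr_decay`` every
    ``lr_step_epochs`` epochs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[1] != model.config.layer_widths[0]:
        raise ValueError(
            f"input width {X.shape[-1]} != model input {model.config.layer_widths[0]}"
        )
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    if tcfg.standardize:
        model.feat_mean = X.mean(axis=0)
        std = X.std(axis=0)
        model.feat_std = np.where(std > 0, std, 1.0)
    X = _apply_scaler(model, X)

    rng = np.random.default_rng(tcfg.seed)
    n = len(X)
    onehot = np.eye(2)[y]
    vel_w = [np.zeros_like(w) for w in model.weights]
    vel_b = [np.zeros_like(b) for b in model.biases]
    for epoch in range(tcfg.epochs):
        lr = tcfg.initial_lr * tcfg.lr_decay ** (epoch // tcfg.lr_step_epochs)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, tcfg.batch_size):
            idx = order[start : start + tcfg.batch_size]
            xb, yb = X[idx], onehot[idx]
            probs, cache = _forward(model, xb, dropout_rng=rng)
            epoch_loss += -np.sum(
                yb * np.log(np.clip(probs, 1e-12, None))
            )
            # backprop
            grad_z = (probs - yb) / len(idx)
            for i in range(len(model.weights) - 1, -1, -1):
                a_prev, _ = cache[i]
                gw = a_prev.T @ grad_z
                gb = grad_z.sum(axis=0)
                if i > 0:
                    a_i, mask_i = cache[i]
                    grad_a = grad_z @ model.weights[i].T
                    if mask_i is not None:
                        grad_a = grad_a * mask_i
                    grad_z = grad_a * (a_i > 0)
                vel_w[i] = tcfg.momentum * vel_w[i] + gw
                vel_b[i] = tcfg.momentum * vel_b[i] + gb
                model.weights[i] -= lr * vel_w[i]
                model.biases[i] -= lr * vel_b[i]
        logger.debug(
            "epoch %d loss %.6f lr %.6g", epoch + 1, epoch_loss / n, lr
        )
    model.trained = True
    return model


def predict_proba(
    model: MLPModel,
    X: np.ndarray,
    dropout_active: bool = False,
    seed: int | None = None,
) -> np.ndarray:
    """Class-probability pairs for each row of X.

    With ``dropout_active=False`` the map is deterministic; with
    ``dropout_active=True`` a fresh dropout mask is sampled (seeded if *seed*
    is given), which is one stochastic forward pass of MC dropout.
    """
    if not model.trained:
        raise RuntimeError("model is not trained")
    X = _apply_scaler(model, np.asarray(X, dtype=float))
    if X.shape[1] != model.config.layer_widths[0]:
        raise ValueError("input width mismatch")
    rng = np.random.default_rng(seed) if dropout_active else None
    probs, _ = _forward(model, X, dropout_rng=rng)
    return probs


def mc_dropout_passes(
    model: MLPModel,
    X: np.ndarray,
    T: int,
    seed: int = 0,
) -> np.ndarray:
    """Run T stochastic forward passes with dropout kept on.

    Returns an (n_samples, T, 2) array whose [j, t] row is the softmax output
    of pass t for sample j; each pass uses an independent dropout mask.
    Deterministic given *seed*.
    """
    if T < 2:
        raise ValueError("T must be >= 2 (sample std needs T-1 >= 1)")
    if not model.trained:
        raise RuntimeError("model is not trained")
    X = _apply_scaler(model, np.asarray(X, dtype=float))
    rng = np.random.default_rng(seed)
    out = np.empty((len(X), T, 2))
    for t in range(T):
        probs, _ = _forward(model, X, dropout_rng=rng)
        out[:, t, :] = probs
    return out
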