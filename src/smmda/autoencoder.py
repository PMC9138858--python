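"""Bottleneck autoencoder compressing pair features to a 64-d code.

A symmetric fully-connected network with seven hidden layers
(512, 256, 128, 64, 128, 256, 512 by default), rectifier activations and
a linear reconstruction output, trained to minimize mean squared
reconstruction error.  The output of the middle (narrowest) layer is the
compressed feature handed to the classifier; because the bottleneck is
rectified, codes are non-negative.

Weights are untied (encoder W and decoder W′ are independent) and
optimized with Adam on shuffled minibatches.  Training is fully
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, DataValidationError, EmptyInputError

__all__ = ["AEConfig", "AEModel", "train_autoencoder", "encode", "reconstruct"]

DEFAULT_WIDTHS = (512, 256, 128, 64, 128, 256, 512)


@dataclass(frozen=True)
class AEConfig:
    """Architecture and optimization settings.

    ``layer_widths`` must be palindromic with a single minimum — the
    bottleneck, whose width (default 64) is the code size.  Optimizer
    defaults: Adam, lr 1e-3, 50 epochs, batch 128.
    """

    layer_widths: tuple[int, ...] = DEFAULT_WIDTHS
    activation: str = "relu"
    epochs: int = 50
    batch_size: int = 128
    lr: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        w = self.layer_widths
        if len(w) < 1 or w != tuple(reversed(w)):
            raise ConfigurationError(f"layer widths {w} are not palindromic")
        if w.count(min(w)) != 1:
            raise ConfigurationError(f"layer widths {w} lack a unique bottleneck")
        if self.activation != "relu":
            raise ConfigurationError("only the rectifier activation is supported")
        if self.epochs < 1 or self.batch_size < 1 or self.lr <= 0:
            raise ConfigurationError("epochs/batch_size/lr must be positive")

    @property
    def bottleneck(self) -> int:
        return min(self.layer_widths)

    @property
    def bottleneck_pos(self) -> int:
        return self.layer_widths.index(self.bottleneck)


@dataclass
class AEModel:
    """Trained weights/biases per layer plus the per-epoch loss log."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    config: AEConfig
    training_log: list[float] = field(default_factory=list)
    initial_loss: float = float("nan")

    @property
    def input_width(self) -> int:
        return self.weights[0].shape[0]

    def save(self, path: str | Path) -> None:
        arrays = {f"W{i}": w for i, w in enumerate(self.weights)}
        arrays |= {f"b{i}": b for i, b in enumerate(self.biases)}
        np.savez(
            path,
            training_log=np.array(self.training_log),
            initial_loss=self.initial_loss,
            layer_widths=np.array(self.config.layer_widths),
            epochs=self.config.epochs,
            batch_size=self.config.batch_size,
            lr=self.config.lr,
            seed=self.config.seed,
            **arrays,
        )

    @classmethod
    def load(cls, path: str | Path) -> "AEModel":
        data = np.load(path)
        cfg = AEConfig(
            layer_widths=tuple(int(x) for x in data["layer_widths"]),
            epochs=int(data["epochs"]),
            batch_size=int(data["batch_size"]),
            lr=float(data["lr"]),
            seed=int(data["seed"]),
        )
        n_layers = len(cfg.layer_widths) + 1
        return cls(
            weights=[data[f"W{i}"] for i in range(n_layers)],
            biases=[data[f"b{i}"] for i in range(n_layers)],
            config=cfg,
            training_log=list(data["training_log"]),
            initial_loss=float(data["initial_loss"]),
        )


def fit_architecture(width: int, cfg: AEConfig | None = None) -> AEConfig:
    """Shrink the layer stack (halving every width) until the bottleneck
    is below the feature width, for small cohorts where the default
    architecture would be wider than its input."""
    from dataclasses import replace

    cfg = cfg or AEConfig()
    widths = cfg.layer_widths
    while min(widths) >= max(2, width) and min(widths) > 2:
        widths = tuple(max(2, w // 2) for w in widths)
    return replace(cfg, layer_widths=widths)


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _forward(model_w, model_b, X):
    """Activations after each layer; hidden layers rectified, output linear."""
    acts = [X]
    h = X
    last = len(model_w) - 1
    for i, (W, b) in enumerate(zip(model_w, model_b)):
        z = h @ W + b
        h = z if i == last else _relu(z)
        acts.append(h)
    return acts


def train_autoencoder(X: np.ndarray, cfg: AEConfig | None = None) -> AEModel:
    """Fit the bottleneck autoencoder to feature rows X.

    He-initialized weights, Adam updates on shuffled minibatches, MSE
    loss.  ``training_log[i]`` is the mean minibatch loss of epoch i;
    ``initial_loss`` is the full-data loss before any update.  Identical
    (X, cfg) always yield identical weights.
    """
    cfg = cfg or AEConfig()
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise EmptyInputError("autoencoder needs a non-empty 2-D feature matrix")
    d = X.shape[1]
    if d < cfg.bottleneck:
        raise ConfigurationError(
            f"feature width {d} is below the bottleneck width {cfg.bottleneck}"
        )
    widths = (d, *cfg.layer_widths, d)
    rng = np.random.default_rng(cfg.seed)
    weights = [
        rng.standard_normal((a, b)) * np.sqrt(2.0 / a)
        for a, b in zip(widths[:-1], widths[1:])
    ]
    biases = [np.zeros(b) for b in widths[1:]]

    initial = float(np.mean((_forward(weights, biases, X)[-1] - X) ** 2))

    mw = [np.zeros_like(w) for w in weights]
    vw = [np.zeros_like(w) for w in weights]
    mb = [np.zeros_like(b) for b in biases]
    vb = [np.zeros_like(b) for b in biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    log: list[float] = []
    n = X.shape[0]
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            batch = X[order[start:start + cfg.batch_size]]
            acts = _forward(weights, biases, batch)
            err = acts[-1] - batch
            losses.append(float(np.mean(err**2)))
            # backprop: dL/dz for MSE with linear output
            grad = 2.0 * err / err.size
            t += 1
            grads_w, grads_b = [], []
            for i in range(len(weights) - 1, -1, -1):
                grads_w.append(acts[i].T @ grad)
                grads_b.append(grad.sum(axis=0))
                if i > 0:
                    grad = (grad @ weights[i].T) * (acts[i] > 0)
            grads_w.reverse()
            grads_b.reverse()
            for i in range(len(weights)):
                for g, p, m, v in ((grads_w[i], weights[i], mw[i], vw[i]),
                                   (grads_b[i], biases[i], mb[i], vb[i])):
                    m *= beta1
                    m += (1 - beta1) * g
                    v *= beta2
                    v += (1 - beta2) * g**2
                    mhat = m / (1 - beta1**t)
                    vhat = v / (1 - beta2**t)
                    p -= cfg.lr * mhat / (np.sqrt(vhat) + eps)
        log.append(float(np.mean(losses)))
    return AEModel(weights=weights, biases=biases, config=cfg,
                   training_log=log, initial_loss=initial)


def encode(model: AEModel, X: np.ndarray) -> np.ndarray:
    """Codes from the bottleneck layer; width = bottleneck (default 64),
    entries ≥ 0 because the bottleneck is rectified."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.input_width:
        raise DataValidationError(
            f"input width {X.shape[1]} != model input width {model.input_width}"
        )
    h = X
    for i in range(model.config.bottleneck_pos + 1):
        h = _relu(h @ model.weights[i] + model.biases[i])
    return h


def reconstruct(model: AEModel, X: np.ndarray) -> np.ndarray:
    """Full forward pass (decoder output)."""
    X = np.asarray(X, dtype=np.float64)
    if X.shape[-1] != model.input_width:
        raise DataValidationError("input width mismatch")
    return _forward(model.weights, model.biases, np.atleast_2d(X))[-1]
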