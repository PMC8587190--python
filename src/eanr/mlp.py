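"""Small feed-forward networks with per-layer trainable masks.

Both the noise classifier (logistic hidden units, softmax output,
cross-entropy loss) and the denoising autoencoder (ReLU hidden units, linear
output, mean-squared-error loss) are instances of the same multilayer
perceptron. The distinguishing feature here is the trainable mask: any subset
of weight layers can be frozen during optimization, and frozen parameters are
guaranteed bit-identical before and after training — the contract that makes
single-layer knowledge transfer possible.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.random import default_rng

from .errors import InvalidArgumentError, TrainingDivergedError
from .features import NormStats


def logistic(z: np.ndarray) -> np.ndarray:
    # numerically stable split form
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def softmax(z: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max-subtraction for overflow safety."""
    shifted = z - z.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


_HIDDEN = {"logistic": logistic, "relu": relu}


@dataclass
class MlpModel:
    """Ordered (W, b) layers plus activation spec and input normalization.

    Weight layer l maps width[l-1] -> width[l]; layers are numbered 1..L from
    the input, matching the convention used for layer substitution.
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    hidden_activation: str = "logistic"
    output_activation: str = "softmax"
    norm_stats: NormStats | None = None
    output_stats: NormStats | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.biases) or not self.weights:
            raise InvalidArgumentError("weights and biases must pair up")
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            if w.shape[1] != b.shape[0]:
                raise InvalidArgumentError(f"layer {i + 1}: W/b width mismatch")
            if i and self.weights[i - 1].shape[1] != w.shape[0]:
                raise InvalidArgumentError(f"layer {i + 1}: dimension chain broken")
        if self.hidden_activation not in _HIDDEN:
            raise InvalidArgumentError(f"unknown hidden activation {self.hidden_activation!r}")
        if self.output_activation not in ("softmax", "linear"):
            raise InvalidArgumentError(f"unknown output activation {self.output_activation!r}")

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    @property
    def layer_dims(self) -> tuple[int, ...]:
        return (self.weights[0].shape[0], *(w.shape[1] for w in self.weights))

    def copy(self) -> "MlpModel":
        return MlpModel(
            [w.copy() for w in self.weights],
            [b.copy() for b in self.biases],
            self.hidden_activation,
            self.output_activation,
            self.norm_stats,
            self.output_stats,
            dict(self.meta),
        )

    def checksum(self) -> str:
        h = hashlib.sha256()
        for w, b in zip(self.weights, self.biases):
            h.update(np.ascontiguousarray(w).tobytes())
            h.update(np.ascontiguousarray(b).tobytes())
        return h.hexdigest()

    def forward(self, x: np.ndarray, return_hidden: bool = False):
        """Propagate (n, width0) inputs; optionally return every layer output."""
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        if x.shape[1] != self.weights[0].shape[0]:
            raise InvalidArgumentError(
                f"input width {x.shape[1]} != model width {self.weights[0].shape[0]}"
            )
        act = _HIDDEN[self.hidden_activation]
        h = x
        hidden: list[np.ndarray] = []
        for l in range(self.n_layers):
            z = h @ self.weights[l] + self.biases[l]
            if l < self.n_layers - 1:
                h = act(z)
            elif self.output_activation == "softmax":
                h = softmax(z)
            else:
                h = z
            hidden.append(h)
        return (h, hidden) if return_hidden else h


def count_parameters(model: MlpModel) -> int:
    """Exact number of scalar parameters: sum of W entries plus biases."""
    return int(sum(w.size + b.size for w, b in zip(model.weights, model.biases)))


def glorot_init(layer_sizes: Sequence[int], seed: int) -> tuple[list, list]:
    """Scaled-uniform (Glorot) weights, zero biases; deterministic in seed."""
    if len(layer_sizes) < 2 or any(s <= 0 for s in layer_sizes):
        raise InvalidArgumentError("need >= 2 positive layer sizes")
    rng = default_rng(seed)
    ws, bs = [], []
    for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        ws.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        bs.append(np.zeros(fan_out))
    return ws, bs


def he_init(layer_sizes: Sequence[int], seed: int) -> tuple[list, list]:
    """He-scaled normal weights for ReLU nets, zero biases."""
    if len(layer_sizes) < 2 or any(s <= 0 for s in layer_sizes):
        raise InvalidArgumentError("need >= 2 positive layer sizes")
    rng = default_rng(seed)
    ws, bs = [], []
    for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        ws.append(rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in))
        bs.append(np.zeros(fan_out))
    return ws, bs


@dataclass(frozen=True)
class TrainCfg:
    """Adam settings plus the per-layer trainable mask."""

    lr: float = 1e-3
    epochs: int = 50
    batch_size: int = 128
    seed: int = 0
    trainable_mask: tuple[bool, ...] | None = None  # None = all trainable
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def resolve_mask(self, n_layers: int) -> tuple[bool, ...]:
        if self.trainable_mask is None:
            return (True,) * n_layers
        if len(self.trainable_mask) != n_layers:
            raise InvalidArgumentError("trainable_mask length != number of layers")
        return tuple(bool(m) for m in self.trainable_mask)


def loss_and_grads(
    model: MlpModel, x: np.ndarray, target: np.ndarray, loss: str
) -> tuple[float, list[np.ndarray], list[np.ndarray]]:
    """One forward/backward pass.

    loss='ce': target is one-hot (n, K), output must be softmax; the loss is
    mean cross-entropy per sample. loss='mse': target is (n, width); the loss
    is the per-sample squared error summed over output units, averaged over
    samples (sum of ||x_hat - x||^2 / M).
    """
    x = np.atleast_2d(x)
    target = np.atleast_2d(target)
    n = x.shape[0]
    act = _HIDDEN[model.hidden_activation]

    pre: list[np.ndarray] = []
    post: list[np.ndarray] = [x]
    h = x
    for l in range(model.n_layers):
        z = h @ model.weights[l] + model.biases[l]
        pre.append(z)
        if l < model.n_layers - 1:
            h = act(z)
        elif model.output_activation == "softmax":
            h = softmax(z)
        else:
            h = z
        post.append(h)
    out = post[-1]

    if loss == "ce":
        if model.output_activation != "softmax":
            raise InvalidArgumentError("cross-entropy requires softmax output")
        value = float(-np.sum(target * np.log(np.maximum(out, 1e-300))) / n)
        delta = (out - target) / n
    elif loss == "mse":
        if model.output_activation != "linear":
            raise InvalidArgumentError("mse loss requires linear output")
        diff = out - target
        value = float(np.sum(diff**2) / n)
        delta = 2.0 * diff / n
    else:
        raise InvalidArgumentError(f"unknown loss {loss!r}")

    gw = [np.empty(0)] * model.n_layers
    gb = [np.empty(0)] * model.n_layers
    for l in range(model.n_layers - 1, -1, -1):
        gw[l] = post[l].T @ delta
        gb[l] = delta.sum(axis=0)
        if l > 0:
            delta = delta @ model.weights[l].T
            if model.hidden_activation == "logistic":
                a = post[l]
                delta = delta * a * (1.0 - a)
            else:
                delta = delta * (pre[l - 1] > 0)
    return value, gw, gb


def train_mlp(
    model: MlpModel,
    x: np.ndarray,
    target: np.ndarray,
    cfg: TrainCfg,
    loss: str,
) -> tuple[MlpModel, list[float]]:
    """Mini-batch Adam on a copy of the model; returns (trained, loss history).

    Layers with trainable_mask False are never touched: their parameters (and
    optimizer state) remain bit-identical to the input model. cfg.epochs == 0
    returns an exact copy. Raises TrainingDivergedError on non-finite loss.
    """
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    target = np.atleast_2d(np.asarray(target, dtype=np.float64))
    if x.shape[0] != target.shape[0]:
        raise InvalidArgumentError("inputs and targets are misaligned")
    mask = cfg.resolve_mask(model.n_layers)
    if not any(mask):
        raise InvalidArgumentError("at least one layer must be trainable")
    out = model.copy()
    history: list[float] = []
    if cfg.epochs == 0:
        return out, history

    rng = default_rng(cfg.seed)
    mw = [np.zeros_like(w) for w in out.weights]
    vw = [np.zeros_like(w) for w in out.weights]
    mb = [np.zeros_like(b) for b in out.biases]
    vb = [np.zeros_like(b) for b in out.biases]
    t = 0
    n = x.shape[0]
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            value, gw, gb = loss_and_grads(out, x[idx], target[idx], loss)
            if not np.isfinite(value):
                raise TrainingDivergedError(f"non-finite loss at step {t}")
            epoch_loss += value
            n_batches += 1
            t += 1
            corr1 = 1.0 - cfg.beta1**t
            corr2 = 1.0 - cfg.beta2**t
            for l in range(out.n_layers):
                if not mask[l]:
                    continue
                mw[l] = cfg.beta1 * mw[l] + (1 - cfg.beta1) * gw[l]
                vw[l] = cfg.beta2 * vw[l] + (1 - cfg.beta2) * gw[l] ** 2
                out.weights[l] -= cfg.lr * (mw[l] / corr1) / (
                    np.sqrt(vw[l] / corr2) + cfg.eps
                )
                mb[l] = cfg.beta1 * mb[l] + (1 - cfg.beta1) * gb[l]
                vb[l] = cfg.beta2 * vb[l] + (1 - cfg.beta2) * gb[l] ** 2
                out.biases[l] -= cfg.lr * (mb[l] / corr1) / (
                    np.sqrt(vb[l] / corr2) + cfg.eps
                )
        history.append(epoch_loss / max(n_batches, 1))
    return out, history


def numerical_gradients(
    model: MlpModel, x: np.ndarray, target: np.ndarray, loss: str, eps: float = 1e-6
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Central-difference gradients; the independent check on backprop."""
    gw = []
    gb = []
    for l in range(model.n_layers):
        g = np.zeros_like(model.weights[l])
        it = np.nditer(g, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            orig = model.weights[l][i]
            model.weights[l][i] = orig + eps
            up, _, _ = loss_and_grads(model, x, target, loss)
            model.weights[l][i] = orig - eps
            dn, _, _ = loss_and_grads(model, x, target, loss)
            model.weights[l][i] = orig
            g[i] = (up - dn) / (2 * eps)
        gw.append(g)
        g = np.zeros_like(model.biases[l])
        for j in range(g.size):
            orig = model.biases[l][j]
            model.biases[l][j] = orig + eps
            up, _, _ = loss_and_grads(model, x, target, loss)
            model.biases[l][j] = orig - eps
            dn, _, _ = loss_and_grads(model, x, target, loss)
            model.biases[l][j] = orig
            g[j] = (up - dn) / (2 * eps)
        gb.append(g)
    return gw, gb
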