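"""Compact feed-forward network for day-level peak classification.

A fully connected net with per-layer activations drawn from
{linear, selu, tanh, softmax}, a sigmoid output unit, binary cross-entropy
loss, minibatch training with sgd / adam / rmsprop, and early stopping on
validation loss (patience and min_delta configurable).  Weights are Glorot-
initialised from a seeded generator, so training is reproducible.

Kept deliberately small: dense layers only, CPU, float64 — the feature
windows here are a few hundred columns wide and the training sets a few
thousand rows, where this is entirely adequate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LayerSpec", "FeedForwardNet", "TrainingResult"]

_SELU_LAMBDA = 1.0507009873554805
_SELU_ALPHA = 1.6732632423543772

ACTIVATIONS = ("linear", "selu", "tanh", "softmax")


def _forward_activation(name: str, z: np.ndarray) -> np.ndarray:
    if name == "linear":
        return z
    if name == "tanh":
        return np.tanh(z)
    if name == "selu":
        return _SELU_LAMBDA * np.where(z > 0, z, _SELU_ALPHA * (np.exp(np.minimum(z, 0.0)) - 1.0))
    if name == "softmax":
        e = np.exp(z - z.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)
    raise ValueError(f"unknown activation {name!r}")


def _backward_activation(name: str, a: np.ndarray, z: np.ndarray, grad: np.ndarray) -> np.ndarray:
    """Gradient wrt z given gradient wrt the activation output a."""
    if name == "linear":
        return grad
    if name == "tanh":
        return grad * (1.0 - a * a)
    if name == "selu":
        deriv = np.where(z > 0, _SELU_LAMBDA, _SELU_LAMBDA * _SELU_ALPHA * np.exp(np.minimum(z, 0.0)))
        return grad * deriv
    if name == "softmax":
        # J^T g = a * (g - <g, a>)
        dot = (grad * a).sum(axis=1, keepdims=True)
        return a * (grad - dot)
    raise ValueError(f"unknown activation {name!r}")


@dataclass(frozen=True)
class LayerSpec:
    units: int
    activation: str

    def __post_init__(self) -> None:
        if self.units < 1:
            raise ValueError("layer units must be >= 1")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"activation must be one of {ACTIVATIONS}")


@dataclass
class TrainingResult:
    epochs_run: int
    best_epoch: int
    best_val_loss: float
    history: list[tuple[float, float]] = field(repr=False)  # (train_loss, val_loss)


class FeedForwardNet:
    """Dense net: input -> hidden layers (LayerSpec...) -> 1 sigmoid unit."""

    def __init__(self, n_inputs: int, layers: list[LayerSpec], seed: int = 0):
        if n_inputs < 1:
            raise ValueError("n_inputs must be >= 1")
        self.n_inputs = n_inputs
        self.layers = list(layers)
        self.seed = seed
        rng = np.random.default_rng(seed)
        sizes = [n_inputs] + [l.units for l in layers] + [1]
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes, sizes[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            self.W.append(rng.uniform(-limit, limit, (fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))

    # -- inference ---------------------------------------------------------
    def _forward(self, X: np.ndarray) -> tuple[list[np.ndarray], list[np.ndarray]]:
        acts = [X]
        zs = []
        a = X
        for i, spec in enumerate(self.layers):
            z = a @ self.W[i] + self.b[i]
            a = _forward_activation(spec.activation, z)
            zs.append(z)
            acts.append(a)
        z_out = a @ self.W[-1] + self.b[-1]
        zs.append(z_out)
        acts.append(1.0 / (1.0 + np.exp(-z_out)))
        return acts, zs

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Per-row probability in [0, 1] that the anchor day is a flight peak."""
        acts, _ = self._forward(np.asarray(X, float))
        return acts[-1].ravel()

    @staticmethod
    def _bce(p: np.ndarray, y: np.ndarray) -> float:
        p = np.clip(p, 1e-12, 1.0 - 1e-12)
        return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))

    # -- training ----------------------------------------------------------
    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray,
        y_val: np.ndarray,
        learning_rate: float = 1e-2,
        optimizer: str = "adam",
        max_epochs: int = 1000,
        batch_size: int = 256,
        patience: int = 17,
        min_delta: float = 0.17,
        seed: int = 0,
    ) -> TrainingResult:
        """Minibatch training with early stopping on validation loss.

        An epoch only resets the patience counter when validation loss
        improves on the best seen by more than ``min_delta``; the weights of
        the best epoch are restored at the end.  Raises FloatingPointError
        when the training loss goes non-finite (the caller treats that as a
        failed trial).
        """
        if optimizer not in ("sgd", "adam", "rmsprop"):
            raise ValueError(f"unknown optimizer {optimizer!r}")
        X = np.asarray(X, float)
        y = np.asarray(y, float).ravel()
        X_val = np.asarray(X_val, float)
        y_val = np.asarray(y_val, float).ravel()
        rng = np.random.default_rng(seed)

        m = [np.zeros_like(w) for w in self.W] + [np.zeros_like(b) for b in self.b]
        v = [np.zeros_like(w) for w in self.W] + [np.zeros_like(b) for b in self.b]
        t = 0
        beta1, beta2, rho, eps = 0.9, 0.999, 0.9, 1e-8

        best_val = np.inf
        best_weights = ([w.copy() for w in self.W], [b.copy() for b in self.b])
        best_epoch = 0
        waited = 0
        history: list[tuple[float, float]] = []

        n = X.shape[0]
        for epoch in range(1, max_epochs + 1):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                Xb, yb = X[idx], y[idx]
                acts, zs = self._forward(Xb)
                p = acts[-1].ravel()
                epoch_loss += self._bce(p, yb) * len(idx)

                grads_W = [None] * len(self.W)
                grads_b = [None] * len(self.b)
                delta = ((p - yb) / len(idx)).reshape(-1, 1)  # dL/dz_out
                grads_W[-1] = acts[-2].T @ delta
                grads_b[-1] = delta.sum(axis=0)
                grad_a = delta @ self.W[-1].T
                for i in range(len(self.layers) - 1, -1, -1):
                    delta_i = _backward_activation(
                        self.layers[i].activation, acts[i + 1], zs[i], grad_a
                    )
                    grads_W[i] = acts[i].T @ delta_i
                    grads_b[i] = delta_i.sum(axis=0)
                    if i > 0:
                        grad_a = delta_i @ self.W[i].T

                t += 1
                params = self.W + self.b
                grads = grads_W + grads_b
                for k, (param, grad) in enumerate(zip(params, grads)):
                    if optimizer == "sgd":
                        param -= learning_rate * grad
                    elif optimizer == "rmsprop":
                        v[k] = rho * v[k] + (1 - rho) * grad * grad
                        param -= learning_rate * grad / (np.sqrt(v[k]) + eps)
                    else:  # adam
                        m[k] = beta1 * m[k] + (1 - beta1) * grad
                        v[k] = beta2 * v[k] + (1 - beta2) * grad * grad
                        m_hat = m[k] / (1 - beta1**t)
                        v_hat = v[k] / (1 - beta2**t)
                        param -= learning_rate * m_hat / (np.sqrt(v_hat) + eps)

            train_loss = epoch_loss / n
            if not np.isfinite(train_loss):
                raise FloatingPointError(f"training loss non-finite at epoch {epoch}")
            val_loss = self._bce(self.predict_proba(X_val), y_val)
            history.append((train_loss, val_loss))

            if val_loss < best_val - min_delta:
                waited = 0
            else:
                waited += 1
            if val_loss < best_val:
                best_val = val_loss
                best_weights = ([w.copy() for w in self.W], [b.copy() for b in self.b])
                best_epoch = epoch
            if waited >= patience:
                break

        self.W, self.b = best_weights
        return TrainingResult(len(history), best_epoch, float(best_val), history)

    # -- (de)serialisation -------------------------------------------------
    def get_weights(self) -> dict[str, np.ndarray]:
        out = {}
        for i, (w, b) in enumerate(zip(self.W, self.b)):
            out[f"W{i}"] = w
            out[f"b{i}"] = b
        return out

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for i in range(len(self.W)):
            self.W[i] = np.asarray(weights[f"W{i}"], float)
            self.b[i] = np.asarray(weights[f"b{i}"], float)
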