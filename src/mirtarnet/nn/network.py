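"""Network container, binary cross-entropy loss and the Adam optimizer."""

from __future__ import annotations

import copy

import numpy as np

from .layers import Dense, Layer


class NonFiniteLossError(RuntimeError):
    """Raised when training produces a NaN/inf loss (diverged run)."""


class Network:
    """An ordered stack of layers ending in a 1-unit sigmoid Dense head."""

    def __init__(self, layers: list[Layer]):
        if not layers:
            raise ValueError("empty layer list")
        head = layers[-1]
        if not (isinstance(head, Dense) and head.activation == "sigmoid"):
            raise ValueError("final layer must be a sigmoid Dense head")
        self.layers = layers

    # ------------------------------------------------------------------ passes
    def forward(self, x, *, training: bool = False, rng=None) -> np.ndarray:
        out = np.asarray(x)
        for layer in self.layers:
            out = layer.forward(out, training=training, rng=rng)
        return out

    def predict(self, x, batch_size: int = 256) -> np.ndarray:
        """Inference-mode probabilities, shape (N,)."""
        x = np.asarray(x)
        chunks = [
            self.forward(x[i : i + batch_size]).ravel()
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(chunks)

    def backward_from_logit_grad(self, dz: np.ndarray) -> None:
        """Backprop from d(loss)/d(pre-sigmoid logit) of the final head."""
        grad = self.layers[-1].backward(dz, pre_activation=True)
        for layer in reversed(self.layers[:-1]):
            grad = layer.backward(grad)

    def train_batch(self, x, y, rng) -> float:
        """One forward/backward pass; returns the batch BCE loss."""
        self.zero_grads()
        probs = self.forward(x, training=True, rng=rng)
        y = np.asarray(y, dtype=np.float64).reshape(probs.shape)
        loss = bce_loss(probs.ravel(), y.ravel())
        if not np.isfinite(loss):
            raise NonFiniteLossError(f"non-finite training loss: {loss}")
        # combined sigmoid+BCE gradient w.r.t. the head's pre-activation
        self.backward_from_logit_grad((probs - y) / len(y))
        return loss

    # -------------------------------------------------------------- parameters
    def zero_grads(self) -> None:
        for layer in self.layers:
            layer.zero_grads()

    def param_count(self) -> int:
        return sum(layer.param_count() for layer in self.layers)

    def named_params(self):
        for li, layer in enumerate(self.layers):
            for name in layer.params:
                yield f"{li}.{name}", layer, name

    def get_weights(self) -> dict[str, np.ndarray]:
        return {key: layer.params[name].copy()
                for key, layer, name in self.named_params()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for key, layer, name in self.named_params():
            layer.params[name] = weights[key].copy()

    def clone_weights(self) -> dict[str, np.ndarray]:
        return copy.deepcopy(self.get_weights())


def bce_loss(probs: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    p = np.clip(probs, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


class Adam:
    """Adam with optional global gradient-norm clipping."""

    def __init__(
        self,
        lr: float = 0.001,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-7,
        clipnorm: float | None = None,
    ):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.clipnorm = clipnorm
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def step(self, net: Network) -> None:
        self.t += 1
        entries = list(net.named_params())
        if self.clipnorm is not None:
            total = np.sqrt(
                sum(float(np.sum(layer.grads[name] ** 2)) for _, layer, name in entries)
            )
            scale = self.clipnorm / total if total > self.clipnorm else 1.0
        else:
            scale = 1.0
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for key, layer, name in entries:
            g = layer.grads[name] * scale
            m = self._m.setdefault(key, np.zeros_like(g))
            v = self._v.setdefault(key, np.zeros_like(g))
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g * g - v)
            layer.params[name] = layer.params[name] - self.lr * (m / b1c) / (
                np.sqrt(v / b2c) + self.eps
            )
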