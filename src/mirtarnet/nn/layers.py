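"""NumPy layers with explicit forward/backward passes.

Every layer stores its parameters in ``self.params`` and accumulates
gradients into ``self.grads`` during :meth:`backward`.  Shapes follow the
batch-first convention: integer token input is ``(B, L)``, feature maps are
``(B, L, C)``, dense activations are ``(B, U)``.
"""

from __future__ import annotations

import numpy as np


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base class; subclasses fill params/grads and implement the two passes."""

    trainable = True

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, *, training=False, rng=None):  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover
        raise NotImplementedError

    def param_count(self) -> int:
        return sum(p.size for p in self.params.values())

    def zero_grads(self) -> None:
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def output_shape(self, input_shape: tuple) -> tuple:
        raise NotImplementedError


class Embedding(Layer):
    """Token -> dense vector lookup; every vocabulary row (incl. N) is trainable."""

    def __init__(self, vocab_size: int, embed_dim: int, rng: np.random.Generator):
        super().__init__()
        self.vocab_size = vocab_size
        self.embed_dim = embed_dim
        self.params["W"] = rng.uniform(-0.05, 0.05, size=(vocab_size, embed_dim))
        self.zero_grads()

    def forward(self, x, *, training=False, rng=None):
        x = np.asarray(x)
        if x.ndim != 2:
            raise ValueError(f"Embedding expects (B, L) integer input, got {x.shape}")
        self._x = x
        return self.params["W"][x]

    def backward(self, dout):
        dW = np.zeros_like(self.params["W"])
        np.add.at(dW, self._x.reshape(-1), dout.reshape(-1, self.embed_dim))
        self.grads["W"] += dW
        return None  # no gradient w.r.t. integer tokens

    def output_shape(self, input_shape):
        return (*input_shape, self.embed_dim)


class Conv1D(Layer):
    """Valid (no implicit padding) 1-D convolution with ReLU activation.

    ``out[b, m, n] = relu(sum_{i,j} W[i, j, n] * x[b, m+i, j] + bias[n])``.
    """

    def __init__(
        self,
        in_channels: int,
        n_kernels: int,
        kernel_size: int,
        rng: np.random.Generator,
    ):
        super().__init__()
        self.in_channels = in_channels
        self.n_kernels = n_kernels
        self.kernel_size = kernel_size
        fan_in = kernel_size * in_channels
        self.params["W"] = _glorot(rng, fan_in, n_kernels, (fan_in, n_kernels))
        self.params["b"] = np.zeros(n_kernels)
        self.zero_grads()

    def forward(self, x, *, training=False, rng=None):
        B, L, C = x.shape
        k = self.kernel_size
        if C != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {C}")
        if L < k:
            raise ValueError(f"input length {L} shorter than kernel {k}")
        # (B, Lout, C, k) -> (B, Lout, k, C) so the flat axis matches W's layout
        windows = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)
        cols = np.ascontiguousarray(windows.transpose(0, 1, 3, 2)).reshape(
            B, L - k + 1, k * C
        )
        z = cols @ self.params["W"] + self.params["b"]
        self._cols = cols
        self._mask = z > 0
        self._in_len = L
        return np.where(self._mask, z, 0.0)

    def backward(self, dout):
        B, Lout, _ = dout.shape
        k, C = self.kernel_size, self.in_channels
        dz = dout * self._mask
        dz_flat = dz.reshape(-1, self.n_kernels)
        self.grads["W"] += self._cols.reshape(-1, k * C).T @ dz_flat
        self.grads["b"] += dz_flat.sum(axis=0)
        dcols = (dz @ self.params["W"].T).reshape(B, Lout, k, C)
        dx = np.zeros((B, self._in_len, C))
        for i in range(k):
            dx[:, i : i + Lout, :] += dcols[:, :, i, :]
        return dx

    def output_shape(self, input_shape):
        B, L, _ = input_shape
        return (B, L - self.kernel_size + 1, self.n_kernels)


class MaxPool1D(Layer):
    """Max over fixed windows along the sequence axis."""

    trainable = False

    def __init__(self, pool_size: int = 2, stride: int = 2):
        super().__init__()
        if pool_size < 1 or stride < 1:
            raise ValueError("pool_size and stride must be positive")
        self.pool_size = pool_size
        self.stride = stride

    def n_out(self, length: int) -> int:
        return (length - self.pool_size) // self.stride + 1

    def forward(self, x, *, training=False, rng=None):
        B, L, C = x.shape
        n = self.n_out(L)
        if n < 1:
            raise ValueError(f"pool window {self.pool_size} exceeds input length {L}")
        starts = np.arange(n) * self.stride
        windows = x[:, starts[:, None] + np.arange(self.pool_size), :]  # (B,n,p,C)
        self._argmax = windows.argmax(axis=2)
        self._starts = starts
        self._in_shape = x.shape
        return windows.max(axis=2)

    def backward(self, dout):
        B, n, C = dout.shape
        dx = np.zeros(self._in_shape)
        b_idx, n_idx, c_idx = np.ix_(np.arange(B), np.arange(n), np.arange(C))
        l_idx = self._starts[None, :, None] + self._argmax
        np.add.at(dx, (b_idx, l_idx, c_idx), dout)
        return dx

    def output_shape(self, input_shape):
        B, L, C = input_shape
        return (B, self.n_out(L), C)


class _LSTMDirection:
    """One direction of an LSTM; gate order in the fused matrices is i,f,g,o."""

    def __init__(self, in_dim, hidden, rng, activation):
        self.in_dim, self.hidden = in_dim, hidden
        self.activation = activation
        H = hidden
        self.W = _glorot(rng, in_dim, 4 * H, (in_dim, 4 * H))
        self.V = _glorot(rng, H, 4 * H, (H, 4 * H))
        b = np.zeros(4 * H)
        b[H : 2 * H] = 1.0  # forget-gate bias 1: standard stable initialization
        self.b = b

    def _act(self, z):
        return np.maximum(z, 0.0) if self.activation == "relu" else np.tanh(z)

    def _act_grad(self, z, a):
        # derivative w.r.t. pre-activation, using z (relu) or a=act(z) (tanh)
        return (z > 0).astype(float) if self.activation == "relu" else 1.0 - a**2

    def forward(self, x):
        B, T, _ = x.shape
        H = self.hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        self._cache = []
        for t in range(T):
            xt = x[:, t, :]
            z = xt @ self.W + h @ self.V + self.b
            i = sigmoid(z[:, :H])
            f = sigmoid(z[:, H : 2 * H])
            zg = z[:, 2 * H : 3 * H]
            o = sigmoid(z[:, 3 * H :])
            g = self._act(zg)
            c_new = f * c + i * g
            ac = self._act(c_new)
            h_new = o * ac
            self._cache.append((xt, h, c, i, f, zg, g, o, c_new, ac))
            h, c = h_new, c_new
        self._T, self._B = T, B
        return h

    def backward(self, dh_final, dW, dV, db):
        H = self.hidden
        T, B = self._T, self._B
        dx = np.zeros((B, T, self.in_dim))
        dh = dh_final
        dc = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            xt, h_prev, c_prev, i, f, zg, g, o, c_new, ac = self._cache[t]
            do = dh * ac
            dc = dc + dh * o * self._act_grad(c_new, ac)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * self._act_grad(zg, g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dW += xt.T @ dz
            dV += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t, :] = dz @ self.W.T
            dh = dz @ self.V.T
            dc = dc * f
        return dx


class BiLSTM(Layer):
    """Bidirectional LSTM returning the concatenated final states (B, 2H).

    ``activation`` replaces tanh in the candidate and cell-output
    nonlinearities ('relu' by default, 'tanh' available as fallback); gate
    activations stay sigmoid.
    """

    def __init__(
        self,
        in_dim: int,
        hidden_units: int,
        rng: np.random.Generator,
        activation: str = "relu",
    ):
        super().__init__()
        if activation not in ("relu", "tanh"):
            raise ValueError(f"unsupported LSTM activation {activation!r}")
        self.in_dim = in_dim
        self.hidden_units = hidden_units
        self.activation = activation
        self.fwd = _LSTMDirection(in_dim, hidden_units, rng, activation)
        self.bwd = _LSTMDirection(in_dim, hidden_units, rng, activation)
        for tag, cell in (("f", self.fwd), ("b", self.bwd)):
            self.params[f"W{tag}"] = cell.W
            self.params[f"V{tag}"] = cell.V
            self.params[f"b{tag}"] = cell.b
        self.zero_grads()

    def _sync(self):
        # params dict is the source of truth (the optimizer rebinds arrays)
        self.fwd.W, self.fwd.V, self.fwd.b = (
            self.params["Wf"], self.params["Vf"], self.params["bf"])
        self.bwd.W, self.bwd.V, self.bwd.b = (
            self.params["Wb"], self.params["Vb"], self.params["bb"])

    def forward(self, x, *, training=False, rng=None):
        self._sync()
        h_f = self.fwd.forward(x)
        h_b = self.bwd.forward(x[:, ::-1, :])
        return np.concatenate([h_f, h_b], axis=1)

    def backward(self, dout):
        H = self.hidden_units
        dx_f = self.fwd.backward(
            dout[:, :H], self.grads["Wf"], self.grads["Vf"], self.grads["bf"]
        )
        dx_b = self.bwd.backward(
            dout[:, H:], self.grads["Wb"], self.grads["Vb"], self.grads["bb"]
        )
        return dx_f + dx_b[:, ::-1, :]

    def output_shape(self, input_shape):
        return (input_shape[0], 2 * self.hidden_units)


class Flatten(Layer):
    trainable = False

    def forward(self, x, *, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)

    def output_shape(self, input_shape):
        B = input_shape[0]
        return (B, int(np.prod(input_shape[1:])))


class Dense(Layer):
    def __init__(
        self,
        in_dim: int,
        units: int,
        rng: np.random.Generator,
        activation: str | None = None,
    ):
        super().__init__()
        if activation not in (None, "relu", "sigmoid"):
            raise ValueError(f"unsupported activation {activation!r}")
        self.in_dim, self.units, self.activation = in_dim, units, activation
        self.params["W"] = _glorot(rng, in_dim, units, (in_dim, units))
        self.params["b"] = np.zeros(units)
        self.zero_grads()

    def forward(self, x, *, training=False, rng=None):
        self._x = x
        z = x @ self.params["W"] + self.params["b"]
        if self.activation == "relu":
            self._mask = z > 0
            return np.where(self._mask, z, 0.0)
        if self.activation == "sigmoid":
            self._out = sigmoid(z)
            return self._out
        return z

    def backward(self, dout, *, pre_activation: bool = False):
        """Backprop; ``pre_activation=True`` means dout is already d(loss)/dz."""
        if pre_activation or self.activation is None:
            dz = dout
        elif self.activation == "relu":
            dz = dout * self._mask
        else:
            dz = dout * self._out * (1.0 - self._out)
        self.grads["W"] += self._x.T @ dz
        self.grads["b"] += dz.sum(axis=0)
        return dz @ self.params["W"].T

    def output_shape(self, input_shape):
        return (input_shape[0], self.units)


class Dropout(Layer):
    """Inverted dropout: active only in training mode, identity at inference."""

    trainable = False

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def forward(self, x, *, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask

    def output_shape(self, input_shape):
        return input_shape
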