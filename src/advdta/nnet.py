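"""Minimal feed-forward neural-network stack on NumPy with explicit backprop.

All model parameters and activations are float32. Every layer caches what it
needs for the backward pass on ``forward`` and accumulates parameter
gradients into ``grads`` on ``backward``; analytic gradients are checked
against central finite differences in the test suite.

Layout conventions: dense layers take ``(batch, n_in)``; 1-D convolutions
take ``(batch, channels, length)`` and use stride 1 with no padding.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    z = np.asarray(z, dtype=np.float64)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Layer:
    """Base class: parameter-free, shape-preserving identity."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0.0


class Dense(Layer):
    """Affine map ``y = x W + b`` with He-style initialisation."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True) -> None:
        super().__init__()
        scale = np.sqrt(1.0 / n_in)
        self.params["W"] = (rng.standard_normal((n_in, n_out)) * scale).astype(DTYPE)
        if bias:
            self.params["b"] = np.zeros(n_out, dtype=DTYPE)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = x @ self.params["W"]
        if "b" in self.params:
            y = y + self.params["b"]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        self.grads["W"] += x.T @ dy
        if "b" in self.params:
            self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(x.dtype)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0).astype(dy.dtype)


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2) -> None:
        super().__init__()
        self.alpha = alpha

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x).astype(x.dtype)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.alpha * dy).astype(dy.dtype)


class PositionSoftmax(Layer):
    """Reshape a flat activation to (positions, symbols) and apply a softmax
    over the symbol axis of every position, so the output rows are per-position
    probability vectors over a vocabulary.
    """

    def __init__(self, n_positions: int, n_symbols: int) -> None:
        super().__init__()
        self.n_positions = n_positions
        self.n_symbols = n_symbols

    def forward(self, x: np.ndarray) -> np.ndarray:
        b = x.shape[0]
        z = x.reshape(b, self.n_positions, self.n_symbols).astype(np.float64)
        z = z - z.max(axis=2, keepdims=True)
        e = np.exp(z)
        self._y = (e / e.sum(axis=2, keepdims=True)).astype(DTYPE)
        return self._y.reshape(b, -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b = dy.shape[0]
        dy3 = dy.reshape(b, self.n_positions, self.n_symbols)
        y = self._y
        dot = (dy3 * y).sum(axis=2, keepdims=True)
        dx = y * (dy3 - dot)
        return dx.reshape(b, -1).astype(DTYPE)


class Conv1D(Layer):
    """1-D cross-correlation, stride 1, no padding.

    Input ``(batch, c_in, L)`` -> output ``(batch, c_out, L - k + 1)``.
    Implemented via im2col + one BLAS matmul per pass.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        scale = np.sqrt(1.0 / (c_in * kernel))
        self.params["W"] = (rng.standard_normal((c_out, c_in, kernel)) * scale).astype(DTYPE)
        self.params["b"] = np.zeros(c_out, dtype=DTYPE)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c_in, L = x.shape
        if c_in != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c_in}")
        if L < self.kernel:
            raise ValueError(f"input length {L} shorter than kernel {self.kernel}")
        t = L - self.kernel + 1
        win = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=2)
        # (b, c_in, t, k) -> (b*t, c_in*k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(b * t, c_in * self.kernel)
        self._cols, self._shape = cols, (b, c_in, L, t)
        Wm = self.params["W"].reshape(self.c_out, -1)
        y = cols @ Wm.T + self.params["b"]
        return y.reshape(b, t, self.c_out).transpose(0, 2, 1).astype(DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c_in, L, t = self._shape
        dym = np.ascontiguousarray(dy.transpose(0, 2, 1)).reshape(b * t, self.c_out)
        Wm = self.params["W"].reshape(self.c_out, -1)
        self.grads["W"] += (dym.T @ self._cols).reshape(self.params["W"].shape)
        self.grads["b"] += dym.sum(axis=0)
        dcols = dym @ Wm  # (b*t, c_in*k)
        dwin = dcols.reshape(b, t, c_in, self.kernel)
        dx = np.zeros((b, c_in, L), dtype=DTYPE)
        for j in range(self.kernel):  # kernel is tiny (4): scatter-add per tap
            dx[:, :, j:j + t] += dwin[:, :, :, j].transpose(0, 2, 1)
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def parameter_layers(self) -> list[Layer]:
        return [l for l in self.layers if l.params]

    def state_dict(self) -> list[dict[str, np.ndarray]]:
        return [{k: v.copy() for k, v in l.params.items()} for l in self.layers]

    def load_state_dict(self, state: list[dict[str, np.ndarray]]) -> None:
        if len(state) != len(self.layers):
            raise ValueError("state does not match architecture")
        for layer, st in zip(self.layers, state):
            if set(st) != set(layer.params):
                raise ValueError("state does not match architecture")
            for k, v in st.items():
                if layer.params[k].shape != v.shape:
                    raise ValueError("state does not match architecture")
                layer.params[k][...] = v


class Adam:
    """Adam optimiser over the parameters of one or more layers."""

    def __init__(self, layers: list[Layer], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.layers = [l for l in layers if l.params]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self._v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for layer, m, v in zip(self.layers, self._m, self._v):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m[k] = self.beta1 * m[k] + (1 - self.beta1) * g
                v[k] = self.beta2 * v[k] + (1 - self.beta2) * g * g
                mh = m[k] / b1t
                vh = v[k] / b2t
                p -= (self.lr * mh / (np.sqrt(vh) + self.eps)).astype(p.dtype)

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on raw logits; returns (loss, dloss/dlogits)."""
    z = np.asarray(logits, dtype=np.float64).ravel()
    t = np.asarray(targets, dtype=np.float64).ravel()
    # softplus(z) - t*z, computed stably
    loss = float(np.mean(np.maximum(z, 0) - t * z + np.log1p(np.exp(-np.abs(z)))))
    grad = ((sigmoid(z) - t) / z.size).astype(DTYPE).reshape(np.shape(logits))
    return loss, grad


def mse_grad(pred: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient w.r.t. predictions."""
    p = np.asarray(pred, dtype=np.float64).ravel()
    t = np.asarray(y, dtype=np.float64).ravel()
    diff = p - t
    loss = float(np.mean(diff ** 2))
    grad = (2.0 * diff / diff.size).astype(DTYPE).reshape(np.shape(pred))
    return loss, grad
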