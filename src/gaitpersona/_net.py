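"""Minimal numpy neural-network core: layers, backprop, seeded SGD.

Implements exactly what the two window classifiers need — dense and 1-D
convolution layers, max pooling, dropout, sigmoid/ReLU activations and
binary cross-entropy on logits — with analytic gradients (checked against
finite differences in the test suite) and a fully seeded mini-batch
gradient-descent loop: init, shuffling and dropout masks all derive from one
``numpy`` generator, so identical data + config give bit-identical models.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "Conv1D",
    "MaxPool1D",
    "Dropout",
    "Flatten",
    "Network",
    "sigmoid",
    "bce_with_logits",
]


def sigmoid(a: np.ndarray) -> np.ndarray:
    # split by sign for overflow safety
    a = np.asarray(a)
    out = np.empty_like(a, dtype=a.dtype if a.dtype.kind == "f" else float)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    ea = np.exp(a[~pos])
    out[~pos] = ea / (1.0 + ea)
    return out


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy of sigmoid(logits) against labels in {0,1}."""
    z, y = np.ravel(logits), np.ravel(y)
    # log(1+e^z) computed stably
    return float(np.mean(np.logaddexp(0.0, z) - y * z))


def _glorot_uniform(rng: np.random.Generator, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Dense:
    """Fully connected layer, optional elementwise activation."""

    def __init__(self, n_in: int, n_out: int, activation: str = "linear"):
        self.n_in, self.n_out = n_in, n_out
        self.activation = activation
        self.W = np.zeros((n_in, n_out))
        self.b = np.zeros(n_out)

    def init(self, rng: np.random.Generator) -> None:
        self.W = _glorot_uniform(rng, (self.n_in, self.n_out), self.n_in, self.n_out)
        self.b = np.zeros(self.n_out)

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool, rng) -> np.ndarray:
        self._x = x
        a = x @ self.W + self.b
        self._a = a
        if self.activation == "relu":
            return np.maximum(a, 0.0)
        if self.activation == "sigmoid":
            self._s = sigmoid(a)
            return self._s
        return a

    def backward(self, dout: np.ndarray):
        if self.activation == "relu":
            da = dout * (self._a > 0)
        elif self.activation == "sigmoid":
            da = dout * self._s * (1.0 - self._s)
        else:
            da = dout
        self.dW = self._x.T @ da
        self.db = da.sum(axis=0)
        return da @ self.W.T

    @property
    def grads(self):
        return [self.dW, self.db]


class Conv1D:
    """Valid (no padding) 1-D convolution over (batch, length, channels)."""

    def __init__(self, kernel: int, n_in: int, n_out: int, activation: str = "relu"):
        self.kernel, self.n_in, self.n_out = kernel, n_in, n_out
        self.activation = activation
        self.W = np.zeros((kernel, n_in, n_out))
        self.b = np.zeros(n_out)

    def init(self, rng: np.random.Generator) -> None:
        fan_in = self.kernel * self.n_in
        fan_out = self.kernel * self.n_out
        self.W = _glorot_uniform(rng, self.W.shape, fan_in, fan_out)
        self.b = np.zeros(self.n_out)

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool, rng) -> np.ndarray:
        # x: (B, L, C_in) -> (B, L-K+1, C_out) via one explicit im2col copy
        view = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=1)
        B, Lp = view.shape[0], view.shape[1]
        cols = np.ascontiguousarray(view.transpose(0, 1, 3, 2)).reshape(
            B * Lp, self.kernel * self.n_in
        )
        self._cols = cols
        a = (cols @ self.W.reshape(-1, self.n_out)).reshape(B, Lp, self.n_out)
        a += self.b
        self._a = a
        self._x_shape = x.shape
        if self.activation == "relu":
            return np.maximum(a, 0.0)
        return a

    def backward(self, dout: np.ndarray):
        da = dout * (self._a > 0) if self.activation == "relu" else dout
        # dW[k, ci, co] = sum_{b,l} x[b, l+k, ci] * da[b, l, co]
        da2 = da.reshape(-1, self.n_out)
        self.dW = (self._cols.T @ da2).reshape(self.W.shape)
        self.db = da.sum(axis=(0, 1))
        # dx is the full convolution of da with the kernel-flipped weights
        B, L, C_in = self._x_shape
        Lp, K = da.shape[1], self.kernel
        pad = K - 1
        da_p = np.zeros((B, Lp + 2 * pad, da.shape[2]), dtype=da.dtype)
        da_p[:, pad : pad + Lp] = da
        cols_b = np.lib.stride_tricks.sliding_window_view(da_p, K, axis=1)
        return np.tensordot(cols_b, self.W[::-1], axes=((3, 2), (0, 2)))

    @property
    def grads(self):
        return [self.dW, self.db]


class MaxPool1D:
    """Max pooling with equal pool size and stride; trailing rest dropped."""

    def __init__(self, size: int = 3):
        self.size = size
        self.params: list = []
        self.grads: list = []

    def init(self, rng) -> None:
        pass

    def forward(self, x: np.ndarray, train: bool, rng) -> np.ndarray:
        B, L, C = x.shape
        n = (L - self.size) // self.size + 1
        blocks = x[:, : n * self.size, :].reshape(B, n, self.size, C)
        self._argmax = blocks.argmax(axis=2)
        self._in_shape = x.shape
        return blocks.max(axis=2)

    def backward(self, dout: np.ndarray):
        B, n, C = dout.shape
        dx = np.zeros(self._in_shape)
        blocks = dx[:, : n * self.size, :].reshape(B, n, self.size, C)
        bi, ni, ci = np.ogrid[:B, :n, :C]
        blocks[bi, ni, self._argmax, ci] = dout
        return dx


class Dropout:
    """Inverted dropout; active only when ``train`` is true."""

    def __init__(self, rate: float):
        self.rate = rate
        self.params: list = []
        self.grads: list = []
        self.frozen_mask: np.ndarray | None = None  # for gradient checks

    def init(self, rng) -> None:
        pass

    def forward(self, x: np.ndarray, train: bool, rng) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if self.frozen_mask is not None:
            mask = self.frozen_mask
        else:
            mask = rng.random(x.shape) >= self.rate
        self._mask = mask / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout: np.ndarray):
        if self._mask is None:
            return dout
        return dout * self._mask


class Flatten:
    def __init__(self):
        self.params: list = []
        self.grads: list = []

    def init(self, rng) -> None:
        pass

    def forward(self, x: np.ndarray, train: bool, rng) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray):
        return dout.reshape(self._shape)


class Network:
    """A layer stack ending in a single logit; sigmoid applied on top.

    The final layer must produce shape (B, 1) logits.  Training minimises
    binary cross-entropy by plain mini-batch gradient descent.
    """

    def __init__(self, layers: list):
        self.layers = layers

    def init(self, rng: np.random.Generator) -> None:
        for layer in self.layers:
            layer.init(rng)

    def astype(self, dtype) -> "Network":
        """Cast all parameters in place (float32 halves training cost)."""
        for layer in self.layers:
            for name in ("W", "b"):
                if hasattr(layer, name):
                    setattr(layer, name, getattr(layer, name).astype(dtype))
        return self

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def set_parameters(self, flats: list[np.ndarray]) -> None:
        it = iter(flats)
        for layer in self.layers:
            for p in layer.params:
                p[...] = next(it)

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def copy_parameters(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    # -- forward / backward -------------------------------------------------
    def forward_logits(
        self, x: np.ndarray, train: bool = False, rng=None, chunk: int = 2048
    ) -> np.ndarray:
        """Logits for a batch; inference is chunked to bound temporaries."""
        if not train and len(x) > chunk:
            return np.concatenate(
                [
                    self.forward_logits(x[lo : lo + chunk], train=False)
                    for lo in range(0, len(x), chunk)
                ]
            )
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x[:, 0]

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return sigmoid(self.forward_logits(x, train=False))

    def backward_from_logits(self, dlogits: np.ndarray) -> np.ndarray:
        dout = dlogits[:, None]
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    # -- training -----------------------------------------------------------
    def fit_sgd(
        self,
        X: np.ndarray,
        y: np.ndarray,
        learning_rate: float,
        epochs: int,
        batch_size: int,
        rng: np.random.Generator,
    ) -> dict[str, np.ndarray]:
        """Seeded mini-batch SGD on BCE; returns per-epoch loss/accuracy."""
        n = len(X)
        losses, accs = [], []
        for _ in range(epochs):
            order = rng.permutation(n)
            ep_loss = ep_correct = 0.0
            for lo in range(0, n, batch_size):
                idx = order[lo : lo + batch_size]
                xb, yb = X[idx], y[idx]
                logits = self.forward_logits(xb, train=True, rng=rng)
                ep_loss += bce_with_logits(logits, yb) * len(idx)
                ep_correct += float(((logits > 0).astype(int) == yb).sum())
                dlogits = (sigmoid(logits) - yb).astype(logits.dtype) / len(idx)
                self.backward_from_logits(dlogits)
                for p, g in zip(self.parameters(), self.gradients()):
                    p -= learning_rate * g
            losses.append(ep_loss / n)
            accs.append(ep_correct / n)
        return {"loss": np.asarray(losses), "accuracy": np.asarray(accs)}
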