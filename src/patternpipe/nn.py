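"""Minimal numpy CNN engine for the small binary image classifiers.

Implements exactly the layer vocabulary the view classifiers need — an
optional factor-4 average-pooling front end, 3x3 same-padding convolutions
each followed by 2x2 max pooling, dropout, flatten, and dense layers —
with softmax cross-entropy loss and Adam.  Convolutions run as im2col +
matmul in float32; everything is seeded and runs on a single CPU.

This is deliberately not a general autodiff framework: layers are composed
in a fixed sequential order and each implements ``forward``/``backward``
explicitly.
"""

from __future__ import annotations

import io
import pickle
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Sequential", "Conv3x3", "MaxPool2", "AvgPool", "Dropout",
           "Flatten", "Dense", "ReLU", "AdamTrainer"]


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3x3(Layer):
    """3x3 convolution, stride 1, same padding, He-initialized."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        fan_in = 9 * c_in
        self.w = (rng.standard_normal((fan_in, c_out)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self.c_in, self.c_out = c_in, c_out

    @staticmethod
    def _im2col(x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        padded = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        win = sliding_window_view(padded, (3, 3), axis=(1, 2))  # n,h,w,c,3,3
        return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(n * h * w, 9 * c)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        self._col = self._im2col(x)
        n, h, w, _ = x.shape
        return (self._col @ self.w + self.b).reshape(n, h, w, self.c_out)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, _ = self._shape
        g = grad.reshape(-1, self.c_out)
        self.grads[0][...] = self._col.T @ g
        self.grads[1][...] = g.sum(axis=0)
        gcol = g @ self.w.T  # n*h*w, 9*c_in
        gcol = gcol.reshape(n, h, w, 3, 3, self.c_in)
        gx = np.zeros((n, h + 2, w + 2, self.c_in), dtype=np.float32)
        for di in range(3):
            for dj in range(3):
                gx[:, di : di + h, dj : dj + w] += gcol[:, :, :, di, dj]
        return gx[:, 1 : 1 + h, 1 : 1 + w]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._pos = x > 0
        return np.where(self._pos, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._pos, grad, 0.0)


class MaxPool2(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        x = x[:, : h2 * 2, : w2 * 2]
        blocks = x.reshape(n, h2, 2, w2, 2, c)
        out = blocks.max(axis=(2, 4))
        self._argmax = blocks == out[:, :, None, :, None, :]
        self._shape = x.shape
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        # split gradient evenly across tied argmax cells (ties are common
        # after ReLU where whole blocks are zero)
        counts = self._argmax.sum(axis=(2, 4), keepdims=True)
        g = self._argmax * (grad[:, :, None, :, None, :] / counts)
        return g.reshape(n, h, w, c).astype(np.float32)


class AvgPool(Layer):
    """Non-overlapping average pooling, used as the resolution-reducing
    front end (factor 4) of the flank classifier."""

    def __init__(self, factor: int = 4):
        super().__init__()
        self.f = factor

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        f = self.f
        n, h, w, c = x.shape
        h2, w2 = h // f, w // f
        self._shape = (n, h2 * f, w2 * f, c)
        return x[:, : h2 * f, : w2 * f].reshape(n, h2, f, w2, f, c).mean(axis=(2, 4))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        f = self.f
        n, h, w, c = self._shape
        g = np.repeat(np.repeat(grad, f, axis=1), f, axis=2) / (f * f)
        return g.astype(np.float32)


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return (x * self._mask).astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return (grad * self._mask).astype(np.float32)


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.w = (rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.w.T


@dataclass
class Sequential:
    layers: list[Layer]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = x.astype(np.float32, copy=False)
        for layer in self.layers:
            out = layer.forward(out, train)
        return out

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def predict_proba(self, x: np.ndarray, batch_size: int = 128) -> np.ndarray:
        outs = []
        for i in range(0, len(x), batch_size):
            logits = self.forward(x[i : i + batch_size], train=False)
            outs.append(_softmax(logits))
        return np.concatenate(outs) if outs else np.zeros((0, 2))

    def n_parameters(self) -> int:
        return sum(p.size for layer in self.layers for p in layer.params)

    def state_bytes(self) -> bytes:
        buf = io.BytesIO()
        pickle.dump([[p.copy() for p in l.params] for l in self.layers], buf)
        return buf.getvalue()

    def load_state_bytes(self, blob: bytes) -> None:
        states = pickle.load(io.BytesIO(blob))
        for layer, params in zip(self.layers, states):
            for p, new in zip(layer.params, params):
                p[...] = new


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class AdamTrainer:
    """Adam with softmax cross-entropy, fixed learning rate, batch shuffling
    seeded per epoch."""

    def __init__(self, model: Sequential, lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._m = [[np.zeros_like(p) for p in l.params] for l in model.layers]
        self._v = [[np.zeros_like(p) for p in l.params] for l in model.layers]
        self._t = 0

    def step_batch(self, xb: np.ndarray, yb: np.ndarray) -> float:
        logits = self.model.forward(xb, train=True)
        probs = _softmax(logits)
        n = len(yb)
        loss = -float(np.mean(np.log(probs[np.arange(n), yb] + 1e-12)))
        grad = probs
        grad[np.arange(n), yb] -= 1.0
        grad /= n
        self.model.backward(grad.astype(np.float32))
        self._t += 1
        b1t = 1 - self.beta1 ** self._t
        b2t = 1 - self.beta2 ** self._t
        for li, layer in enumerate(self.model.layers):
            for pi, p in enumerate(layer.params):
                g = layer.grads[pi]
                m = self._m[li][pi]
                v = self._v[li][pi]
                m *= self.beta1
                m += (1 - self.beta1) * g
                v *= self.beta2
                v += (1 - self.beta2) * g * g
                p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
        return loss

    def fit(self, X: np.ndarray, y: np.ndarray, epochs: int,
            batch_size: int = 32, rng: np.random.Generator | None = None,
            verbose: bool = False) -> list[float]:
        rng = rng or np.random.default_rng(0)
        history = []
        for ep in range(epochs):
            order = rng.permutation(len(X))
            losses = []
            for i in range(0, len(X), batch_size):
                idx = order[i : i + batch_size]
                losses.append(self.step_batch(X[idx], y[idx]))
            history.append(float(np.mean(losses)))
            if verbose:
                print(f"epoch {ep + 1}/{epochs} loss {history[-1]:.4f}")
        return history
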