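"""Minimal neural-network layer kit (numpy, hand-written backprop).

Supports exactly what the package needs: 3×3 same-padding convolutions,
ReLU, 2×2 average pooling, dense layers, softmax cross-entropy and MSE
losses, and Adam.  Everything is deterministic given the initialization
seed and the data order; there is no GPU path and none is needed at the
problem sizes this package trains at.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32  # all parameters and activations


class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv3x3(Layer):
    """3×3 convolution, stride 1, zero padding 1 (shape-preserving)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 input_grad: bool = True):
        scale = np.sqrt(2.0 / (c_in * 9))
        self.w = rng.normal(0.0, scale, size=(c_out, c_in, 3, 3)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.input_grad = input_grad  # first layer skips the (unused) dx pass
        self._xpad: np.ndarray | None = None

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x, train=True):
        # nine shifted GEMMs: avoids materializing the 9× im2col copy
        n, _, h, w = x.shape
        xpad = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        if train:
            self._xpad = xpad
        y = np.empty((n, h, w, self.w.shape[0]), dtype=DTYPE)
        y[...] = self.b
        for p in range(3):
            for q in range(3):
                y += np.tensordot(
                    xpad[:, :, p : p + h, q : q + w], self.w[:, :, p, q],
                    axes=([1], [1]),
                )
        return np.transpose(y, (0, 3, 1, 2))

    def backward(self, dy):
        n, _, h, w = dy.shape
        self.db[...] = dy.sum(axis=(0, 2, 3))
        dxpad = (
            np.zeros_like(self._xpad) if self.input_grad else None
        )
        for p in range(3):
            for q in range(3):
                xs = self._xpad[:, :, p : p + h, q : q + w]
                # dW[o,c,p,q] = sum_{n,i,j} dy[n,o,i,j] * xpad[n,c,i+p,j+q]
                self.dw[:, :, p, q] = np.tensordot(dy, xs, axes=([0, 2, 3], [0, 2, 3]))
                if dxpad is not None:
                    dxpad[:, :, p : p + h, q : q + w] += np.tensordot(
                        dy, self.w[:, :, p, q], axes=([1], [0])
                    ).transpose(0, 3, 1, 2)
        if dxpad is None:
            return dy  # first layer: input gradient never consumed
        return dxpad[:, :, 1:-1, 1:-1]


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class AvgPool2(Layer):
    """2×2 average pooling; spatial dims must be even."""

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        self._shape = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, dy):
        n, c, h, w = self._shape
        up = np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3) / 4.0
        return up


class GlobalAvgPool(Layer):
    """(N, C, H, W) → (N, C); makes the head translation-invariant."""

    def forward(self, x, train=True):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w)


class Flatten(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.dw[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.w.T


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params(), state):
            p[...] = s


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return float(loss), grad / n


def mse_grad(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - target
    loss = float(np.mean(diff**2))
    return loss, 2.0 * diff / diff.size


def small_cnn(input_depth: int, n_classes: int, rng: np.random.Generator,
              input_size: int = 32, width: int = 16,
              head: str = "gap") -> Sequential:
    """Three conv blocks + a classification head; input (N, depth, S, S).

    The default head global-average-pools the last feature map, which makes
    the classifier translation-invariant — neighborhood signals are then
    detected wherever they sit in the context crop rather than memorized by
    position.  ``head='flatten'`` keeps the location-sensitive variant.
    """
    if input_size % 8 != 0:
        raise ValueError("input_size must be divisible by 8")
    final = input_size // 8
    blocks: list[Layer] = [
        Conv3x3(input_depth, width, rng, input_grad=False), ReLU(), AvgPool2(),
        Conv3x3(width, 2 * width, rng), ReLU(), AvgPool2(),
        Conv3x3(2 * width, 2 * width, rng), ReLU(), AvgPool2(),
    ]
    if head == "gap":
        blocks += [GlobalAvgPool(), Dense(2 * width, 64, rng), ReLU(),
                   Dense(64, n_classes, rng)]
    elif head == "flatten":
        blocks += [Flatten(), Dense(final * final * 2 * width, 64, rng), ReLU(),
                   Dense(64, n_classes, rng)]
    else:
        raise ValueError(f"unknown head {head!r}")
    return Sequential(blocks)


def mlp(n_in: int, hidden: tuple[int, ...], n_out: int,
        rng: np.random.Generator) -> Sequential:
    layers: list[Layer] = []
    prev = n_in
    for h in hidden:
        layers += [Dense(prev, h, rng), ReLU()]
        prev = h
    layers.append(Dense(prev, n_out, rng))
    return Sequential(layers)
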