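"""Minimal numpy neural-network backend: layers, a small CNN backbone, heads, SGD.

This is the package's training engine. It implements exactly what the
two-phase trainer needs -- stride-1 same-padding convolutions, ReLU, 2x2 max
pooling, global average pooling and dense layers, all with hand-derived
backward passes -- and keeps two parameter groups (backbone vs. head) so the
trainer can drive them at different learning rates. Everything is float32 and
fully deterministic given the init seed.

The backbone contract is: ``forward`` maps a batch of (B, H, W, 3) images to
a (B, F) feature matrix. Any object with ``layers`` exposing ``params()``,
``forward`` and ``backward`` satisfies it; :class:`SmallCNN` is the default
(a 4-block CNN, a stand-in scale model of the large residual classifiers used
for full-size radiology work).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Conv2d",
    "ReLU",
    "MaxPool2",
    "GlobalAvgPool",
    "Linear",
    "Sequential",
    "SmallCNN",
    "linear_head",
    "projection_head",
    "Model",
    "SGD",
    "softmax",
    "BACKBONES",
]


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Conv2d:
    """3x3 (or kxk) stride-1 convolution with same zero padding, NHWC layout."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (k * k * c_in))  # He init for ReLU nets
        self.k = k
        self.w = Param(rng.standard_normal((k, k, c_in, c_out)) * scale)
        self.b = Param(np.zeros(c_out))
        self._cols = None
        self._in_shape = None

    def params(self):
        return [self.w, self.b]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k = self.k
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = sliding_window_view(xp, (k, k), axis=(1, 2))  # (B, H, W, C, k, k)
        win = win.transpose(0, 1, 2, 4, 5, 3)  # (B, H, W, k, k, C)
        b, h, w = x.shape[:3]
        return np.ascontiguousarray(win).reshape(b * h * w, k * k * x.shape[3])

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b, h, w, c = x.shape
        cols = self._im2col(x)
        out = cols @ self.w.value.reshape(-1, self.w.value.shape[-1]) + self.b.value
        if train:
            self._cols = cols
            self._in_shape = x.shape
        return out.reshape(b, h, w, -1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        b, h, w, c_out = g.shape
        gf = g.reshape(-1, c_out)
        self.w.grad += (self._cols.T @ gf).reshape(self.w.value.shape)
        self.b.grad += gf.sum(axis=0)
        # dx = same-conv of g with the spatially flipped kernel, channels swapped
        w_flip = self.w.value[::-1, ::-1].transpose(0, 1, 3, 2)  # (k, k, c_out, c_in)
        k = self.k
        p = k // 2
        gp = np.pad(g, ((0, 0), (p, p), (p, p), (0, 0)))
        win = sliding_window_view(gp, (k, k), axis=(1, 2)).transpose(0, 1, 2, 4, 5, 3)
        cols = np.ascontiguousarray(win).reshape(b * h * w, k * k * c_out)
        dx = cols @ w_flip.reshape(-1, w_flip.shape[-1])
        return dx.reshape(self._in_shape)


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask


class MaxPool2:
    """2x2 max pooling, stride 2; gradient flows to the argmax of each window."""

    def __init__(self):
        self._idx = None
        self._shape = None

    def params(self):
        return []

    @staticmethod
    def _blocks(x: np.ndarray) -> np.ndarray:
        b, h, w, c = x.shape
        return x.reshape(b, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5).reshape(
            b, h // 2, w // 2, 4, c
        )

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        blocks = self._blocks(x)
        idx = blocks.argmax(axis=3)
        if train:
            self._idx = idx
            self._shape = x.shape
        return np.take_along_axis(blocks, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, g: np.ndarray) -> np.ndarray:
        b, hp, wp, c = g.shape
        blocks = np.zeros((b, hp, wp, 4, c), dtype=g.dtype)
        np.put_along_axis(blocks, self._idx[:, :, :, None, :], g[:, :, :, None, :], axis=3)
        return blocks.reshape(b, hp, wp, 2, 2, c).transpose(0, 1, 3, 2, 4, 5).reshape(self._shape)


class GlobalAvgPool:
    def __init__(self):
        self._shape = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, g: np.ndarray) -> np.ndarray:
        b, h, w, c = self._shape
        return np.broadcast_to(g[:, None, None, :] / (h * w), self._shape).astype(g.dtype)


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = Param(rng.standard_normal((n_in, n_out)) * scale)
        self.b = Param(np.zeros(n_out))
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ g
        self.b.grad += g.sum(axis=0)
        return g @ self.w.value.T


class Sequential:
    def __init__(self, layers: list):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g


class SmallCNN(Sequential):
    """4-block convolutional backbone: (conv-ReLU-pool) x3 then conv-ReLU-GAP.

    Default widths (8, 16, 32, 32) give ~15k parameters -- sized for 32 px
    inputs and one-CPU training runs. The feature dimension is the last width.
    """

    def __init__(self, rng: np.random.Generator, widths: tuple[int, ...] = (8, 16, 32, 32)):
        layers = []
        c_in = 3
        for i, c_out in enumerate(widths):
            layers += [Conv2d(c_in, c_out, 3, rng), ReLU()]
            layers.append(MaxPool2() if i < len(widths) - 1 else GlobalAvgPool())
            c_in = c_out
        super().__init__(layers)
        self.feature_dim = widths[-1]
        self.widths = tuple(widths)


def linear_head(feature_dim: int, n_outputs: int, rng: np.random.Generator) -> Sequential:
    """Single fully connected layer (the pretext-phase classifier)."""
    return Sequential([Linear(feature_dim, n_outputs, rng)])


def projection_head(feature_dim: int, n_outputs: int, rng: np.random.Generator) -> Sequential:
    """Nonlinear projection: dense -> ReLU -> dense (the grading-phase classifier)."""
    return Sequential([Linear(feature_dim, feature_dim, rng), ReLU(), Linear(feature_dim, n_outputs, rng)])


BACKBONES = {"small_cnn": SmallCNN}


class Model:
    """Backbone + head with separate parameter groups."""

    def __init__(self, backbone: Sequential, head: Sequential):
        self.backbone = backbone
        self.head = head

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.head.forward(self.backbone.forward(x, train=train), train=train)

    def backward(self, g: np.ndarray) -> None:
        self.backbone.backward(self.head.backward(g))

    def zero_grad(self) -> None:
        for p in self.backbone.params() + self.head.params():
            p.grad[...] = 0.0

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        outs = []
        for i in range(0, len(x), batch_size):
            outs.append(softmax(self.forward(x[i : i + batch_size], train=False)))
        return np.concatenate(outs, axis=0)

    def backbone_checksum(self) -> float:
        return float(sum(np.abs(p.value).sum() for p in self.backbone.params()))


class SGD:
    """Plain SGD with coupled L2 weight decay and per-group learning rates."""

    def __init__(self, groups: list[list[Param]], weight_decay: float = 0.0):
        self.groups = groups
        self.weight_decay = weight_decay

    def step(self, lrs: list[float]) -> None:
        for params, lr in zip(self.groups, lrs):
            for p in params:
                p.value -= lr * (p.grad + self.weight_decay * p.value)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)
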