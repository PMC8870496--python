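"""A small convolutional network in numpy for the three-label femur classifier.

This is the desk-scale backbone of the training harness: two 3×3
convolution + ReLU + 2×2 max-pool blocks, global average pooling, and a
linear classifier head.  Forward and backward passes are explicit so the
training loop (SGD with the step learning-rate schedule) and Grad-CAM (which
needs the gradient of a class logit with respect to intermediate feature
maps) can be driven directly.

Tensors are ``(N, C, H, W)`` float64.  Convolutions are 'same' (zero pad
k//2), implemented with stride-trick sliding windows + einsum.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base layer: ``forward`` caches what ``backward`` needs; parameterized
    layers expose ``params()`` → list of (weight array, gradient array)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self):
        return []


class Conv2D(Layer):
    def __init__(self, c_in: int, c_out: int, k: int = 3, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        # He initialization for ReLU nets
        std = np.sqrt(2.0 / (c_in * k * k))
        self.W = rng.normal(0.0, std, size=(c_out, c_in, k, k))
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.k = k

    def forward(self, x: np.ndarray) -> np.ndarray:
        # 'same' convolution with edge-replicate padding: zero padding would
        # make the border ring contrast with any non-zero background, creating
        # spurious border responses that pollute class-activation maps
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), mode="edge")
        self._xp_shape = xp.shape
        self._windows = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        return np.einsum("nchwij,ocij->nohw", self._windows, self.W) + self.b[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW += np.einsum("nohw,nchwij->ocij", dy, self._windows)
        self.db += dy.sum(axis=(0, 2, 3))
        N, C, Hp, Wp = self._xp_shape
        Ho, Wo = dy.shape[2], dy.shape[3]
        dxp = np.zeros(self._xp_shape)
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i:i + Ho, j:j + Wo] += np.einsum("nohw,oc->nchw", dy, self.W[:, :, i, j])
        p = self.k // 2
        # fold the replicate-pad gradients back onto the edge pixels they copy
        dxp[:, :, p, :] += dxp[:, :, :p, :].sum(axis=2)
        dxp[:, :, Hp - p - 1, :] += dxp[:, :, Hp - p:, :].sum(axis=2)
        dxp[:, :, :, p] += dxp[:, :, :, :p].sum(axis=3)
        dxp[:, :, :, Wp - p - 1] += dxp[:, :, :, Wp - p:].sum(axis=3)
        return dxp[:, :, p:Hp - p, p:Wp - p]

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2(Layer):
    """2×2 max pooling, stride 2; trailing odd rows/columns are dropped."""

    def forward(self, x):
        N, C, H, W = x.shape
        Ho, Wo = H // 2, W // 2
        self._in_shape = x.shape
        xv = x[:, :, :Ho * 2, :Wo * 2].reshape(N, C, Ho, 2, Wo, 2)
        self._xv = xv
        out = xv.max(axis=(3, 5))
        self._argmask = xv == out[:, :, :, None, :, None]
        return out

    def backward(self, dy):
        N, C, H, W = self._in_shape
        Ho, Wo = H // 2, W // 2
        # ties split the gradient evenly (rare with continuous activations)
        counts = self._argmask.sum(axis=(3, 5), keepdims=True)
        g = self._argmask * (dy[:, :, :, None, :, None] / counts)
        dx = np.zeros(self._in_shape)
        dx[:, :, :Ho * 2, :Wo * 2] = g.reshape(N, C, Ho * 2, Wo * 2)
        return dx


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class GlobalAvgPool(Layer):
    def forward(self, x):
        self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        N, C, H, W = self._in_shape
        return np.broadcast_to(dy[:, :, None, None], self._in_shape) / (H * W)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None,
                 init_scale: float = 1.0):
        rng = rng or np.random.default_rng(0)
        std = init_scale * np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, std, size=(n_out, n_in))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy):
        self.dW += dy.T @ self._x
        self.db += dy.sum(axis=0)
        return dy @ self.W

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, dlogits / n


class TinyCNN:
    """conv(3×3)→ReLU→pool → conv(3×3)→ReLU→pool → flatten → linear.

    The spatial (flatten) head rather than global average pooling lets the
    classifier use lesion position/extent directly, which matters at the
    small training sizes this backbone is meant for.  ``last_conv_index``
    marks the post-activation feature maps of the last convolutional block,
    the default Grad-CAM target.
    """

    name = "tiny"

    def __init__(self, in_channels: int = 1, n_classes: int = 3,
                 widths: tuple[int, int] = (8, 16),
                 input_hw: tuple[int, int] = (50, 30), seed: int = 0):
        rng = np.random.default_rng(seed)
        h, w = input_hw
        n_feat = widths[1] * (h // 4) * (w // 4)
        self.layers: list[Layer] = [
            Conv2D(in_channels, widths[0], 3, rng), ReLU(), MaxPool2(),
            Conv2D(widths[0], widths[1], 3, rng), ReLU(), MaxPool2(),
            # near-zero head so an untrained net predicts ~uniform scores
            Flatten(), Linear(n_feat, n_classes, rng, init_scale=0.01),
        ]
        self.last_conv_index = 4   # ReLU after the second convolution
        self.in_channels = in_channels
        self.n_classes = n_classes
        self.input_hw = (h, w)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x))

    def zero_grad(self) -> None:
        for layer in self.layers:
            for _, g in layer.params():
                g[...] = 0.0

    def backward(self, dlogits: np.ndarray, to_index: int = 0) -> np.ndarray:
        """Backpropagate from the logits down to (and excluding) layer
        ``to_index``; returns the gradient at that layer's output."""
        g = dlogits
        for layer in reversed(self.layers[to_index + 1:]):
            g = layer.backward(g)
        return g

    def parameters(self):
        for layer in self.layers:
            yield from layer.params()

    def activations(self, x: np.ndarray) -> list[np.ndarray]:
        """Forward pass returning every layer's output (caches populated)."""
        outs = []
        for layer in self.layers:
            x = layer.forward(x)
            outs.append(x)
        return outs
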