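"""Minimal CPU tensor layers with explicit forward/backward passes.

A compact NumPy layer library sized for desk-scale training of the
segmentation network: same-padded 3x3 convolution (im2col), 1x1
convolution, 2x2 max pooling, non-overlapping transposed convolution
(kernel = stride), ReLU, inverted dropout, and an Adam optimizer with
per-parameter learning-rate groups and decoupled L2. All tensors are NCHW
float32; every layer stores exactly what its backward pass needs.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer", "Conv2d", "Conv1x1", "MaxPool2", "ReLU", "Dropout",
    "ConvTransposeBlock", "Adam", "he_init",
]


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)).astype(np.float32)


class Layer:
    """Base: parameters in ``params``, matching gradients in ``grads``;
    ``lr_group`` tags transferred layers for the two-rate schedule."""

    lr_group = "new"

    def __init__(self):
        self.params: dict = {}
        self.grads: dict = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*k*k) patch matrix for stride-1 same conv."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # N,C,H,W,k,k
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)


class Conv2d(Layer):
    """Stride-1, same-padded k x k convolution."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        super().__init__()
        if k % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.pad = k // 2
        self.params = {
            "W": he_init(rng, (c_out, c_in, k, k), c_in * k * k),
            "b": np.zeros(c_out, dtype=np.float32),
        }
        self._cols: Optional[np.ndarray] = None
        self._shape = None

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        cols = _im2col(x, self.k, self.pad)
        y = cols @ self.params["W"].reshape(self.c_out, -1).T + self.params["b"]
        self._cols = cols if train else None
        self._shape = x.shape
        return y.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, grad):
        n, _, h, w = self._shape
        g = grad.transpose(0, 2, 3, 1).reshape(n * h * w, self.c_out)
        self.grads["W"] = (g.T @ self._cols).reshape(self.params["W"].shape)
        self.grads["b"] = g.sum(axis=0)
        # dX = "full" correlation of grad with the flipped, transposed kernel
        w_flip = self.params["W"][:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        cols_g = _im2col(grad, self.k, self.pad)
        dx = cols_g @ w_flip.reshape(self.c_in, -1).T
        self._cols = None
        return dx.reshape(n, h, w, self.c_in).transpose(0, 3, 1, 2)


class Conv1x1(Layer):
    """Pointwise convolution (channel mixing); realizes FC layers in the
    fully-convolutional conversion and the skip projections."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 scale: Optional[float] = None):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        W = he_init(rng, (c_out, c_in), c_in)
        if scale is not None:
            W *= scale
        self.params = {"W": W, "b": np.zeros(c_out, dtype=np.float32)}
        self._x = None

    def forward(self, x, train=False):
        self._x = x if train else None
        y = np.einsum("nchw,fc->nfhw", x, self.params["W"], optimize=True)
        return y + self.params["b"][None, :, None, None]

    def backward(self, grad):
        self.grads["W"] = np.einsum("nfhw,nchw->fc", grad, self._x, optimize=True)
        self.grads["b"] = grad.sum(axis=(0, 2, 3))
        self._x = None
        return np.einsum("nfhw,fc->nchw", grad, self.params["W"], optimize=True)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2 (even spatial sizes only)."""

    def __init__(self):
        super().__init__()
        self._argmax = None
        self._shape = None

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2 requires even spatial size, got {h}x{w}")
        blocks = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        blocks = blocks.reshape(n, c, h // 2, w // 2, 4)
        idx = blocks.argmax(axis=-1)
        out = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]
        if train:
            self._argmax, self._shape = idx, x.shape
        return out

    def backward(self, grad):
        n, c, h, w = self._shape
        blocks = np.zeros((n, c, h // 2, w // 2, 4), dtype=grad.dtype)
        np.put_along_axis(blocks, self._argmax[..., None], grad[..., None], axis=-1)
        out = blocks.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._argmax = None
        return out.reshape(n, c, h, w)


class ReLU(Layer):
    def __init__(self):
        super().__init__()
        self._mask = None

    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, grad):
        g = grad * self._mask
        self._mask = None
        return g


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.p <= 0:
            return x
        self._mask = (self.rng.uniform(size=x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        g = grad * self._mask
        self._mask = None
        return g


class ConvTransposeBlock(Layer):
    """Transposed convolution with kernel = stride = ``factor`` (exact,
    non-overlapping upsampling: each input pixel expands to a factor x
    factor block). Initialized to nearest-neighbor interpolation; trainable."""

    def __init__(self, c_in: int, c_out: int, factor: int,
                 rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out, self.factor = c_in, c_out, factor
        W = np.zeros((c_in, c_out, factor, factor), dtype=np.float32)
        for i in range(min(c_in, c_out)):
            W[i, i] = 1.0  # nearest-neighbor start
        W += he_init(rng, W.shape, c_in) * 0.01
        self.params = {"W": W, "b": np.zeros(c_out, dtype=np.float32)}
        self._x = None

    def forward(self, x, train=False):
        self._x = x if train else None
        n, c, h, w = x.shape
        f = self.factor
        y = np.einsum("nchw,cfij->nfhiwj", x, self.params["W"], optimize=True)
        y = y.reshape(n, self.c_out, h * f, w * f)
        return y + self.params["b"][None, :, None, None]

    def backward(self, grad):
        n, _, hf, wf = grad.shape
        f = self.factor
        g = grad.reshape(n, self.c_out, hf // f, f, wf // f, f)
        self.grads["W"] = np.einsum("nfhiwj,nchw->cfij", g, self._x, optimize=True)
        self.grads["b"] = grad.sum(axis=(0, 2, 3))
        dx = np.einsum("nfhiwj,cfij->nchw", g, self.params["W"], optimize=True)
        self._x = None
        return dx


class Adam:
    """Adam with per-layer learning-rate groups and L2 weight decay on
    weight matrices (not biases)."""

    def __init__(self, layers, lr_groups: dict, weight_decay: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.entries = []  # (layer, name, m, v)
        for layer in layers:
            for name, p in layer.params.items():
                self.entries.append(
                    [layer, name, np.zeros_like(p), np.zeros_like(p)]
                )
        self.lr_groups = dict(lr_groups)
        self.scale = 1.0  # plateau-based reduction multiplies this
        self.wd = weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for entry in self.entries:
            layer, name, m, v = entry
            g = layer.grads.get(name)
            if g is None:
                continue
            g = g.astype(np.float32)
            if self.wd > 0 and name == "W":
                g = g + self.wd * layer.params[name]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            lr = self.lr_groups[layer.lr_group] * self.scale
            layer.params[name] -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
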