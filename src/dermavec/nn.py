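"""Minimal float32 neural-network primitives with explicit backprop.

Just enough machinery for the compact style-based GAN: dense layers, 1x1 and
3x3 convolutions (im2col), style-modulated 3x3 convolutions, leaky ReLU,
nearest-neighbour up/average-down sampling, and Adam.  Layers cache their
last forward pass; call ``backward`` immediately after the matching
``forward``.  Gradients are written fresh into ``layer.grads`` on each
backward call.

Weights use the equalized-learning-rate convention: parameters are stored
at unit scale and multiplied by their He constant at run time, so Adam's
per-parameter step is comparable across layers of different fan-in.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


def lrelu(x: np.ndarray, slope: float = 0.2) -> np.ndarray:
    return np.where(x >= 0, x, slope * x)


def lrelu_grad(x: np.ndarray, dy: np.ndarray, slope: float = 0.2) -> np.ndarray:
    return np.where(x >= 0, dy, slope * dy)


def im2col3(x: np.ndarray) -> np.ndarray:
    """(B,C,H,W) -> (B, C*9, H*W) patches for a 3x3 same-padding conv."""
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = np.empty((b, c, 9, h, w), dtype=x.dtype)
    k = 0
    for di in range(3):
        for dj in range(3):
            cols[:, :, k] = xp[:, :, di : di + h, dj : dj + w]
            k += 1
    return cols.reshape(b, c * 9, h * w)

def col2im3(dcols: np.ndarray, shape: tuple) -> np.ndarray:
    """Adjoint of im2col3; scatter-adds patch gradients back to (B,C,H,W)."""
    b, c, h, w = shape
    dxp = np.zeros((b, c, h + 2, w + 2), dtype=dcols.dtype)
    dc = dcols.reshape(b, c, 9, h, w)
    k = 0
    for di in range(3):
        for dj in range(3):
            dxp[:, :, di : di + h, dj : dj + w] += dc[:, :, k]
            k += 1
    return dxp[:, :, 1:-1, 1:-1]


class Layer:
    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, w_scale: float | None = None):
        super().__init__()
        self.c = F32(w_scale if w_scale is not None else np.sqrt(2.0 / n_in))
        self.params = {
            "W": rng.standard_normal((n_out, n_in)).astype(F32),
            "b": np.zeros(n_out, dtype=F32),
        }

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ (self.c * self.params["W"]).T + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads = {"W": self.c * (dy.T @ self._x), "b": dy.sum(axis=0)}
        return dy @ (self.c * self.params["W"])


class Conv1x1(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, w_scale: float | None = None):
        super().__init__()
        self.c = F32(w_scale if w_scale is not None else np.sqrt(2.0 / c_in))
        self.params = {
            "W": rng.standard_normal((c_out, c_in)).astype(F32),
            "b": np.zeros(c_out, dtype=F32),
        }

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        b, c, h, w = x.shape
        y = np.matmul(self.c * self.params["W"], x.reshape(b, c, h * w))
        return y.reshape(b, -1, h, w) + self.params["b"][None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, h, w = self._x.shape
        dyf = dy.reshape(b, -1, h * w)
        xf = self._x.reshape(b, c, h * w)
        self.grads = {
            "W": self.c * np.einsum("bop,bcp->oc", dyf, xf, optimize=True),
            "b": dy.sum(axis=(0, 2, 3)),
        }
        dx = np.matmul((self.c * self.params["W"]).T, dyf)
        return dx.reshape(b, c, h, w)


class Conv3x3(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.c = F32(np.sqrt(2.0 / (c_in * 9)))
        self.params = {
            "W": rng.standard_normal((c_out, c_in * 9)).astype(F32),
            "b": np.zeros(c_out, dtype=F32),
        }

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        self._cols = im2col3(x)
        b, c, h, w = x.shape
        y = np.matmul(self.c * self.params["W"], self._cols)
        return y.reshape(b, -1, h, w) + self.params["b"][None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        dyf = dy.reshape(b, -1, h * w)
        self.grads = {
            "W": self.c * np.einsum("bop,bcp->oc", dyf, self._cols, optimize=True),
            "b": dy.sum(axis=(0, 2, 3)),
        }
        dcols = np.matmul((self.c * self.params["W"]).T, dyf)
        return col2im3(dcols, self._shape)


class ModConv3x3(Layer):
    """3x3 convolution whose input channels are scaled by a per-sample style.

    The style s = affine(w) multiplies each input channel before the spatial
    convolution (weight demodulation omitted in this compact variant).
    """

    def __init__(self, c_in: int, c_out: int, w_dim: int, rng: np.random.Generator):
        super().__init__()
        self.c = F32(np.sqrt(2.0 / (c_in * 9)))
        self.ca = F32(0.05 / np.sqrt(w_dim))  # gentle style modulation at init
        self.params = {
            "W": rng.standard_normal((c_out, c_in * 9)).astype(F32),
            "b": np.zeros(c_out, dtype=F32),
            "A": rng.standard_normal((c_in, w_dim)).astype(F32),
            "a_bias": np.ones(c_in, dtype=F32),
        }

    def forward(self, x: np.ndarray, w: np.ndarray) -> np.ndarray:
        self._x, self._w = x, w
        self._s = w @ (self.ca * self.params["A"]).T + self.params["a_bias"]
        xs = x * self._s[:, :, None, None]
        self._shape = x.shape
        self._cols = im2col3(xs)
        b, c, h, wd = x.shape
        y = np.matmul(self.c * self.params["W"], self._cols)
        return y.reshape(b, -1, h, wd) + self.params["b"][None, :, None, None]

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        b, c, h, wd = self._shape
        dyf = dy.reshape(b, -1, h * wd)
        gW = self.c * np.einsum("bop,bcp->oc", dyf, self._cols, optimize=True)
        gb = dy.sum(axis=(0, 2, 3))
        dxs = col2im3(np.matmul((self.c * self.params["W"]).T, dyf), self._shape)
        dx = dxs * self._s[:, :, None, None]
        ds = np.einsum("bchw,bchw->bc", dxs, self._x, optimize=True)
        self.grads = {
            "W": gW,
            "b": gb,
            "A": self.ca * (ds.T @ self._w),
            "a_bias": ds.sum(axis=0),
        }
        dw = ds @ (self.ca * self.params["A"])
        return dx, dw


def upsample2(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=2).repeat(2, axis=3)


def upsample2_grad(dy: np.ndarray) -> np.ndarray:
    b, c, h, w = dy.shape
    return dy.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def avgpool2(x: np.ndarray) -> np.ndarray:
    b, c, h, w = x.shape
    return x.reshape(b, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


def avgpool2_grad(dy: np.ndarray) -> np.ndarray:
    return dy.repeat(2, axis=2).repeat(2, axis=3) * F32(0.25)


class Adam:
    """Adam over a list of (layer, param-name) slots; ``grads`` may be given
    explicitly as a flat list in slot order."""

    def __init__(self, layers: list[Layer], lr: float, beta1: float = 0.0, beta2: float = 0.99, eps: float = 1e-8):
        self.slots = [(lay, k) for lay in layers for k in lay.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(lay.params[k]) for lay, k in self.slots]
        self.v = [np.zeros_like(lay.params[k]) for lay, k in self.slots]
        self.t = 0

    def step(self, grads: list[np.ndarray] | None = None) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for i, (lay, k) in enumerate(self.slots):
            g = lay.grads[k] if grads is None else grads[i]
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            lay.params[k] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(F32)


def collect_grads(layers: list[Layer]) -> list[np.ndarray]:
    """Snapshot all layer gradients in a flat, stable order."""
    out = []
    for lay in layers:
        for k in lay.params:
            out.append(lay.grads[k].copy())
    return out


def add_grad_lists(a: list[np.ndarray], b: list[np.ndarray], scale_b: float = 1.0) -> list[np.ndarray]:
    return [x + scale_b * y for x, y in zip(a, b)]


def set_grads(layers: list[Layer], flat: list[np.ndarray]) -> None:
    i = 0
    for lay in layers:
        for k in lay.params:
            lay.grads[k] = flat[i]
            i += 1
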