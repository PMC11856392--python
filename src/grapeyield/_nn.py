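"""Minimal CPU neural-network core used by the segmentation and counting models.

Layers operate on float32 arrays in NCHW layout and implement explicit
forward/backward passes; optimisation is plain Adam.  The scope is exactly
what the two small networks in this package need: 1x1 / 3x3 'same'
convolutions, 2x2 max pooling, 2x2-stride-2 transpose convolutions, dense
layers, ReLU, softmax cross-entropy and mean-squared-error losses.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv2d",
    "ConvTranspose2x2",
    "Linear",
    "ReLU",
    "MaxPool2x2",
    "AvgPool2x2",
    "Adam",
    "softmax_cross_entropy",
    "mse_loss",
]


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


def _he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d:
    """k x k 'same' convolution (k in {1, 3}) with bias."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        if k not in (1, 3):
            raise ValueError("kernel size must be 1 or 3")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.w = Param(_he_normal(rng, (c_in * k * k, c_out), c_in * k * k))
        self.b = Param(np.zeros(c_out, dtype=np.float32))
        self._cols: np.ndarray | None = None
        self._shape: tuple | None = None

    def params(self):
        return [self.w, self.b]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if self.k == 1:
            return x.reshape(n, c, h * w)
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        # layout: channel-major then offset, matching weight rows (c_in*k*k)
        cols = np.empty((n, c, 9, h, w), dtype=np.float32)
        k = 0
        for i in range(3):
            for j in range(3):
                cols[:, :, k] = xp[:, :, i : i + h, j : j + w]
                k += 1
        return cols.reshape(n, c * 9, h * w)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        cols = self._im2col(x)
        self._cols, self._shape = cols, x.shape
        y = np.matmul(cols.transpose(0, 2, 1), self.w.value)  # (n, hw, c_out)
        y += self.b.value
        return y.transpose(0, 2, 1).reshape(n, self.c_out, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dy2 = dy.reshape(n, self.c_out, h * w).transpose(0, 2, 1)  # (n, hw, c_out)
        self.w.grad += np.matmul(self._cols, dy2).sum(axis=0)
        self.b.grad += dy2.sum(axis=(0, 1))
        dcols = np.matmul(dy2, self.w.value.T).transpose(0, 2, 1)  # (n, c*k*k, hw)
        self._cols = None
        if self.k == 1:
            return dcols.reshape(n, c, h, w)
        dcols = dcols.reshape(n, c, 9, h, w)
        dxp = np.zeros((n, c, h + 2, w + 2), dtype=np.float32)
        k = 0
        for i in range(3):
            for j in range(3):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, k]
                k += 1
        return dxp[:, :, 1 : 1 + h, 1 : 1 + w]


class ConvTranspose2x2:
    """Transpose convolution, kernel 2x2, stride 2 (exact 2x upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.c_in, self.c_out = c_in, c_out
        self.w = Param(_he_normal(rng, (c_in, c_out * 4), c_in))
        self.b = Param(np.zeros(c_out, dtype=np.float32))
        self._x: np.ndarray | None = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self._x = x
        x2 = x.reshape(n, c, h * w).transpose(0, 2, 1)  # (n, hw, c_in)
        t = np.matmul(x2, self.w.value)  # (n, hw, c_out*4)
        t = t.reshape(n, h, w, self.c_out, 2, 2).transpose(0, 3, 1, 4, 2, 5)
        y = np.ascontiguousarray(t).reshape(n, self.c_out, 2 * h, 2 * w)
        return y + self.b.value[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        n, c, h, w = x.shape
        self.b.grad += dy.sum(axis=(0, 2, 3))
        dt = dy.reshape(n, self.c_out, h, 2, w, 2).transpose(0, 2, 4, 1, 3, 5)
        dt = np.ascontiguousarray(dt).reshape(n, h * w, self.c_out * 4)
        x2 = x.reshape(n, c, h * w)  # (n, c_in, hw)
        self.w.grad += np.matmul(x2, dt).sum(axis=0)
        dx2 = np.matmul(dt, self.w.value.T)  # (n, hw, c_in)
        self._x = None
        return dx2.transpose(0, 2, 1).reshape(n, c, h, w)


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = Param(_he_normal(rng, (n_in, n_out), n_in))
        self.b = Param(np.zeros(n_out, dtype=np.float32))
        self._x: np.ndarray | None = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        self._x = None
        return dy @ self.w.value.T


class ReLU:
    def __init__(self):
        self._mask: np.ndarray | None = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32, copy=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        out = np.where(self._mask, dy, 0.0).astype(np.float32, copy=False)
        self._mask = None
        return out


class MaxPool2x2:
    """2x2 max pooling with stride 2; spatial dims must be even."""

    def __init__(self):
        self._idx: np.ndarray | None = None
        self._shape: tuple | None = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = np.ascontiguousarray(xr).reshape(n, c, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        dxr = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._idx = None
        return np.ascontiguousarray(dxr).reshape(n, c, h, w)


class AvgPool2x2:
    """2x2 average pooling with stride 2; sum-preserving up to a constant,
    which matters for readouts that integrate evidence over the image."""

    def __init__(self):
        self._shape: tuple | None = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self._shape = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dx = np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3) * np.float32(0.25)
        return np.ascontiguousarray(dx[:, :, :h, :w])


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.value -= lr_t * m / (np.sqrt(v) + self.eps)


def softmax_cross_entropy(logits: np.ndarray, target: np.ndarray):
    """Per-pixel two-class cross-entropy.

    logits: (n, n_class, h, w); target: (n, h, w) integer labels.
    Returns (mean loss, gradient wrt logits).
    """
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n, _, h, w = logits.shape
    flat = p.reshape(n, p.shape[1], -1)
    tflat = target.reshape(n, -1)
    picked = np.take_along_axis(flat, tflat[:, None, :], axis=1)[:, 0, :]
    loss = float(-np.log(np.maximum(picked, 1e-12)).mean())
    grad = p.copy()
    np.put_along_axis(
        grad.reshape(n, p.shape[1], -1), tflat[:, None, :],
        picked[:, None, :] - 1.0, axis=1,
    )
    grad /= n * h * w
    return loss, grad.astype(np.float32, copy=False)


def mse_loss(pred: np.ndarray, target: np.ndarray):
    """Mean squared error over every entry; returns (loss, grad wrt pred)."""
    diff = (pred - target).astype(np.float32, copy=False)
    loss = float(np.mean(diff**2))
    return loss, (2.0 / diff.size) * diff
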