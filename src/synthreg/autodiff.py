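"""Minimal reverse-mode automatic differentiation over numpy arrays.

The registration networks in this package (feature detector, hypernetwork,
U-Net velocity-field predictor) are small enough at desk scale that a compact
tape-based engine covers training end to end: dense and convolutional layers,
max pooling, bilinear warping with gradients through both the sampled image
and the sampling coordinates (the spatial-transformer primitive), and the
small-matrix inverse needed by the closed-form weighted-least-squares layer.

All arithmetic is float64 and purely deterministic, which makes seeded
training runs bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor", "as_tensor", "add", "mul", "matmul", "matinv", "relu",
    "leaky_relu", "exp", "concatenate", "conv2d", "maxpool2d",
    "upsample2d_linear", "bilinear_sample", "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """Node in the computation graph; wraps a float64 numpy array."""

    __slots__ = ("value", "grad", "_parents", "_backward")

    def __init__(self, value, parents=(), backward=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    # -- graph traversal ---------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.value)
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        for node in topo:
            node.grad = np.zeros_like(node.value)
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -as_tensor(other))

    def __rsub__(self, other):
        return add(as_tensor(other), -self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return mul(self, _reciprocal(other))

    def __rtruediv__(self, other):
        return mul(as_tensor(other), _reciprocal(self))

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, key):
        src = self

        def back(g):
            tmp = np.zeros_like(src.value)
            np.add.at(tmp, key, g)
            src.grad += tmp

        return Tensor(self.value[key], (self,), back)

    def reshape(self, *shape):
        src = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def back(g):
            src.grad += g.reshape(src.value.shape)

        return Tensor(self.value.reshape(shape), (self,), back)

    def sum(self, axis=None, keepdims=False):
        src = self

        def back(g):
            if axis is None:
                src.grad += np.broadcast_to(g, src.value.shape)
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                src.grad += np.broadcast_to(gg, src.value.shape)

        return Tensor(self.value.sum(axis=axis, keepdims=keepdims), (self,), back)

    def mean(self, axis=None, keepdims=False):
        n = self.value.size if axis is None else np.prod(
            [self.value.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def back(g):
        a.grad += _unbroadcast(g, a.value.shape)
        b.grad += _unbroadcast(g, b.value.shape)

    return Tensor(a.value + b.value, (a, b), back)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def back(g):
        a.grad += _unbroadcast(g * b.value, a.value.shape)
        b.grad += _unbroadcast(g * a.value, b.value.shape)

    return Tensor(a.value * b.value, (a, b), back)


def _reciprocal(a: Tensor) -> Tensor:
    def back(g):
        a.grad += -g / (a.value ** 2)

    return Tensor(1.0 / a.value, (a,), back)


def square(a) -> Tensor:
    a = as_tensor(a)

    def back(g):
        a.grad += 2.0 * a.value * g

    return Tensor(a.value ** 2, (a,), back)


def exp(a) -> Tensor:
    a = as_tensor(a)
    out_val = np.exp(a.value)

    def back(g):
        a.grad += g * out_val

    return Tensor(out_val, (a,), back)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def back(g):
        a.grad += g @ b.value.T
        b.grad += a.value.T @ g

    return Tensor(a.value @ b.value, (a, b), back)


def matinv(a) -> Tensor:
    """Inverse of a small square matrix; d(A^-1) = -A^-1 dA A^-1."""
    a = as_tensor(a)
    inv = np.linalg.inv(a.value)

    def back(g):
        a.grad += -inv.T @ g @ inv.T

    return Tensor(inv, (a,), back)


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.value > 0

    def back(g):
        a.grad += g * mask

    return Tensor(a.value * mask, (a,), back)


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = as_tensor(a)
    mask = a.value > 0
    scale = np.where(mask, 1.0, slope)

    def back(g):
        a.grad += g * scale

    return Tensor(a.value * scale, (a,), back)


def concatenate(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.value.shape[axis] for t in tensors]
    offs = np.cumsum([0] + sizes)

    def back(g):
        for t, lo, hi in zip(tensors, offs[:-1], offs[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t.grad += g[tuple(sl)]

    return Tensor(np.concatenate([t.value for t in tensors], axis=axis),
                  tuple(tensors), back)


# ---------------------------------------------------------------------------
# convolutional primitives (2D, channels-first, stride 1, zero 'same' padding)
# ---------------------------------------------------------------------------

def conv2d(x, w, b=None) -> Tensor:
    """x: (Cin, H, W), w: (Cout, Cin, kh, kw), b: (Cout,). Stride 1, same pad."""
    x, w = as_tensor(x), as_tensor(w)
    b = as_tensor(b) if b is not None else None
    cout, cin, kh, kw = w.value.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.value, ((0, 0), (ph, ph), (pw, pw)))
    win = sliding_window_view(xp, (kh, kw), axis=(1, 2))  # (Cin, H, W, kh, kw)
    out = np.einsum("cijuv,ocuv->oij", win, w.value, optimize=True)
    if b is not None:
        out = out + b.value[:, None, None]

    def back(g):
        w.grad += np.einsum("cijuv,oij->ocuv", win, g, optimize=True)
        if b is not None:
            b.grad += g.sum(axis=(1, 2))
        wf = w.value[:, :, ::-1, ::-1]
        gp = np.pad(g, ((0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1)))
        gwin = sliding_window_view(gp, (kh, kw), axis=(1, 2))
        gxp = np.einsum("oabuv,ocuv->cab", gwin, wf, optimize=True)
        h, wd = x.value.shape[1:]
        x.grad += gxp[:, ph:ph + h, pw:pw + wd]

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out, parents, back)


def maxpool2d(x, k: int = 2) -> Tensor:
    """Non-overlapping k x k max pooling; spatial dims must be divisible by k."""
    x = as_tensor(x)
    c, h, w = x.value.shape
    r = x.value.reshape(c, h // k, k, w // k, k).transpose(0, 1, 3, 2, 4)
    r = r.reshape(c, h // k, w // k, k * k)
    idx = r.argmax(axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def back(g):
        tmp = np.zeros_like(r)
        np.put_along_axis(tmp, idx[..., None], g[..., None], axis=-1)
        tmp = tmp.reshape(c, h // k, w // k, k, k).transpose(0, 1, 3, 2, 4)
        x.grad += tmp.reshape(c, h, w)

    return Tensor(out, (x,), back)


def _resize_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Linear-interpolation matrix for 1D resize with half-pixel alignment."""
    m = np.zeros((n_out, n_in))
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    pos = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    pos = np.clip(pos, 0, n_in - 1)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = pos - lo
    m[np.arange(n_out), lo] += 1 - frac
    m[np.arange(n_out), hi] += frac
    return m


def resize2d_linear(x, out_shape) -> Tensor:
    """Bilinearly resize (C, H, W) to (C, *out_shape) (half-pixel aligned)."""
    x = as_tensor(x)
    c, h, w = x.value.shape
    uh = _resize_matrix(h, out_shape[0])
    uw = _resize_matrix(w, out_shape[1])
    out = np.einsum("ai,cij,bj->cab", uh, x.value, uw, optimize=True)

    def back(g):
        x.grad += np.einsum("ai,cab,bj->cij", uh, g, uw, optimize=True)

    return Tensor(out, (x,), back)


def upsample2d_linear(x, factor: int = 2) -> Tensor:
    """Bilinearly resize (C, H, W) to (C, factor*H, factor*W)."""
    x = as_tensor(x)
    _, h, w = x.value.shape
    return resize2d_linear(x, (factor * h, factor * w))


def bilinear_sample(img, coords, mode: str = "zeros") -> Tensor:
    """Sample (C, H, W) at float (2, Hp, Wp) index coordinates, bilinearly.

    mode='zeros': values outside the grid read as 0 (pull-back fill).
    mode='edge' : coordinates are clamped to the grid (edge replication);
                  used for warp self-composition during SVF integration.
    Gradients flow into both the image and the coordinates.
    """
    img, coords = as_tensor(img), as_tensor(coords)
    c, h, w = img.value.shape
    cy, cx = coords.value[0], coords.value[1]
    if mode == "edge":
        in_y = (cy > 0) & (cy < h - 1)
        in_x = (cx > 0) & (cx < w - 1)
        cy = np.clip(cy, 0.0, h - 1.0)
        cx = np.clip(cx, 0.0, w - 1.0)
    y0 = np.floor(cy).astype(int)
    x0 = np.floor(cx).astype(int)
    y1, x1 = y0 + 1, x0 + 1
    dy, dx = cy - y0, cx - x0

    def corner(yi, xi):
        if mode == "edge":
            yc = np.clip(yi, 0, h - 1)
            xc = np.clip(xi, 0, w - 1)
            return img.value[:, yc, xc], np.ones_like(cy), yc, xc
        valid = (yi >= 0) & (yi < h) & (xi >= 0) & (xi < w)
        yc = np.clip(yi, 0, h - 1)
        xc = np.clip(xi, 0, w - 1)
        return img.value[:, yc, xc] * valid, valid.astype(float), yc, xc

    v00, m00, yc00, xc00 = corner(y0, x0)
    v01, m01, yc01, xc01 = corner(y0, x1)
    v10, m10, yc10, xc10 = corner(y1, x0)
    v11, m11, yc11, xc11 = corner(y1, x1)
    w00 = (1 - dy) * (1 - dx)
    w01 = (1 - dy) * dx
    w10 = dy * (1 - dx)
    w11 = dy * dx
    out = w00 * v00 + w01 * v01 + w10 * v10 + w11 * v11

    def back(g):
        gi = np.zeros_like(img.value)
        for wgt, msk, yc, xc in ((w00, m00, yc00, xc00), (w01, m01, yc01, xc01),
                                 (w10, m10, yc10, xc10), (w11, m11, yc11, xc11)):
            np.add.at(gi, (slice(None), yc, xc), g * (wgt * msk))
        img.grad += gi
        # d out / d cy and d cx
        gy = ((v10 - v00) * (1 - dx) + (v11 - v01) * dx)
        gx = ((v01 - v00) * (1 - dy) + (v11 - v10) * dy)
        gy = (g * gy).sum(axis=0)
        gx = (g * gx).sum(axis=0)
        if mode == "edge":
            gy = gy * in_y
            gx = gx * in_x
        gc = np.zeros_like(coords.value)
        gc[0], gc[1] = gy, gx
        coords.grad += gc

    return Tensor(out, (img, coords), back)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adaptive-moment stochastic gradient descent on a list of leaf Tensors."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def reset_moments(self):
        self.t = 0
        for a in self.m:
            a[...] = 0.0
        for a in self.v:
            a[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
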