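"""Minimal reverse-mode autodiff over numpy arrays.

Only the operations needed by the segmentation networks are implemented:
dense matmul, 2D convolution / transposed convolution, 2x2 max pooling,
pointwise nonlinearities, row softmax, concatenation and reductions.
Every op records a closure that accumulates gradients into its parents;
``Tensor.backward`` runs them in reverse topological order.

Arrays are kept in whatever dtype they are given (training uses float32,
gradient-check tests use float64).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad=False, _parents=(), _backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # -- basic protocol -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self):
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(as_tensor(other), mul(self, -1.0))

    def reshape(self, *shape):
        return reshape(self, shape)


def as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _needs(*tensors):
    return any(t.requires_grad for t in tensors)


def _sum_to_shape(g, shape):
    """Reduce a broadcast gradient back to ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if g.shape[ax] != n:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data + b.data, requires_grad=_needs(a, b), _parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            a._accum(_sum_to_shape(g, a.data.shape))
        if b.requires_grad:
            b._accum(_sum_to_shape(g, b.data.shape))

    out._backward = bwd
    return out


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data * b.data, requires_grad=_needs(a, b), _parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            a._accum(_sum_to_shape(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_sum_to_shape(g * a.data, b.data.shape))

    out._backward = bwd
    return out


def matmul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data @ b.data, requires_grad=_needs(a, b), _parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            a._accum(g @ b.data.T)
        if b.requires_grad:
            b._accum(a.data.T @ g)

    out._backward = bwd
    return out


def reshape(x, shape):
    x = as_tensor(x)
    out = Tensor(x.data.reshape(shape), requires_grad=x.requires_grad, _parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(g.reshape(x.data.shape))

    out._backward = bwd
    return out


def transpose2d(x):
    x = as_tensor(x)
    out = Tensor(x.data.T, requires_grad=x.requires_grad, _parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(g.T)

    out._backward = bwd
    return out


def relu(x):
    x = as_tensor(x)
    out = Tensor(np.maximum(x.data, 0), requires_grad=x.requires_grad, _parents=(x,))
    pos = x.data > 0

    def bwd(g):
        if x.requires_grad:
            x._accum(g * pos)

    out._backward = bwd
    return out


def leaky_relu(x, alpha=0.2):
    x = as_tensor(x)
    out = Tensor(np.where(x.data > 0, x.data, alpha * x.data),
                 requires_grad=x.requires_grad, _parents=(x,))
    slope = np.where(x.data > 0, 1.0, alpha).astype(x.data.dtype)

    def bwd(g):
        if x.requires_grad:
            x._accum(g * slope)

    out._backward = bwd
    return out


def sigmoid(x):
    x = as_tensor(x)
    s = _expit(x.data)
    out = Tensor(s, requires_grad=x.requires_grad, _parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(g * s * (1.0 - s))

    out._backward = bwd
    return out


def log(x):
    x = as_tensor(x)
    out = Tensor(np.log(x.data), requires_grad=x.requires_grad, _parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(g / x.data)

    out._backward = bwd
    return out


def clip(x, lo, hi):
    """Clamp values; gradient passes only through the unclamped region."""
    x = as_tensor(x)
    out = Tensor(np.clip(x.data, lo, hi), requires_grad=x.requires_grad, _parents=(x,))
    inside = (x.data > lo) & (x.data < hi)

    def bwd(g):
        if x.requires_grad:
            x._accum(g * inside)

    out._backward = bwd
    return out


def mean(x):
    x = as_tensor(x)
    out = Tensor(np.asarray(x.data.mean()), requires_grad=x.requires_grad, _parents=(x,))
    n = x.data.size

    def bwd(g):
        if x.requires_grad:
            x._accum(np.full_like(x.data, g / n))

    out._backward = bwd
    return out


def sum_(x):
    x = as_tensor(x)
    out = Tensor(np.asarray(x.data.sum()), requires_grad=x.requires_grad, _parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(np.full_like(x.data, g))

    out._backward = bwd
    return out


def _expit(z):
    """Overflow-safe logistic function."""
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax_rows(x):
    """Row-wise softmax of a 2D tensor (each row sums to 1)."""
    x = as_tensor(x)
    y = x.data - x.data.max(axis=1, keepdims=True)
    np.exp(y, out=y)
    y /= y.sum(axis=1, keepdims=True)
    out = Tensor(y, requires_grad=x.requires_grad, _parents=(x,))

    def bwd(g):
        if x.requires_grad:
            dot = (g * y).sum(axis=1, keepdims=True)
            x._accum(y * (g - dot))

    out._backward = bwd
    return out


def concat_channels(a, b):
    """Concatenate two (C,H,W) tensors along the channel axis."""
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(np.concatenate([a.data, b.data], axis=0),
                 requires_grad=_needs(a, b), _parents=(a, b))
    ca = a.data.shape[0]

    def bwd(g):
        if a.requires_grad:
            a._accum(g[:ca])
        if b.requires_grad:
            b._accum(g[ca:])

    out._backward = bwd
    return out


# -- spatial ops --------------------------------------------------------

def _im2col(xpad, kh, kw, stride):
    # (C, Ho, Wo, kh, kw) view -> (C*kh*kw, Ho*Wo) contiguous
    win = sliding_window_view(xpad, (kh, kw), axis=(1, 2))[:, ::stride, ::stride]
    c, ho, wo = win.shape[0], win.shape[1], win.shape[2]
    cols = np.ascontiguousarray(win.transpose(0, 3, 4, 1, 2)).reshape(c * kh * kw, ho * wo)
    return cols, ho, wo


def conv2d(x, w, b, stride=1, pad=0):
    """2D correlation of a (C,H,W) tensor with (Cout,Cin,kh,kw) weights."""
    x, w, b = as_tensor(x), as_tensor(w), as_tensor(b)
    cin, h, wi = x.data.shape
    cout, cin_w, kh, kw = w.data.shape
    if cin != cin_w:
        raise ValueError(f"conv2d channel mismatch: input {cin}, weight {cin_w}")
    xpad = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad))) if pad else x.data
    cols, ho, wo = _im2col(xpad, kh, kw, stride)
    wmat = w.data.reshape(cout, cin * kh * kw)
    y = (wmat @ cols + b.data[:, None]).reshape(cout, ho, wo)
    out = Tensor(y, requires_grad=_needs(x, w, b), _parents=(x, w, b))

    def bwd(g):
        gmat = g.reshape(cout, ho * wo)
        if w.requires_grad:
            w._accum((gmat @ cols.T).reshape(w.data.shape))
        if b.requires_grad:
            b._accum(gmat.sum(axis=1))
        if x.requires_grad:
            dcols = (wmat.T @ gmat).reshape(cin, kh, kw, ho, wo)
            dxpad = np.zeros_like(xpad)
            for di in range(kh):
                for dj in range(kw):
                    dxpad[:, di:di + stride * ho:stride,
                          dj:dj + stride * wo:stride] += dcols[:, di, dj]
            x._accum(dxpad[:, pad:pad + h, pad:pad + wi] if pad else dxpad)

    out._backward = bwd
    return out


def conv_transpose2x2(x, w, b):
    """Transposed convolution with kernel 2, stride 2 (exact 2x upsampling).

    ``w`` has shape (Cin, Cout, 2, 2).
    """
    x, w, b = as_tensor(x), as_tensor(w), as_tensor(b)
    cin, h, wi = x.data.shape
    cin_w, cout = w.data.shape[0], w.data.shape[1]
    if cin != cin_w:
        raise ValueError(f"conv_transpose channel mismatch: input {cin}, weight {cin_w}")
    xm = x.data.reshape(cin, h * wi)
    wm = w.data.transpose(1, 2, 3, 0).reshape(cout * 4, cin)
    y = (wm @ xm).reshape(cout, 2, 2, h, wi).transpose(0, 3, 1, 4, 2).reshape(cout, 2 * h, 2 * wi)
    y = y + b.data[:, None, None]
    out = Tensor(y, requires_grad=_needs(x, w, b), _parents=(x, w, b))

    def bwd(g):
        gm = np.ascontiguousarray(
            g.reshape(cout, h, 2, wi, 2).transpose(0, 2, 4, 1, 3)
        ).reshape(cout * 4, h * wi)
        if x.requires_grad:
            x._accum((wm.T @ gm).reshape(x.data.shape))
        if w.requires_grad:
            w._accum((gm @ xm.T).reshape(cout, 2, 2, cin).transpose(3, 0, 1, 2))
        if b.requires_grad:
            b._accum(g.sum(axis=(1, 2)))

    out._backward = bwd
    return out


def maxpool2x2(x):
    x = as_tensor(x)
    c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2x2 requires even spatial dimensions")
    win = np.ascontiguousarray(
        x.data.reshape(c, h // 2, 2, w // 2, 2).transpose(0, 1, 3, 2, 4)
    ).reshape(c, h // 2, w // 2, 4)
    idx = win.argmax(axis=-1)
    y = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
    out = Tensor(y, requires_grad=x.requires_grad, _parents=(x,))

    def bwd(g):
        if x.requires_grad:
            dwin = np.zeros_like(win)
            np.put_along_axis(dwin, idx[..., None], g[..., None], axis=-1)
            x._accum(
                dwin.reshape(c, h // 2, w // 2, 2, 2)
                .transpose(0, 1, 3, 2, 4)
                .reshape(c, h, w)
            )

    out._backward = bwd
    return out
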