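"""Layer containers with seeded He/Glorot initialization."""

from __future__ import annotations

import numpy as np

from .tensor import (
    Tensor,
    conv2d,
    conv_transpose2x2,
    leaky_relu,
    relu,
)

DTYPE = np.float32


class Module:
    """Container with named parameters, gathered recursively."""

    def parameters(self):
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_arrays(self):
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch: {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=p.data.dtype)


class Conv2d(Module):
    def __init__(self, cin, cout, kernel, rng, stride=1, pad=None, gain="relu"):
        self.stride = stride
        self.pad = kernel // 2 if pad is None else pad
        fan_in = cin * kernel * kernel
        scale = np.sqrt(2.0 / fan_in) if gain == "relu" else np.sqrt(1.0 / fan_in)
        self.w = Tensor(
            rng.normal(0.0, scale, size=(cout, cin, kernel, kernel)).astype(DTYPE),
            requires_grad=True,
        )
        self.b = Tensor(np.zeros(cout, dtype=DTYPE), requires_grad=True)

    def __call__(self, x):
        return conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class ConvTranspose2x2(Module):
    def __init__(self, cin, cout, rng):
        scale = np.sqrt(2.0 / (cin * 4))
        self.w = Tensor(
            rng.normal(0.0, scale, size=(cin, cout, 2, 2)).astype(DTYPE),
            requires_grad=True,
        )
        self.b = Tensor(np.zeros(cout, dtype=DTYPE), requires_grad=True)

    def __call__(self, x):
        return conv_transpose2x2(x, self.w, self.b)


class DoubleConv(Module):
    """Two 3x3 same-padding convolutions, each followed by ReLU."""

    def __init__(self, cin, cout, rng):
        self.c1 = Conv2d(cin, cout, 3, rng)
        self.c2 = Conv2d(cout, cout, 3, rng)

    def __call__(self, x):
        return relu(self.c2(relu(self.c1(x))))


class LeakyConv(Module):
    def __init__(self, cin, cout, kernel, rng, alpha=0.2):
        self.conv = Conv2d(cin, cout, kernel, rng, stride=2, gain="linear")
        self.alpha = alpha

    def __call__(self, x):
        return leaky_relu(self.conv(x), self.alpha)


class Adam(Module):
    """Adam over an explicit parameter list; state keyed by position."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.99, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / bias1
            vhat = self.v[i] / bias2
            p.data = p.data - (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
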