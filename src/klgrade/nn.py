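"""Minimal NumPy neural-network core with explicit reverse-mode gradients.

Layers are functional: ``forward`` returns ``(output, cache)`` and
``backward`` consumes that cache, returning the input gradient while
*accumulating* parameter gradients into ``Param.grad``.  The accumulation
contract is what lets one encoder instance serve two patch streams
(weight sharing): run forward twice with separate caches, backward twice,
and the shared parameters collect both contributions.

Shapes follow the (batch, channel, height, width) convention.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False, rng=None):
        raise NotImplementedError

    def backward(self, dy: np.ndarray, cache):
        raise NotImplementedError


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """(B,C,H,W) -> (B, out_h*out_w, C*kh*kw) patch matrix."""
    b, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    out_h = (h + 2 * pad - kh) // stride + 1
    out_w = (w + 2 * pad - kw) // stride + 1
    s0, s1, s2, s3 = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x,
        shape=(b, c, out_h, out_w, kh, kw),
        strides=(s0, s1, s2 * stride, s3 * stride, s2, s3),
        writeable=False,
    )
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(b, out_h * out_w, c * kh * kw)
    return cols, out_h, out_w


def _col2im(cols, x_shape, kh, kw, stride, pad):
    """Scatter-add the inverse of :func:`_im2col`."""
    b, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    out_h = (hp - kh) // stride + 1
    out_w = (wp - kw) // stride + 1
    dx = np.zeros((b, c, hp, wp))
    cols = cols.reshape(b, out_h, out_w, c, kh, kw)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i : i + out_h * stride : stride, j : j + out_w * stride : stride] += (
                cols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            )
    return dx[:, :, pad : pad + h, pad : pad + w] if pad else dx


class Conv2d(Layer):
    """Cross-correlation with He-normal initialization."""

    def __init__(self, in_ch, out_ch, kernel=3, stride=1, pad=1, rng=None, name="conv"):
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, kernel, kernel))
        self.weight = Param(w, f"{name}.weight")
        self.bias = Param(np.zeros(out_ch), f"{name}.bias")
        self.kernel, self.stride, self.pad = kernel, stride, pad

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train=False, rng=None):
        k = self.kernel
        cols, out_h, out_w = _im2col(x, k, k, self.stride, self.pad)
        wmat = self.weight.value.reshape(self.weight.value.shape[0], -1)
        y = cols @ wmat.T + self.bias.value
        y = y.transpose(0, 2, 1).reshape(x.shape[0], -1, out_h, out_w)
        return y, (x.shape, cols)

    def backward(self, dy, cache):
        x_shape, cols = cache
        b, oc, oh, ow = dy.shape
        dy_mat = dy.reshape(b, oc, oh * ow).transpose(0, 2, 1)  # (B, P, OC)
        wmat = self.weight.value.reshape(oc, -1)
        self.weight.grad += np.einsum("bpo,bpk->ok", dy_mat, cols).reshape(
            self.weight.value.shape
        )
        self.bias.grad += dy_mat.sum(axis=(0, 1))
        dcols = dy_mat @ wmat
        return _col2im(dcols, x_shape, self.kernel, self.kernel, self.stride, self.pad)


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        y = np.maximum(x, 0.0)
        return y, (x > 0.0)

    def backward(self, dy, cache):
        return dy * cache


class Linear(Layer):
    def __init__(self, in_dim, out_dim, rng=None, name="linear", bias=True):
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(1.0 / in_dim), size=(out_dim, in_dim))
        self.weight = Param(w, f"{name}.weight")
        self.bias = Param(np.zeros(out_dim), f"{name}.bias") if bias else None

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x, train=False, rng=None):
        y = x @ self.weight.value.T
        if self.bias is not None:
            y = y + self.bias.value
        return y, x

    def backward(self, dy, cache):
        x = cache
        self.weight.grad += dy.T @ x
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.value


class Dropout(Layer):
    def __init__(self, p: float = 0.1):
        self.p = p

    def forward(self, x, train=False, rng=None):
        if not train or self.p <= 0.0:
            return x, None
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * mask, mask

    def backward(self, dy, cache):
        return dy if cache is None else dy * cache


class GeMPool(Layer):
    """Generalized-mean spatial pooling with a learnable exponent.

    ``y_c = (mean_{hw} clamp(x, eps)^p)^(1/p)``: p=1 is average pooling and
    p -> inf approaches max pooling, letting the network learn how sharply
    to focus on the most informative spatial locations.
    """

    def __init__(self, p_init: float = 3.0, eps: float = 1e-6, name="gem"):
        if p_init < 1.0:
            raise ValueError("GeM exponent must be >= 1")
        self.p = Param(np.array(float(p_init)), f"{name}.p")
        self.eps = eps

    def params(self):
        return [self.p]

    def forward(self, x, train=False, rng=None):
        p = float(self.p.value)
        xc = np.maximum(x, self.eps)
        m = (xc**p).mean(axis=(2, 3))  # (B, C)
        y = m ** (1.0 / p)
        return y, (x, xc, m, y)

    def backward_input(self, dy, cache):
        """Input gradient only (no accumulation into the exponent)."""
        x, xc, m, y = cache
        p = float(self.p.value)
        hw = x.shape[2] * x.shape[3]
        # dy/dx_i = m^(1/p - 1) * xc_i^(p-1) / hw, zero where the clamp binds
        coef = (m ** (1.0 / p - 1.0) / hw)[:, :, None, None]
        dx = dy[:, :, None, None] * coef * xc ** (p - 1.0)
        dx[x < self.eps] = 0.0
        return dx

    def backward(self, dy, cache):
        x, xc, m, y = cache
        p = float(self.p.value)
        dx = self.backward_input(dy, cache)
        # dy/dp = y * (-ln m / p^2 + mean(xc^p ln xc) / (p m))
        logm = np.log(m)
        mlog = ((xc**p) * np.log(xc)).mean(axis=(2, 3))
        dp = y * (-logm / p**2 + mlog / (p * m))
        self.p.grad += float((dy * dp).sum())
        return dx


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=False, rng=None):
        caches = []
        for layer in self.layers:
            x, c = layer.forward(x, train=train, rng=rng)
            caches.append(c)
        return x, caches

    def backward(self, dy, caches):
        for layer, c in zip(reversed(self.layers), reversed(caches)):
            dy = layer.backward(dy, c)
        return dy


def l2_normalize(x: np.ndarray, eps: float = 1e-12):
    """Row-wise unit-norm projection; returns (y, cache) for backward."""
    norm = np.sqrt((x**2).sum(axis=1, keepdims=True))
    norm = np.maximum(norm, eps)
    y = x / norm
    return y, (y, norm)


def l2_normalize_backward(dy: np.ndarray, cache):
    y, norm = cache
    return (dy - y * (y * dy).sum(axis=1, keepdims=True)) / norm


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=axis, keepdims=True))


class AdamW:
    """Decoupled-weight-decay Adam over named parameter groups.

    Each group is ``{"params": [...], "lr": float, "weight_decay": float}``;
    ``lr`` may be updated between steps by a schedule.
    """

    def __init__(self, groups, betas=(0.9, 0.999), eps=1e-8):
        self.groups = groups
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.state = {}
        for g in groups:
            for p in g["params"]:
                self.state[id(p)] = (np.zeros_like(p.value), np.zeros_like(p.value))

    def zero_grad(self):
        for g in self.groups:
            for p in g["params"]:
                p.zero_grad()

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for g in self.groups:
            lr = g["lr"]
            wd = g.get("weight_decay", 0.0)
            for p in g["params"]:
                m, v = self.state[id(p)]
                m *= self.b1
                m += (1.0 - self.b1) * p.grad
                v *= self.b2
                v += (1.0 - self.b2) * p.grad**2
                update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
                p.value -= lr * (update + wd * p.value)
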