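"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the segmentation network needs: stride-1
same-padding 2-D convolution, 2x2 max pooling, 2x nearest upsampling, batch
normalization, channel concatenation, elementwise arithmetic with
broadcasting, ReLU/sigmoid/log/clip, reductions, dropout, and a
channel-wise k-extreme order-statistics primitive.

All feature tensors are float32 NHWC (batch, height, width, channels);
convolution kernels are (kh, kw, Cin, Cout).  The channels-last layout lets
convolution run as a handful of shifted (HW, C) x (C, F) matrix products,
which is the fastest pure-NumPy formulation on one core.  Gradients are
accumulated into ``Tensor.grad`` by ``Tensor.backward()`` over a
topologically sorted tape.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "as_tensor", "add", "sub", "mul", "div", "relu", "sigmoid",
    "log", "clip", "tsum", "tmean", "concat", "conv2d", "maxpool2",
    "upsample2", "batchnorm", "dropout", "channel_extremes",
]


class Tensor:
    """A NumPy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        """Reverse-accumulate gradients from this (scalar) tensor."""
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
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(t, g):
    if not (t.requires_grad or t._parents):
        return
    if t.grad is None:
        t.grad = np.zeros_like(t.data)
    t.grad += g


def _unbroadcast(g, shape):
    """Sum gradient ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def _make(data, parents, backward):
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out._parents = tuple(parents)
        out._backward = backward
    return out


# ---------------------------------------------------------------- arithmetic

def add(a, b):
    a, b = as_tensor(a), as_tensor(b)

    def bw(g):
        _accum(a, _unbroadcast(g, a.shape))
        _accum(b, _unbroadcast(g, b.shape))

    return _make(a.data + b.data, (a, b), bw)


def sub(a, b):
    a, b = as_tensor(a), as_tensor(b)

    def bw(g):
        _accum(a, _unbroadcast(g, a.shape))
        _accum(b, _unbroadcast(-g, b.shape))

    return _make(a.data - b.data, (a, b), bw)


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)

    def bw(g):
        _accum(a, _unbroadcast(g * b.data, a.shape))
        _accum(b, _unbroadcast(g * a.data, b.shape))

    return _make(a.data * b.data, (a, b), bw)


def div(a, b):
    a, b = as_tensor(a), as_tensor(b)

    def bw(g):
        _accum(a, _unbroadcast(g / b.data, a.shape))
        _accum(b, _unbroadcast(-g * a.data / (b.data * b.data), b.shape))

    return _make(a.data / b.data, (a, b), bw)


# --------------------------------------------------------------- activations

def relu(x):
    x = as_tensor(x)
    mask = x.data > 0

    def bw(g):
        _accum(x, g * mask)

    return _make(np.where(mask, x.data, 0.0), (x,), bw)


def sigmoid(x):
    x = as_tensor(x)
    s = np.empty_like(x.data)
    pos = x.data >= 0
    s[pos] = 1.0 / (1.0 + np.exp(-x.data[pos]))
    ex = np.exp(x.data[~pos])
    s[~pos] = ex / (1.0 + ex)

    def bw(g):
        _accum(x, g * s * (1.0 - s))

    return _make(s, (x,), bw)


def log(x):
    x = as_tensor(x)

    def bw(g):
        _accum(x, g / x.data)

    return _make(np.log(x.data), (x,), bw)


def clip(x, lo, hi):
    x = as_tensor(x)
    mask = (x.data > lo) & (x.data < hi)

    def bw(g):
        _accum(x, g * mask)

    return _make(np.clip(x.data, lo, hi), (x,), bw)


# ---------------------------------------------------------------- reductions

def tsum(x):
    x = as_tensor(x)

    def bw(g):
        _accum(x, np.full(x.shape, g, dtype=np.float32))

    return _make(x.data.sum(), (x,), bw)


def tmean(x):
    x = as_tensor(x)
    n = x.data.size

    def bw(g):
        _accum(x, np.full(x.shape, g / n, dtype=np.float32))

    return _make(x.data.mean(), (x,), bw)


# -------------------------------------------------------------- shape ops

def concat(tensors, axis=-1):
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, gi in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, gi)

    return _make(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), bw)


def upsample2(x):
    """2x nearest-neighbour upsampling on NHWC."""
    x = as_tensor(x)

    def bw(g):
        n, h2, w2, c = g.shape
        _accum(x, g.reshape(n, h2 // 2, 2, w2 // 2, 2, c).sum(axis=(2, 4)))

    return _make(np.repeat(np.repeat(x.data, 2, axis=1), 2, axis=2), (x,), bw)


def maxpool2(x):
    """2x2 max pooling, stride 2, on NHWC with even spatial dims."""
    x = as_tensor(x)
    n, h, w, c = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2 requires even spatial dims, got {h}x{w}")
    windows = x.data.reshape(n, h // 2, 2, w // 2, 2, c)
    flat = windows.transpose(0, 1, 3, 2, 4, 5).reshape(n, h // 2, w // 2, 4, c)
    arg = flat.argmax(axis=3)
    out = np.take_along_axis(flat, arg[:, :, :, None], axis=3)[:, :, :, 0]

    def bw(g):
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, arg[:, :, :, None], g[:, :, :, None], axis=3)
        gx = gflat.reshape(n, h // 2, w // 2, 2, 2, c).transpose(
            0, 1, 3, 2, 4, 5).reshape(n, h, w, c)
        _accum(x, gx)

    return _make(np.ascontiguousarray(out), (x,), bw)


# ------------------------------------------------------------- convolution

def conv2d(x, w, b=None):
    """Stride-1 'same' cross-correlation.

    x: (N, H, W, Cin); w: (kh, kw, Cin, Cout); b: (Cout,).  Runs as kh*kw
    shifted matrix products on the channels-last layout.
    """
    x, w = as_tensor(x), as_tensor(w)
    b = as_tensor(b) if b is not None else None
    kh, kw, cin, cout = w.shape
    if x.shape[-1] != cin:
        raise ValueError(f"conv2d channel mismatch: input {x.shape[-1]}, "
                         f"kernel expects {cin}")
    n, h, wd = x.shape[:3]
    ph, pw = kh // 2, kw // 2
    if kh == 1 and kw == 1:
        xpad = x.data
    else:
        xpad = np.pad(x.data, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    out = np.zeros((n, h, wd, cout), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            out += xpad[:, i:i + h, j:j + wd, :] @ w.data[i, j]
    if b is not None:
        out += b.data

    def bw(g):
        if b is not None:
            _accum(b, g.sum(axis=(0, 1, 2)))
        gflat = g.reshape(-1, cout)
        if w.requires_grad or w._parents:
            gw = np.empty_like(w.data)
            for i in range(kh):
                for j in range(kw):
                    xs = xpad[:, i:i + h, j:j + wd, :].reshape(-1, cin)
                    gw[i, j] = xs.T @ gflat
            _accum(w, gw)
        if x.requires_grad or x._parents:
            gxpad = np.zeros_like(xpad)
            for i in range(kh):
                for j in range(kw):
                    gxpad[:, i:i + h, j:j + wd, :] += g @ w.data[i, j].T
            if kh == 1 and kw == 1:
                _accum(x, gxpad)
            else:
                _accum(x, gxpad[:, ph:ph + h, pw:pw + wd, :])

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, bw)


# --------------------------------------------------------- batch norm & drop

def batchnorm(x, gamma, beta, running_mean, running_var, training,
              momentum=0.1, eps=1e-5):
    """Per-channel batch normalization on NHWC.

    ``running_mean``/``running_var`` are plain float32 arrays mutated in
    place during training (standard running-estimate update).
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    axes = (0, 1, 2)
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= (1 - momentum)
        running_mean += momentum * mean
        running_var *= (1 - momentum)
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv = (1.0 / np.sqrt(var + eps)).astype(np.float32)
    xhat = (x.data - mean) * inv
    out = gamma.data * xhat + beta.data

    def bw(g):
        _accum(gamma, (g * xhat).sum(axis=axes))
        _accum(beta, g.sum(axis=axes))
        if x.requires_grad or x._parents:
            if training:
                m = x.data.shape[0] * x.data.shape[1] * x.data.shape[2]
                gxh = g * gamma.data
                t1 = gxh - gxh.mean(axis=axes, keepdims=True)
                t2 = xhat * (gxh * xhat).sum(axis=axes, keepdims=True) / m
                _accum(x, inv * (t1 - t2))
            else:
                _accum(x, g * (gamma.data * inv))

    return _make(out.astype(np.float32), (x, gamma, beta), bw)


def dropout(x, rate, rng, training):
    x = as_tensor(x)
    if not training or rate <= 0.0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.shape) < keep).astype(np.float32) / keep

    def bw(g):
        _accum(x, g * mask)

    return _make(x.data * mask, (x,), bw)


# ---------------------------------------------------- order-statistics core

def channel_extremes(x, k):
    """Per-pixel mean of the k smallest / k largest channel values.

    x: (N, H, W, C) -> (small, large), each (N, H, W, 1).  The backward pass
    routes gradient 1/k to each selected channel entry.
    """
    x = as_tensor(x)
    c = x.shape[-1]
    if not 1 <= k <= c:
        raise ValueError(f"k must be in [1, {c}], got {k}")
    order = np.argsort(x.data, axis=-1, kind="stable")
    srt = np.take_along_axis(x.data, order, axis=-1)
    small = srt[..., :k].mean(axis=-1, keepdims=True)
    large = srt[..., c - k:].mean(axis=-1, keepdims=True)

    def bw_small(g):
        gx = np.zeros_like(x.data)
        np.put_along_axis(gx, order[..., :k],
                          np.broadcast_to(g / k, order[..., :k].shape), axis=-1)
        _accum(x, gx)

    def bw_large(g):
        gx = np.zeros_like(x.data)
        np.put_along_axis(gx, order[..., c - k:],
                          np.broadcast_to(g / k, order[..., c - k:].shape),
                          axis=-1)
        _accum(x, gx)

    out_s = _make(small, (x,), bw_small)
    out_l = _make(large, (x,), bw_large)
    return out_s, out_l
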