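"""Minimal 3D-convolutional layer library (numpy, CPU).

Tensors are channel-first float32: (N, C, T, H, W).  Convolutions are im2col
matrix products; backward passes are hand-written.  Padding per axis is
either "same" (output extent = ceil(input/stride), TF-style asymmetric pad)
or "valid" (no pad) — the temporal axis of the last stride-2 pool in the clip
classifiers is "valid" so 20 input frames reach a temporal extent of 2 before
the final average pool.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

# im2col buffers above this many bytes are processed in temporal chunks
_CHUNK_BYTES = 2.5e8


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def forward(self, x, train=False):
        raise NotImplementedError

    def backward(self, dy):
        raise NotImplementedError

    def params(self):
        return []

    def initialize(self, rng):
        pass

    def iter_layers(self):
        yield self


def _pad_amount(n: int, k: int, s: int, mode: str):
    if mode == "valid":
        return 0, 0
    out = -(-n // s)
    total = max(0, (out - 1) * s + k - n)
    return total // 2, total - total // 2


def _out_extent(n: int, k: int, s: int, mode: str) -> int:
    lo, hi = _pad_amount(n, k, s, mode)
    return (n + lo + hi - k) // s + 1


def _windows(xp: np.ndarray, kernel, stride):
    """Strided view (N, C, To, Ho, Wo, kt, kh, kw) of padded input."""
    w = sliding_window_view(xp, kernel, axis=(2, 3, 4))
    return w[:, :, ::stride[0], ::stride[1], ::stride[2]]


class Conv3d(Layer):
    """3D convolution with bias.  kernel/stride are (t, h, w) triples.

    im2col layout is (N, C*kt*kh*kw, positions), filled by one strided copy
    per kernel offset; 1x1x1 stride-1 convolutions skip im2col entirely and
    run as a channel matmul.
    """

    def __init__(self, cin, cout, kernel, stride=(1, 1, 1), pad=("same",) * 3):
        self.cin, self.cout = cin, cout
        self.kernel = tuple(kernel)
        self.stride = tuple(stride)
        self.pad = tuple(pad)
        k = int(np.prod(self.kernel)) * cin
        self.W = Param(np.zeros((cout, k)))
        self.b = Param(np.zeros(cout))
        self.initialize(np.random.default_rng(0))

    def initialize(self, rng):
        fan_in = self.W.value.shape[1]
        self.W.value = (rng.standard_normal(self.W.value.shape)
                        * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b.value = np.zeros(self.cout, dtype=np.float32)

    def params(self):
        return [self.W, self.b]

    @property
    def _pointwise(self):
        return self.kernel == (1, 1, 1) and self.stride == (1, 1, 1)

    def _im2col(self, xp, ot, oh, ow):
        N, C = xp.shape[:2]
        kt, kh, kw = self.kernel
        st, sh, sw = self.stride
        # pre-subsample by stride residue so each kernel-offset copy below is
        # a cheap unit-stride slice rather than a strided gather
        sub = {}
        for rt in range(st):
            for rh in range(sh):
                for rw in range(sw):
                    sub[rt, rh, rw] = np.ascontiguousarray(
                        xp[:, :, rt::st, rh::sh, rw::sw])
        cols = np.empty((N, C, kt, kh, kw, ot, oh, ow), dtype=np.float32)
        for i in range(kt):
            for j in range(kh):
                for k in range(kw):
                    s = sub[i % st, j % sh, k % sw]
                    cols[:, :, i, j, k] = s[:, :, i // st:i // st + ot,
                                            j // sh:j // sh + oh,
                                            k // sw:k // sw + ow]
        return cols.reshape(N, C * kt * kh * kw, ot * oh * ow)

    def forward(self, x, train=False):
        N, C, T, H, W = x.shape
        assert C == self.cin, (C, self.cin)
        x = x.astype(np.float32, copy=False)
        if self._pointwise:
            xm = x.reshape(N, C, -1)
            y = np.matmul(self.W.value, xm)
            y += self.b.value[:, None]
            if train:
                self._cols = xm
                self._oshape = (T, H, W)
                self._xp_shape, self._pads = x.shape, None
            return np.ascontiguousarray(y.reshape(N, self.cout, T, H, W))
        pads = [(0, 0), (0, 0)] + [
            _pad_amount(n, k, s, m)
            for n, k, s, m in zip(x.shape[2:], self.kernel, self.stride, self.pad)
        ]
        xp = np.pad(x, pads)
        ot, oh, ow = [(n - k) // s + 1 for n, k, s in
                      zip(xp.shape[2:], self.kernel, self.stride)]
        cols = self._im2col(xp, ot, oh, ow)
        y = np.matmul(self.W.value, cols)
        y += self.b.value[:, None]
        if train:
            self._cols = cols
            self._xp_shape = xp.shape
            self._pads = pads
            self._oshape = (ot, oh, ow)
        return np.ascontiguousarray(y.reshape((N, self.cout, ot, oh, ow)))

    def backward(self, dy):
        N = dy.shape[0]
        ot, oh, ow = self._oshape
        dym = np.ascontiguousarray(dy.reshape(N, self.cout, -1))
        self.W.grad += np.matmul(dym, self._cols.transpose(0, 2, 1)).sum(axis=0)
        self.b.grad += dym.sum(axis=(0, 2))
        dcols = np.matmul(self.W.value.T, dym)
        self._cols = None
        if self._pointwise:
            return dcols.reshape((N, self.cin) + self._oshape)
        kt, kh, kw = self.kernel
        st, sh, sw = self.stride
        dcols = dcols.reshape(N, self.cin, kt, kh, kw, ot, oh, ow)
        dxp = np.zeros(self._xp_shape, dtype=np.float32)
        for i in range(kt):
            for j in range(kh):
                for k in range(kw):
                    dxp[:, :, i:i + st * ot:st, j:j + sh * oh:sh,
                        k:k + sw * ow:sw] += dcols[:, :, i, j, k]
        (t0, t1), (h0, h1), (w0, w1) = self._pads[2:]
        Tp, Hp, Wp = self._xp_shape[2:]
        return dxp[:, :, t0:Tp - t1, h0:Hp - h1, w0:Wp - w1]


class BatchNorm3d(Layer):
    def __init__(self, c, momentum=0.9, eps=1e-5):
        self.c, self.momentum, self.eps = c, momentum, eps
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def initialize(self, rng):
        self.gamma.value = np.ones(self.c, dtype=np.float32)
        self.beta.value = np.zeros(self.c, dtype=np.float32)
        self.running_mean[:] = 0
        self.running_var[:] = 1

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        axes = (0, 2, 3, 4)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        sh = (1, -1, 1, 1, 1)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(sh)) * inv.reshape(sh)
        if train:
            self._xhat, self._inv, self._n = xhat, inv, x.size // x.shape[1]
        return (self.gamma.value.reshape(sh) * xhat
                + self.beta.value.reshape(sh)).astype(np.float32)

    def backward(self, dy):
        sh = (1, -1, 1, 1, 1)
        axes = (0, 2, 3, 4)
        xhat, inv, n = self._xhat, self._inv, self._n
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        g = self.gamma.value.reshape(sh)
        dxhat = dy * g
        dx = (inv.reshape(sh) / n) * (
            n * dxhat
            - dxhat.sum(axis=axes).reshape(sh)
            - xhat * (dxhat * xhat).sum(axis=axes).reshape(sh)
        )
        self._xhat = None
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x, train=False):
        y = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy):
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool3d(Layer):
    """Max pooling; "same" padding uses -inf fill, per-axis "valid" supported."""

    def __init__(self, kernel, stride, pad=("same",) * 3):
        self.kernel, self.stride, self.pad = tuple(kernel), tuple(stride), tuple(pad)

    def forward(self, x, train=False):
        pads = [(0, 0), (0, 0)] + [
            _pad_amount(n, k, s, m)
            for n, k, s, m in zip(x.shape[2:], self.kernel, self.stride, self.pad)
        ]
        xp = np.pad(x, pads, constant_values=-np.inf)
        w = _windows(xp, self.kernel, self.stride)
        N, C, ot, oh, ow = w.shape[:5]
        flat = w.reshape(N, C, ot, oh, ow, -1)
        idx = flat.argmax(axis=-1)
        y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._xp_shape, self._pads = idx, xp.shape, pads
        return np.ascontiguousarray(y)

    def backward(self, dy):
        kt, kh, kw = self.kernel
        st, sh, sw = self.stride
        N, C, ot, oh, ow = dy.shape
        idx = self._idx
        # unravel window argmax into padded-input coordinates
        it = idx // (kh * kw)
        ij = (idx // kw) % kh
        ik = idx % kw
        t = it + st * np.arange(ot).reshape(1, 1, ot, 1, 1)
        h = ij + sh * np.arange(oh).reshape(1, 1, 1, oh, 1)
        w = ik + sw * np.arange(ow).reshape(1, 1, 1, 1, ow)
        n = np.arange(N).reshape(N, 1, 1, 1, 1)
        c = np.arange(C).reshape(1, C, 1, 1, 1)
        Tp, Hp, Wp = self._xp_shape[2:]
        flat = (((n * C + c) * Tp + t) * Hp + h) * Wp + w
        dxp = np.zeros(N * C * Tp * Hp * Wp, dtype=np.float32)
        np.add.at(dxp, np.broadcast_to(flat, dy.shape).ravel(), dy.ravel())
        dxp = dxp.reshape(self._xp_shape)
        (t0, t1), (h0, h1), (w0, w1) = self._pads[2:]
        self._idx = None
        return dxp[:, :, t0:Tp - t1, h0:Hp - h1, w0:Wp - w1]


class GlobalAvgPool(Layer):
    """Average over the full remaining (T, H, W) extent -> (N, C).

    At the nominal 20x224x224 input the remaining extent is exactly the
    printed 2x7x7 pooling window.
    """

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, dy):
        N, C, T, H, W = self._shape
        return np.broadcast_to(dy[:, :, None, None, None] / (T * H * W),
                               self._shape).astype(np.float32)


class Linear(Layer):
    def __init__(self, cin, cout):
        self.cin, self.cout = cin, cout
        self.W = Param(np.zeros((cout, cin)))
        self.b = Param(np.zeros(cout))
        self.initialize(np.random.default_rng(0))

    def initialize(self, rng):
        self.W.value = (rng.standard_normal((self.cout, self.cin))
                        * np.sqrt(2.0 / self.cin)).astype(np.float32)
        self.b.value = np.zeros(self.cout, dtype=np.float32)

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, dy):
        self.W.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        dx = dy @ self.W.value
        self._x = None
        return dx


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def initialize(self, rng):
        for layer in self.layers:
            layer.initialize(rng)

    def iter_layers(self):
        for layer in self.layers:
            yield from layer.iter_layers()


class InceptionModule(Layer):
    """Four parallel branches concatenated along channels.

    Branches: 1x1x1 conv; 1x1x1 bottleneck then 3x3x3; a second (narrower)
    1x1x1 then 3x3x3; and 3x3x3 maxpool then 1x1x1 projection.  All branches
    preserve the spatiotemporal extent.
    """

    def __init__(self, cin, spec):
        b1, (b2r, b2), (b3r, b3), b4 = spec
        conv = lambda ci, co, k: [Conv3d(ci, co, (k,) * 3), BatchNorm3d(co), ReLU()]
        self.branches = [
            Sequential(conv(cin, b1, 1)),
            Sequential(conv(cin, b2r, 1) + conv(b2r, b2, 3)),
            Sequential(conv(cin, b3r, 1) + conv(b3r, b3, 3)),
            Sequential([MaxPool3d((3, 3, 3), (1, 1, 1))] + conv(cin, b4, 1)),
        ]
        self.cout = b1 + b2 + b3 + b4

    def forward(self, x, train=False):
        outs = [b.forward(x, train=train) for b in self.branches]
        self._splits = np.cumsum([o.shape[1] for o in outs])[:-1]
        return np.concatenate(outs, axis=1)

    def backward(self, dy):
        parts = np.split(dy, self._splits, axis=1)
        dx = None
        for b, p in zip(self.branches, parts):
            d = b.backward(np.ascontiguousarray(p))
            dx = d if dx is None else dx + d
        return dx

    def params(self):
        return [p for b in self.branches for p in b.params()]

    def initialize(self, rng):
        for b in self.branches:
            b.initialize(rng)

    def iter_layers(self):
        for b in self.branches:
            yield from b.iter_layers()


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy and gradient w.r.t. logits."""
    p = softmax(logits)
    n = len(labels)
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    d = p.copy()
    d[np.arange(n), labels] -= 1.0
    return float(loss), (d / n).astype(np.float32)
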