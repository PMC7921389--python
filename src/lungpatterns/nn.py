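"""Minimal 3D convolutional network layers with explicit backpropagation.

All layers operate on float32 arrays of shape ``(batch, channels, D, H, W)``
and store whatever they need from the forward pass to compute gradients.
Convolutions are 3x3x3 with padding 1; stride is 1 or 2.  im2col buffers are
chunked over the batch axis to bound peak memory.
"""

from __future__ import annotations

import numpy as np


def _offset_slice(stride: int, a: int, b: int, c: int, do: int, ho: int, wo: int):
    return (slice(a, a + stride * do, stride),
            slice(b, b + stride * ho, stride),
            slice(c, c + stride * wo, stride))


def conv3d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int) -> np.ndarray:
    """Offset-sum convolution: for each of the 27 kernel taps, a strided slice
    of the padded input hits one GEMM with the (c_out, c_in) tap matrix."""
    bsz, c_in, d, h, wd = x.shape
    c_out = w.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
    do, ho, wo = d // stride, h // stride, wd // stride
    n = do * ho * wo
    acc = np.zeros((c_out, bsz * n), np.float32)
    for a in range(3):
        for bb in range(3):
            for c in range(3):
                sl = (slice(None), slice(None)) + _offset_slice(stride, a, bb, c, do, ho, wo)
                xs = np.ascontiguousarray(xp[sl].transpose(1, 0, 2, 3, 4)).reshape(c_in, bsz * n)
                acc += w[:, :, a, bb, c] @ xs
    out = acc.reshape(c_out, bsz, do, ho, wo).transpose(1, 0, 2, 3, 4)
    return np.ascontiguousarray(out) + b[None, :, None, None, None]


def conv3d_backward(x: np.ndarray, w: np.ndarray, stride: int, g: np.ndarray):
    """Return (grad_x, grad_w, grad_b) for conv3d_forward."""
    bsz, c_in, d, h, wd = x.shape
    c_out = w.shape[0]
    do, ho, wo = g.shape[2:]
    n = do * ho * wo
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
    gm = np.ascontiguousarray(g.transpose(1, 0, 2, 3, 4)).reshape(c_out, bsz * n)
    gw = np.empty_like(w)
    gb = g.sum(axis=(0, 2, 3, 4))
    gxp = np.zeros_like(xp)
    for a in range(3):
        for bb in range(3):
            for c in range(3):
                sl = (slice(None), slice(None)) + _offset_slice(stride, a, bb, c, do, ho, wo)
                xs = np.ascontiguousarray(xp[sl].transpose(1, 0, 2, 3, 4)).reshape(c_in, bsz * n)
                gw[:, :, a, bb, c] = gm @ xs.T
                contrib = (w[:, :, a, bb, c].T @ gm).reshape(c_in, bsz, do, ho, wo)
                gxp[sl] += contrib.transpose(1, 0, 2, 3, 4)
    gx = gxp[:, :, 1:1 + d, 1:1 + h, 1:1 + wd]
    return gx, gw, gb


class Conv3d:
    """3x3x3 convolution, padding 1, stride 1 or 2, He-initialised."""

    def __init__(self, c_in: int, c_out: int, stride: int, rng: np.random.Generator,
                 bias_init: float = 0.0):
        fan_in = c_in * 27
        self.w = (rng.standard_normal((c_out, c_in, 3, 3, 3)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.full(c_out, bias_init, np.float32)
        self.stride = stride
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._x = None

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]

    def forward(self, x):
        self._x = x
        return conv3d_forward(x, self.w, self.b, self.stride)

    def backward(self, g):
        gx, gw, gb = conv3d_backward(self._x, self.w, self.stride, g)
        self.gw += gw
        self.gb += gb
        return gx


class BatchNorm:
    """Per-channel batch standardisation with an optional learnable affine.

    Accepts (B, C) or (B, C, D, H, W) input.  Training mode uses batch
    statistics and maintains running estimates; evaluation mode uses the
    running estimates, so single-item and batched evaluation agree exactly.
    With `affine`, the shift is initialised slightly positive so that a
    degenerate (zero-variance) batch still produces a nonzero output that a
    downstream ReLU passes and gradients can reach.
    """

    def __init__(self, n_channels: int, momentum: float = 0.9, eps: float = 1e-5,
                 affine: bool = False):
        self.running_mean = np.zeros(n_channels, np.float32)
        self.running_var = np.ones(n_channels, np.float32)
        self.momentum = momentum
        self.eps = eps
        self.training = False
        self.affine = affine
        if affine:
            self.gamma = np.ones(n_channels, np.float32)
            self.beta = np.full(n_channels, 0.1, np.float32)
            self.ggamma = np.zeros_like(self.gamma)
            self.gbeta = np.zeros_like(self.beta)

    def params(self):
        if self.affine:
            return [(self.gamma, self.ggamma), (self.beta, self.gbeta)]
        return []

    def state_arrays(self):
        return [self.running_mean, self.running_var]

    @staticmethod
    def _axes(x):
        return (0,) if x.ndim == 2 else (0, 2, 3, 4)

    @staticmethod
    def _expand(v, x):
        return v[None, :] if x.ndim == 2 else v[None, :, None, None, None]

    def forward(self, x):
        axes = self._axes(x)
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean[...] = m * self.running_mean + (1 - m) * mean
            self.running_var[...] = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._expand(mean, x)) * self._expand(inv, x)
        if self.training:
            self._xhat = xhat
            self._inv = inv
            self._n = int(np.prod([x.shape[a] for a in axes]))
        else:
            self._xhat = xhat if self.affine else None
            self._inv = inv
        if self.affine:
            return self._expand(self.gamma, x) * xhat + self._expand(self.beta, x)
        return xhat

    def backward(self, g):
        axes = self._axes(g)
        if self.affine:
            self.ggamma += (g * self._xhat).sum(axis=axes).astype(np.float32)
            self.gbeta += g.sum(axis=axes).astype(np.float32)
            g = g * self._expand(self.gamma, g)
        if not self.training:  # eval mode: plain rescaling
            return g * self._expand(self._inv, g)
        n = self._n
        sum_g = g.sum(axis=axes)
        sum_gx = (g * self._xhat).sum(axis=axes)
        gx = g - (self._expand(sum_g, g) + self._xhat * self._expand(sum_gx, g)) / n
        return gx * self._expand(self._inv, g)


class ReLU:
    def params(self):
        return []

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, np.float32(0.0))

    def backward(self, g):
        return np.where(self._mask, g, np.float32(0.0))


class Upsample2:
    """Nearest-neighbour x2 upsampling along each spatial axis."""

    def params(self):
        return []

    def forward(self, x):
        self._shape = x.shape
        return x.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)

    def backward(self, g):
        b, c, d, h, w = self._shape
        return g.reshape(b, c, d, 2, h, 2, w, 2).sum(axis=(3, 5, 7))


class SpatialMean:
    """(B,C,s,s,s) -> (B,C) global average."""

    def params(self):
        return []

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, g):
        b, c, d, h, w = self._shape
        scale = np.float32(1.0 / (d * h * w))
        return np.broadcast_to((g * scale)[:, :, None, None, None], self._shape).astype(np.float32)


class Broadcast:
    """(B,C) -> (B,C,s,s,s) tiling; backward sums over space."""

    def __init__(self, size: int):
        self.size = size

    def params(self):
        return []

    def forward(self, x):
        s = self.size
        return np.broadcast_to(x[:, :, None, None, None], x.shape + (s, s, s)).astype(np.float32)

    def backward(self, g):
        return g.sum(axis=(2, 3, 4))


class Adam:
    """Adam over a list of (param, grad) array pairs; updates in place."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)

    def zero_grad(self):
        for _, g in self.params:
            g[...] = 0
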