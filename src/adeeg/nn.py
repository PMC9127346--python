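"""Minimal CPU neural-network layers with explicit backpropagation.

Convolutions are evaluated as GEMMs over im2col patches; the data
gradient is the transposed convolution (input gradient of a strided
convolution equals a stride-1 convolution of the zero-dilated output
gradient with the spatially flipped, channel-transposed kernel). All
tensors are float32 NCHW.

This is deliberately small: Conv2d, BatchNorm2d, ReLU, 2x2 MaxPool,
global average pooling, Linear, a residual block, softmax cross-entropy
and Adam — the pieces the recurrence-plot classifier needs.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Param:
    """A learnable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """Return (cols, out_h, out_w); cols is (N*Ho*Wo, C*kh*kw)."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    windows = sliding_window_view(x, (kh, kw), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]
    n, c, ho, wo = windows.shape[:4]
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    return np.ascontiguousarray(cols), ho, wo


class Conv2d:
    """2-D convolution, odd kernel, 'same'-style padding k//2."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        if k % 2 == 0:
            raise ValueError("kernel size must be odd")
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, c_in, k, k))
        self.W = Param(w)
        self.b = Param(np.zeros(c_out))
        self.k, self.stride, self.pad = k, stride, k // 2
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=DTYPE)
        cols, ho, wo = _im2col(x, self.k, self.k, self.stride, self.pad)
        c_out = self.W.value.shape[0]
        wmat = self.W.value.reshape(c_out, -1)
        out = cols @ wmat.T + self.b.value
        n = x.shape[0]
        out = out.reshape(n, ho, wo, c_out).transpose(0, 3, 1, 2)
        if train:
            self._cache = (cols, x.shape, ho, wo)
        return np.ascontiguousarray(out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape, ho, wo = self._cache
        n, c_in, h, w = x_shape
        c_out = self.W.value.shape[0]
        dmat = np.ascontiguousarray(
            dout.transpose(0, 2, 3, 1).reshape(-1, c_out)
        )
        self.W.grad += (dmat.T @ cols).reshape(self.W.value.shape)
        self.b.grad += dmat.sum(axis=0)
        # data gradient, accumulated per kernel offset with strided adds
        # into an NHWC buffer (one GEMM per offset, no patch copies)
        k, s, p = self.k, self.stride, self.pad
        wv = self.W.value.reshape(c_out, c_in, k * k)
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c_in), dtype=DTYPE)
        for u in range(k):
            for v in range(k):
                tmp = (dmat @ wv[:, :, u * k + v]).reshape(n, ho, wo, c_in)
                dxp[:, u:u + s * ho:s, v:v + s * wo:s, :] += tmp
        if p:
            dxp = dxp[:, p:p + h, p:p + w, :]
        return np.ascontiguousarray(dxp.transpose(0, 3, 1, 2))


class BatchNorm2d:
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * inv_std[:, None, None]
        out = (self.gamma.value[:, None, None] * xhat
               + self.beta.value[:, None, None])
        if train:
            self._cache = (xhat.astype(DTYPE), inv_std.astype(DTYPE))
        return out.astype(DTYPE)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.value[:, None, None]
        sum_d = dxhat.sum(axis=(0, 2, 3), keepdims=True).transpose(1, 0, 2, 3)
        sum_dx = ((dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
                  .transpose(1, 0, 2, 3))
        dx = (inv_std[:, None, None] / m
              * (m * dxhat - sum_d.transpose(1, 0, 2, 3)
                 - xhat * sum_dx.transpose(1, 0, 2, 3)))
        return dx.astype(DTYPE)


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2x2:
    """2x2 max pooling, stride 2; odd sides are padded with -inf."""

    def __init__(self):
        self._cache = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        ph, pw = h % 2, w % 2
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)),
                       constant_values=-np.inf)
        ho, wo = x.shape[2] // 2, x.shape[3] // 2
        patches = (x.reshape(n, c, ho, 2, wo, 2)
                   .transpose(0, 1, 2, 4, 3, 5)
                   .reshape(n, c, ho, wo, 4))
        idx = patches.argmax(axis=-1)
        out = np.take_along_axis(patches, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, (n, c, h, w), ho, wo)
        return np.ascontiguousarray(out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, (n, c, h, w), ho, wo = self._cache
        dpatches = np.zeros((n, c, ho, wo, 4), dtype=DTYPE)
        np.put_along_axis(dpatches, idx[..., None], dout[..., None], axis=-1)
        dx = (dpatches.reshape(n, c, ho, wo, 2, 2)
              .transpose(0, 1, 2, 4, 3, 5)
              .reshape(n, c, ho * 2, wo * 2))
        return np.ascontiguousarray(dx[:, :, :h, :w])


class GlobalAvgPool:
    def __init__(self):
        self._shape = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(
            dout[:, :, None, None] / (h * w), (n, c, h, w)
        ).astype(DTYPE)


class Linear:
    def __init__(self, d_in: int, d_out: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / d_in), (d_out, d_in)))
        self.b = Param(np.zeros(d_out))
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.W.grad += dout.T @ self._x
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value


class ResidualBlock:
    """Two 3x3 conv+BN layers with a shortcut; projection (1x1 conv+BN,
    same stride) when the channel count or resolution changes."""

    def __init__(self, c_in: int, c_out: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.conv1 = Conv2d(c_in, c_out, 3, stride=stride, rng=rng)
        self.bn1 = BatchNorm2d(c_out)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c_out, c_out, 3, stride=1, rng=rng)
        self.bn2 = BatchNorm2d(c_out)
        self.relu_out = ReLU()
        if c_in != c_out or stride != 1:
            self.proj_conv = Conv2d(c_in, c_out, 1, stride=stride, rng=rng)
            self.proj_bn = BatchNorm2d(c_out)
        else:
            self.proj_conv = self.proj_bn = None

    def params(self):
        out = (self.conv1.params() + self.bn1.params()
               + self.conv2.params() + self.bn2.params())
        if self.proj_conv is not None:
            out += self.proj_conv.params() + self.proj_bn.params()
        return out

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        h = self.relu1.forward(
            self.bn1.forward(self.conv1.forward(x, train), train), train
        )
        h = self.bn2.forward(self.conv2.forward(h, train), train)
        if self.proj_conv is not None:
            sc = self.proj_bn.forward(self.proj_conv.forward(x, train), train)
        else:
            sc = x
        return self.relu_out.forward(h + sc, train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.relu_out.backward(dout)
        dmain = self.conv1.backward(
            self.bn1.backward(
                self.relu1.backward(
                    self.conv2.backward(self.bn2.backward(d))
                )
            )
        )
        if self.proj_conv is not None:
            dshort = self.proj_conv.backward(self.proj_bn.backward(d))
        else:
            dshort = d
        return dmain + dshort


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy and its gradient wrt logits."""
    probs = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = float(-np.log(probs[np.arange(n), labels] + 1e-12).mean())
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(DTYPE)


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.eps = lr, eps
        self.b1, self.b2 = betas
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
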