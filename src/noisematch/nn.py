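"""Minimal NumPy convolutional-network backend.

Implements exactly the layers the lesion detector needs — 2-D
convolution, strided transposed convolution, instance normalization,
ReLU, residual blocks — with hand-derived backward passes and an Adam
optimizer.  Tensors are float32 in NHWC layout (channels last), and
convolutions contract sliding-window views with ``einsum`` so the
inner loop runs as a single BLAS-bound contraction without an
intermediate im2col copy.  The data gradient of a (strided)
convolution is computed as a stride-1 convolution of the zero-dilated
output gradient with the spatially flipped, channel-transposed kernel.
Every layer's gradient is validated against finite differences in the
test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


class Param:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.ascontiguousarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)
        self.name = name


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(F32)


def _conv_windows(xp: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(N, Ho, Wo, C, k, k) sliding-window view of a padded NHWC array."""
    win = sliding_window_view(xp, (k, k), axis=(1, 2))
    return win[:, ::stride, ::stride]


class Conv2d(Layer):
    """k x k convolution, stride s, symmetric zero padding, NHWC."""

    def __init__(self, c_in, c_out, k=3, stride=1, pad=None, rng=None, name=""):
        rng = rng or np.random.default_rng(0)
        self.k, self.stride = k, stride
        self.pad = (k - 1) // 2 if pad is None else pad
        self.w = Param(he_init(rng, (c_out, c_in, k, k), c_in * k * k), name + ".w")
        self.b = Param(np.zeros(c_out, dtype=F32), name + ".b")
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        win = _conv_windows(xp, k, s)
        y = np.einsum("nhwcij,ocij->nhwo", win, self.w.value, optimize=True)
        self._cache = (x.shape, xp)
        return y + self.b.value

    def backward(self, dy):
        (n, h, w, c), xp = self._cache
        k, s, p = self.k, self.stride, self.pad
        win = _conv_windows(xp, k, s)
        self.w.grad += np.einsum("nhwcij,nhwo->ocij", win, dy, optimize=True)
        self.b.grad += dy.sum(axis=(0, 1, 2))
        # data gradient: dilate dy by the stride, pad so the output
        # matches the input size, correlate with the flipped kernel
        ho, wo = dy.shape[1], dy.shape[2]
        if s > 1:
            dil = np.zeros((n, s * (ho - 1) + 1, s * (wo - 1) + 1, dy.shape[3]), F32)
            dil[:, ::s, ::s] = dy
        else:
            dil = dy
        pad_t = k - 1 - p
        pad_b_h = h + k - 1 - dil.shape[1] - pad_t
        pad_b_w = w + k - 1 - dil.shape[2] - pad_t
        dilp = np.pad(dil, ((0, 0), (pad_t, pad_b_h), (pad_t, pad_b_w), (0, 0)))
        wflip = self.w.value[:, :, ::-1, ::-1]
        dwin = _conv_windows(dilp, k, 1)
        return np.einsum("nhwoij,ocij->nhwc", dwin, wflip, optimize=True)


class ConvTranspose2d(Layer):
    """2 x 2 transposed convolution with stride 2 (exact x2 upsampling)."""

    def __init__(self, c_in, c_out, rng=None, name=""):
        rng = rng or np.random.default_rng(0)
        self.w = Param(he_init(rng, (c_in, c_out, 2, 2), c_in), name + ".w")
        self.b = Param(np.zeros(c_out, dtype=F32), name + ".b")
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        self._x = x
        n, h, w, c = x.shape
        c_out = self.w.value.shape[1]
        t = np.einsum("nhwc,coij->nhwoij", x, self.w.value, optimize=True)
        y = np.empty((n, 2 * h, 2 * w, c_out), dtype=F32)
        for i in range(2):
            for j in range(2):
                y[:, i::2, j::2, :] = t[..., i, j]
        return y + self.b.value

    def backward(self, dy):
        x = self._x
        n, h, w, _ = x.shape
        dys = np.stack(
            [dy[:, i::2, j::2, :] for i in range(2) for j in range(2)], axis=-1
        ).reshape(n, h, w, dy.shape[3], 2, 2)
        self.w.grad += np.einsum("nhwc,nhwoij->coij", x, dys, optimize=True)
        self.b.grad += dy.sum(axis=(0, 1, 2))
        return np.einsum("nhwoij,coij->nhwc", dys, self.w.value, optimize=True)


class BatchNorm(Layer):
    """Batch normalization over (N, H, W) with running statistics.

    Training mode normalizes by batch moments and updates the running
    mean/variance; evaluation mode uses the frozen running statistics,
    so a distribution shift in the inputs is *not* re-normalized away
    at inference — essential when the point of the experiment is to
    measure sensitivity to such shifts.
    """

    def __init__(self, c, eps=1e-5, momentum=0.1, name=""):
        self.eps = eps
        self.momentum = momentum
        self.training = True
        self.g = Param(np.ones(c, dtype=F32), name + ".g")
        self.beta = Param(np.zeros(c, dtype=F32), name + ".b")
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self._cache = None

    def params(self):
        return [self.g, self.beta]

    def buffers(self) -> list[np.ndarray]:
        return [self.running_mean, self.running_var]

    def forward(self, x):
        if self.training:
            mu = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            m = self.momentum
            self.running_mean *= 1 - m
            self.running_mean += m * mu
            self.running_var *= 1 - m
            self.running_var += m * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(F32)
        xh = (x - mu) * inv
        self._cache = (xh, inv)
        return self.g.value * xh + self.beta.value

    def backward(self, dy):
        xh, inv = self._cache
        self.g.grad += (dy * xh).sum(axis=(0, 1, 2))
        self.beta.grad += dy.sum(axis=(0, 1, 2))
        dxh = dy * self.g.value
        if not self.training:
            return dxh * inv
        m1 = dxh.mean(axis=(0, 1, 2))
        m2 = (dxh * xh).mean(axis=(0, 1, 2))
        return inv * (dxh - m1 - xh * m2)


class InstanceNorm(Layer):
    """Per-sample, per-channel normalization over the spatial axes with
    a learned channel-wise affine transform."""

    def __init__(self, c, eps=1e-5, name=""):
        self.eps = eps
        self.g = Param(np.ones(c, dtype=F32), name + ".g")
        self.beta = Param(np.zeros(c, dtype=F32), name + ".b")
        self._cache = None

    def params(self):
        return [self.g, self.beta]

    def forward(self, x):
        mu = x.mean(axis=(1, 2), keepdims=True)
        var = x.var(axis=(1, 2), keepdims=True)
        inv = (1.0 / np.sqrt(var + self.eps)).astype(F32)
        xh = (x - mu) * inv
        self._cache = (xh, inv)
        return self.g.value * xh + self.beta.value

    def backward(self, dy):
        xh, inv = self._cache
        self.g.grad += (dy * xh).sum(axis=(0, 1, 2))
        self.beta.grad += dy.sum(axis=(0, 1, 2))
        dxh = dy * self.g.value
        m1 = dxh.mean(axis=(1, 2), keepdims=True)
        m2 = (dxh * xh).mean(axis=(1, 2), keepdims=True)
        return inv * (dxh - m1 - xh * m2)


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class ResBlock(Layer):
    """conv-BN-ReLU-conv-BN plus a (projected, possibly strided)
    shortcut, followed by ReLU."""

    def __init__(self, c_in, c_out, stride=1, rng=None, name=""):
        self.conv1 = Conv2d(c_in, c_out, 3, stride=stride, rng=rng, name=name + ".c1")
        self.in1 = BatchNorm(c_out, name=name + ".n1")
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c_out, c_out, 3, rng=rng, name=name + ".c2")
        self.in2 = BatchNorm(c_out, name=name + ".n2")
        self.proj = (
            Conv2d(c_in, c_out, 1, stride=stride, pad=0, rng=rng, name=name + ".sc")
            if (c_in != c_out or stride != 1)
            else None
        )
        self.relu_out = ReLU()

    def params(self):
        out = (
            self.conv1.params()
            + self.in1.params()
            + self.conv2.params()
            + self.in2.params()
        )
        if self.proj is not None:
            out += self.proj.params()
        return out

    def norms(self) -> list[BatchNorm]:
        return [self.in1, self.in2]

    def buffers(self) -> list[np.ndarray]:
        return self.in1.buffers() + self.in2.buffers()

    def forward(self, x):
        h = self.in2.forward(
            self.conv2.forward(
                self.relu1.forward(self.in1.forward(self.conv1.forward(x)))
            )
        )
        sc = self.proj.forward(x) if self.proj is not None else x
        return self.relu_out.forward(h + sc)

    def backward(self, dy):
        d = self.relu_out.backward(dy)
        dh = self.conv1.backward(
            self.in1.backward(
                self.relu1.backward(self.conv2.backward(self.in2.backward(d)))
            )
        )
        dsc = self.proj.backward(d) if self.proj is not None else d
        return dh + dsc


class Adam:
    """Adam with bias correction; one state slot per parameter."""

    def __init__(self, params: list[Param], lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def bce_with_logits(z: np.ndarray, g: np.ndarray) -> float:
    """Mean binary cross-entropy, numerically stable in the logits."""
    return float(np.mean(np.logaddexp(0.0, z) - z * g))


def get_state(params: list[Param]) -> list[np.ndarray]:
    return [p.value.copy() for p in params]


def set_state(params: list[Param], state: list[np.ndarray]) -> None:
    for p, s in zip(params, state):
        p.value[...] = s
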