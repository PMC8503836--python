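"""Minimal NumPy layers for 1D convolutional networks.

Everything here operates on channels-last arrays of shape ``(batch, length,
channels)`` and implements both the forward pass and reverse-mode gradients,
enough to build and train the EfficientNet-style feature extractor used for
sleep staging.  Conventions follow the common Keras ones: convolutions are
bias-free and followed by batch normalization (whose moving statistics are
counted as parameters of the layer), squeeze-and-excitation reductions are
computed from the block's input channel count, and "same" padding for strided
convolutions pads asymmetrically so the output length is ``ceil(L / stride)``.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Parameter",
    "Layer",
    "Sequential",
    "Conv1d",
    "DepthwiseConv1d",
    "BatchNorm1d",
    "Swish",
    "ReLU",
    "Dense",
    "GlobalAvgPool1d",
    "SqueezeExcite",
    "MBConv",
    "conv_output_length",
]


class Parameter:
    """A trainable array together with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    """Base class: forward/backward plus parameter bookkeeping."""

    def parameters(self) -> list[Parameter]:
        return []

    def buffers(self) -> list[np.ndarray]:
        """Non-trainable state (e.g. BN moving statistics)."""
        return []

    def n_params(self) -> int:
        """Total parameter count, moving statistics included."""
        return sum(p.size for p in self.parameters()) + sum(
            b.size for b in self.buffers()
        )

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x, train=False):
        return self.forward(x, train=train)


def conv_output_length(length: int, kernel: int, stride: int, padding: str) -> int:
    if padding == "valid":
        if length < kernel:
            raise ValueError(f"input length {length} shorter than kernel {kernel}")
        return (length - kernel) // stride + 1
    if padding == "same":
        return math.ceil(length / stride)
    raise ValueError(f"unknown padding {padding!r}")


def _same_pad(length: int, kernel: int, stride: int) -> tuple[int, int]:
    out = math.ceil(length / stride)
    pad = max((out - 1) * stride + kernel - length, 0)
    return pad // 2, pad - pad // 2


class Conv1d(Layer):
    """1D convolution, bias-free by default (BN follows in this architecture)."""

    def __init__(self, cin, cout, kernel, stride=1, padding="same", bias=False,
                 rng=None, name=""):
        rng = rng or np.random.default_rng(0)
        fan_in = kernel * cin
        w = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(kernel, cin, cout))
        self.w = Parameter(w, name=f"{name}.w")
        self.b = Parameter(np.zeros(cout), name=f"{name}.b") if bias else None
        self.kernel, self.stride, self.padding = kernel, stride, padding
        self._cache = None

    def parameters(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x, train=False):
        k, s = self.kernel, self.stride
        n, L, cin = x.shape
        if self.padding == "same":
            pl, pr = _same_pad(L, k, s)
            xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        else:
            pl = 0
            xp = x
        lout = conv_output_length(L, k, s, self.padding)
        view = sliding_window_view(xp, k, axis=1)[:, ::s][:, :lout]  # (n,lout,cin,k)
        out = np.einsum("nlck,kco->nlo", view, self.w.value, optimize=True)
        if self.b is not None:
            out += self.b.value
        if train:
            self._cache = (xp, view, L, pl, lout)
        return out

    def backward(self, dout):
        xp, view, L, pl, lout = self._cache
        k, s = self.kernel, self.stride
        self.w.grad += np.einsum("nlck,nlo->kco", view, dout, optimize=True)
        if self.b is not None:
            self.b.grad += dout.sum(axis=(0, 1))
        dxp = np.zeros_like(xp)
        wv = self.w.value
        for j in range(k):
            # positions j, j+s, ..., j+s*(lout-1) in the padded input
            dxp[:, j : j + s * lout : s, :] += dout @ wv[j].T
        return dxp[:, pl : pl + L, :]


class DepthwiseConv1d(Layer):
    """Per-channel (depthwise) convolution with 'same' padding."""

    def __init__(self, channels, kernel, stride=1, rng=None, name=""):
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, math.sqrt(2.0 / kernel), size=(kernel, channels))
        self.w = Parameter(w, name=f"{name}.w")
        self.kernel, self.stride = kernel, stride
        self._cache = None

    def parameters(self):
        return [self.w]

    def forward(self, x, train=False):
        k, s = self.kernel, self.stride
        n, L, c = x.shape
        pl, pr = _same_pad(L, k, s)
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        lout = conv_output_length(L, k, s, "same")
        view = sliding_window_view(xp, k, axis=1)[:, ::s][:, :lout]  # (n,lout,c,k)
        out = np.einsum("nlck,kc->nlc", view, self.w.value, optimize=True)
        if train:
            self._cache = (xp, view, L, pl, lout)
        return out

    def backward(self, dout):
        xp, view, L, pl, lout = self._cache
        k, s = self.kernel, self.stride
        self.w.grad += np.einsum("nlck,nlc->kc", view, dout, optimize=True)
        dxp = np.zeros_like(xp)
        wv = self.w.value
        for j in range(k):
            dxp[:, j : j + s * lout : s, :] += dout * wv[j]
        return dxp[:, pl : pl + L, :]


class BatchNorm1d(Layer):
    """Batch normalization over (batch, length); 4 stored arrays per channel."""

    def __init__(self, channels, momentum=0.9, eps=1e-3, name=""):
        self.gamma = Parameter(np.ones(channels), name=f"{name}.gamma")
        self.beta = Parameter(np.zeros(channels), name=f"{name}.beta")
        self.moving_mean = np.zeros(channels)
        self.moving_var = np.ones(channels)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def parameters(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return [self.moving_mean, self.moving_var]

    def forward(self, x, train=False):
        if train:
            mu = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.moving_mean *= self.momentum
            self.moving_mean += (1 - self.momentum) * mu
            self.moving_var *= self.momentum
            self.moving_var += (1 - self.momentum) * var
        else:
            mu, var = self.moving_mean, self.moving_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mu) / std
        if train:
            self._cache = (xhat, std)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dout):
        xhat, std = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=(0, 1))
        self.beta.grad += dout.sum(axis=(0, 1))
        dxhat = dout * self.gamma.value
        m = dxhat.mean(axis=(0, 1))
        mx = (dxhat * xhat).mean(axis=(0, 1))
        return (dxhat - m - xhat * mx) / std


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Swish(Layer):
    """x * sigmoid(x)."""

    def __init__(self):
        self._cache = None

    def forward(self, x, train=False):
        s = _sigmoid(x)
        if train:
            self._cache = (x, s)
        return x * s

    def backward(self, dout):
        x, s = self._cache
        return dout * (s + x * s * (1.0 - s))


class ReLU(Layer):
    def __init__(self):
        self._cache = None

    def forward(self, x, train=False):
        if train:
            self._cache = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dout):
        return dout * self._cache


class Dense(Layer):
    """Affine map on the trailing axis."""

    def __init__(self, din, dout, rng=None, name=""):
        rng = rng or np.random.default_rng(0)
        limit = math.sqrt(6.0 / (din + dout))
        self.w = Parameter(rng.uniform(-limit, limit, size=(din, dout)),
                           name=f"{name}.w")
        self.b = Parameter(np.zeros(dout), name=f"{name}.b")
        self._cache = None

    def parameters(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        if train:
            self._cache = x
        return x @ self.w.value + self.b.value

    def backward(self, dout):
        x = self._cache
        self.w.grad += np.tensordot(x, dout, axes=(tuple(range(x.ndim - 1)),) * 2) \
            if x.ndim > 2 else x.T @ dout
        self.b.grad += dout.reshape(-1, dout.shape[-1]).sum(axis=0)
        return dout @ self.w.value.T


class GlobalAvgPool1d(Layer):
    def __init__(self):
        self._len = None

    def forward(self, x, train=False):
        if train:
            self._len = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dout):
        L = self._len
        return np.repeat(dout[:, None, :], L, axis=1) / L


class SqueezeExcite(Layer):
    """Channel attention: pool -> reduce (swish) -> expand (sigmoid) -> scale.

    The reduction width comes from the *block input* channel count, following
    the EfficientNet convention, not from the expanded width being gated.
    """

    def __init__(self, channels, se_channels, rng=None, name=""):
        rng = rng or np.random.default_rng(0)
        self.reduce = Dense(channels, se_channels, rng=rng, name=f"{name}.reduce")
        self.expand = Dense(se_channels, channels, rng=rng, name=f"{name}.expand")
        self.act = Swish()
        self._cache = None

    def parameters(self):
        return self.reduce.parameters() + self.expand.parameters()

    def forward(self, x, train=False):
        z = x.mean(axis=1)  # (n, c)
        h = self.act.forward(self.reduce.forward(z, train), train)
        a = _sigmoid(self.expand.forward(h, train))
        if train:
            self._cache = (x, a)
        return x * a[:, None, :]

    def backward(self, dout):
        x, a = self._cache
        dx = dout * a[:, None, :]
        da = (dout * x).sum(axis=1)
        dh = self.expand.backward(da * a * (1.0 - a))
        dz = self.reduce.backward(self.act.backward(dh))
        L = x.shape[1]
        dx += dz[:, None, :] / L
        return dx


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def parameters(self):
        return [p for l in self.layers for p in l.parameters()]

    def buffers(self):
        return [b for l in self.layers for b in l.buffers()]

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout


class MBConv(Layer):
    """Mobile inverted residual bottleneck block (1D).

    expand 1x1 conv -> depthwise conv -> squeeze-and-excitation -> linear
    1x1 projection, each conv followed by BN.  The residual connection is
    present only when stride == 1 and cin == cout.
    """

    def __init__(self, cin, cout, kernel, stride, expand_ratio, se_ratio=0.25,
                 rng=None, name=""):
        rng = rng or np.random.default_rng(0)
        cexp = cin * expand_ratio
        self.use_expand = expand_ratio != 1
        seq = []
        if self.use_expand:
            seq += [Conv1d(cin, cexp, 1, 1, "same", rng=rng, name=f"{name}.exp"),
                    BatchNorm1d(cexp, name=f"{name}.exp_bn"), Swish()]
        seq += [DepthwiseConv1d(cexp, kernel, stride, rng=rng, name=f"{name}.dw"),
                BatchNorm1d(cexp, name=f"{name}.dw_bn"), Swish()]
        se_ch = max(1, int(cin * se_ratio))
        seq += [SqueezeExcite(cexp, se_ch, rng=rng, name=f"{name}.se")]
        seq += [Conv1d(cexp, cout, 1, 1, "same", rng=rng, name=f"{name}.proj"),
                BatchNorm1d(cout, name=f"{name}.proj_bn")]
        self.body = Sequential(seq)
        self.skip = stride == 1 and cin == cout

    def parameters(self):
        return self.body.parameters()

    def buffers(self):
        return self.body.buffers()

    def forward(self, x, train=False):
        out = self.body.forward(x, train=train)
        if self.skip:
            out = out + x
        return out

    def backward(self, dout):
        dx = self.body.backward(dout)
        if self.skip:
            dx = dx + dout
        return dx
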