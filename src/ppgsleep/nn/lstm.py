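"""LSTM and bidirectional LSTM over a single feature sequence.

The sequence here is a night of per-epoch CNN features, shape ``(T, D)``;
batching is one night at a time.  Parameterization is the standard combined
one — a single weight matrix of shape ``(D + H, 4H)`` and one bias of shape
``(4H,)`` per direction — so a bidirectional layer holds
``2 * 4 * ((D + H) * H + H)`` parameters.
"""

from __future__ import annotations

import math

import numpy as np

from .core import Layer, Parameter, _sigmoid

__all__ = ["LSTM", "BiLSTM"]


class LSTM(Layer):
    """Single-direction LSTM; gate order (input, forget, cell, output)."""

    def __init__(self, input_size, hidden_size, rng=None, name=""):
        rng = rng or np.random.default_rng(0)
        d, h = input_size, hidden_size
        limit = math.sqrt(6.0 / (d + h + 4 * h))
        self.w = Parameter(rng.uniform(-limit, limit, size=(d + h, 4 * h)),
                           name=f"{name}.w")
        b = np.zeros(4 * h)
        b[h : 2 * h] = 1.0  # forget-gate bias
        self.b = Parameter(b, name=f"{name}.b")
        self.input_size, self.hidden_size = d, h
        self._cache = None

    def parameters(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        T, d = x.shape
        h = self.hidden_size
        W, b = self.w.value, self.b.value
        hs = np.zeros((T, h))
        cache = [] if train else None
        h_prev = np.zeros(h)
        c_prev = np.zeros(h)
        for t in range(T):
            xh = np.concatenate([x[t], h_prev])
            z = xh @ W + b
            i = _sigmoid(z[:h])
            f = _sigmoid(z[h : 2 * h])
            g = np.tanh(z[2 * h : 3 * h])
            o = _sigmoid(z[3 * h :])
            c = f * c_prev + i * g
            tc = np.tanh(c)
            hs[t] = o * tc
            if train:
                cache.append((xh, i, f, g, o, c_prev, tc))
            h_prev, c_prev = hs[t], c
        if train:
            self._cache = cache
        return hs

    def backward(self, dout):
        cache = self._cache
        T = len(cache)
        h = self.hidden_size
        d = self.input_size
        W = self.w.value
        dx = np.zeros((T, d))
        dh_next = np.zeros(h)
        dc_next = np.zeros(h)
        for t in range(T - 1, -1, -1):
            xh, i, f, g, o, c_prev, tc = cache[t]
            dh = dout[t] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            di, df, dg = dc * g, dc * c_prev, dc * i
            dc_next = dc * f
            dz = np.concatenate([
                di * i * (1 - i),
                df * f * (1 - f),
                dg * (1 - g * g),
                do * o * (1 - o),
            ])
            self.w.grad += np.outer(xh, dz)
            self.b.grad += dz
            dxh = W @ dz
            dx[t] = dxh[:d]
            dh_next = dxh[d:]
        return dx


class BiLSTM(Layer):
    """Concatenation of a forward and a time-reversed LSTM pass."""

    def __init__(self, input_size, hidden_size, rng=None, name=""):
        rng = rng or np.random.default_rng(0)
        self.fwd = LSTM(input_size, hidden_size, rng=rng, name=f"{name}.fwd")
        self.bwd = LSTM(input_size, hidden_size, rng=rng, name=f"{name}.bwd")
        self.hidden_size = hidden_size

    def parameters(self):
        return self.fwd.parameters() + self.bwd.parameters()

    def forward(self, x, train=False):
        hf = self.fwd.forward(x, train=train)
        hb = self.bwd.forward(x[::-1], train=train)[::-1]
        return np.concatenate([hf, hb], axis=1)

    def backward(self, dout):
        h = self.hidden_size
        dxf = self.fwd.backward(dout[:, :h])
        dxb = self.bwd.backward(dout[::-1, h:])[::-1]
        return dxf + dxb
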