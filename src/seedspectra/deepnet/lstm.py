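"""Stacked LSTM over the spectral sequence, with numba-compiled recurrence.

The input projections ``x @ Wx + b`` for all positions are computed as one
large BLAS matmul outside the jitted kernels; the kernels only carry the
per-step recurrent matmul and gate nonlinearities.  Gates are ordered
``(input, forget, cell, output)`` along the ``4H`` axis.  Initial hidden and
cell states are zero.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .layers import Layer, Param

__all__ = ["LSTMStack"]


@njit(cache=True)
def _lstm_fwd(zbar: np.ndarray, wh: np.ndarray):
    """zbar: (T, N, 4H) pre-computed input projections; wh: (H, 4H)."""
    t_len, n, h4 = zbar.shape
    h_dim = h4 // 4
    gates = np.empty_like(zbar)
    h_all = np.empty((t_len, n, h_dim), zbar.dtype)
    c_all = np.empty((t_len, n, h_dim), zbar.dtype)
    h_prev = np.zeros((n, h_dim), zbar.dtype)
    c_prev = np.zeros((n, h_dim), zbar.dtype)
    one = zbar.dtype.type(1.0)  # keeps float32 math in float32 under numba
    for t in range(t_len):
        z = zbar[t] + np.dot(h_prev, wh)
        i_g = one / (one + np.exp(-z[:, :h_dim]))
        f_g = one / (one + np.exp(-z[:, h_dim : 2 * h_dim]))
        g_g = np.tanh(z[:, 2 * h_dim : 3 * h_dim])
        o_g = one / (one + np.exp(-z[:, 3 * h_dim :]))
        c_new = f_g * c_prev + i_g * g_g
        h_new = o_g * np.tanh(c_new)
        gates[t, :, :h_dim] = i_g
        gates[t, :, h_dim : 2 * h_dim] = f_g
        gates[t, :, 2 * h_dim : 3 * h_dim] = g_g
        gates[t, :, 3 * h_dim :] = o_g
        c_all[t] = c_new
        h_all[t] = h_new
        h_prev, c_prev = h_new, c_new
    return h_all, c_all, gates


@njit(cache=True)
def _lstm_bwd(dh_seq: np.ndarray, gates: np.ndarray, c_all: np.ndarray,
              h_all: np.ndarray, wh: np.ndarray):
    """Backward through time; returns (dzbar, dWh)."""
    t_len, n, h_dim = dh_seq.shape
    dzbar = np.empty((t_len, n, 4 * h_dim), dh_seq.dtype)
    dwh = np.zeros_like(wh)
    wh_t = np.ascontiguousarray(wh.T)
    dh_next = np.zeros((n, h_dim), dh_seq.dtype)
    dc_next = np.zeros((n, h_dim), dh_seq.dtype)
    zeros = np.zeros((n, h_dim), dh_seq.dtype)
    one = dh_seq.dtype.type(1.0)
    for t in range(t_len - 1, -1, -1):
        i_g = gates[t, :, :h_dim]
        f_g = gates[t, :, h_dim : 2 * h_dim]
        g_g = gates[t, :, 2 * h_dim : 3 * h_dim]
        o_g = gates[t, :, 3 * h_dim :]
        tc = np.tanh(c_all[t])
        dh = dh_seq[t] + dh_next
        do = dh * tc
        dc = dc_next + dh * o_g * (one - tc * tc)
        c_prev = c_all[t - 1] if t > 0 else zeros
        h_prev = h_all[t - 1] if t > 0 else zeros
        di = dc * g_g
        df = dc * c_prev
        dg = dc * i_g
        dc_next = dc * f_g
        dz = dzbar[t]
        dz[:, :h_dim] = di * i_g * (one - i_g)
        dz[:, h_dim : 2 * h_dim] = df * f_g * (one - f_g)
        dz[:, 2 * h_dim : 3 * h_dim] = dg * (one - g_g * g_g)
        dz[:, 3 * h_dim :] = do * o_g * (one - o_g)
        dz_c = np.ascontiguousarray(dz)
        dwh += np.dot(np.ascontiguousarray(h_prev.T), dz_c)
        dh_next = np.dot(dz_c, wh_t)
    return dzbar, dwh


class _LSTMLayer:
    """One recurrent layer: parameters plus cached forward state."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator, dtype: np.dtype, idx: int):
        bound = 1.0 / np.sqrt(hidden)
        self.wx = Param(f"lstm{idx}.wx", rng.uniform(-bound, bound, (d_in, 4 * hidden)).astype(dtype))
        self.wh = Param(f"lstm{idx}.wh", rng.uniform(-bound, bound, (hidden, 4 * hidden)).astype(dtype))
        self.b = Param(f"lstm{idx}.b", np.zeros(4 * hidden, dtype=dtype))
        # Forget-gate bias of 1 is the standard trick for stable early training.
        self.b.value[hidden : 2 * hidden] = 1.0
        self.hidden = hidden

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, t, d = x.shape
        self._x = x
        zbar = (x.reshape(n * t, d) @ self.wx.value + self.b.value).reshape(n, t, 4 * self.hidden)
        zbar = np.ascontiguousarray(zbar.transpose(1, 0, 2))
        h_all, c_all, gates = _lstm_fwd(zbar, self.wh.value)
        self._cache = (h_all, c_all, gates)
        return np.ascontiguousarray(h_all.transpose(1, 0, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        h_all, c_all, gates = self._cache
        dh_seq = np.ascontiguousarray(dy.transpose(1, 0, 2))
        dzbar, dwh = _lstm_bwd(dh_seq, gates, c_all, h_all, self.wh.value)
        self.wh.grad += dwh
        x = self._x
        n, t, d = x.shape
        dz_flat = np.ascontiguousarray(dzbar.transpose(1, 0, 2)).reshape(n * t, 4 * self.hidden)
        self.wx.grad += x.reshape(n * t, d).T @ dz_flat
        self.b.grad += dz_flat.sum(axis=0)
        return (dz_flat @ self.wx.value.T).reshape(n, t, d)


class LSTMStack(Layer):
    """``n_layers`` LSTMs applied in sequence over (N, T, C) -> (N, T, H)."""

    def __init__(self, d_in: int, hidden: int, n_layers: int,
                 rng: np.random.Generator, dtype: np.dtype):
        self.layers = [
            _LSTMLayer(d_in if i == 0 else hidden, hidden, rng, dtype, i)
            for i in range(n_layers)
        ]

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in (layer.wx, layer.wh, layer.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy
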