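"""Hand-written neural layers with explicit forward/backward passes.

Every layer caches what its backward pass needs on ``forward`` and exposes
its trainable arrays as :class:`Param` objects so the optimizer can walk the
whole model uniformly.  Shapes follow the sequence convention ``(N, T, C)``
(batch, positions along the wavelength axis, feature channels) except for
the convolution front end which uses ``(N, C, L)``.
"""

from __future__ import annotations

import numpy as np

from ..errors import ShapeError
from .config import EcaSpec

__all__ = [
    "Param",
    "Layer",
    "Conv1d",
    "ReLU",
    "MaxPool1d",
    "ToSequence",
    "MultiHeadSelfAttention",
    "ECA",
    "GlobalAveragePool",
    "Dense",
    "softmax",
    "eca_forward",
]


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Conv1d(Layer):
    """1-D convolution along the band axis, stride 1, symmetric zero padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 padding: int, rng: np.random.Generator, dtype: np.dtype):
        self.k = kernel_size
        self.padding = padding
        scale = np.sqrt(2.0 / (in_channels * kernel_size))
        self.w = Param("conv.w", (rng.normal(0.0, scale, (out_channels, in_channels, kernel_size))).astype(dtype))
        self.b = Param("conv.b", np.zeros(out_channels, dtype=dtype))

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, l = x.shape
        p = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        l_out = l + 2 * p - self.k + 1
        self._xp, self._l_out = xp, l_out
        w = self.w.value
        y = np.tile(self.b.value[None, :, None], (n, 1, l_out)).astype(x.dtype)
        for kk in range(self.k):
            y += np.einsum("ncl,oc->nol", xp[:, :, kk : kk + l_out], w[:, :, kk])
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp, l_out = self._xp, self._l_out
        w = self.w.value
        self.b.grad += dy.sum(axis=(0, 2))
        dxp = np.zeros_like(xp)
        for kk in range(self.k):
            self.w.grad[:, :, kk] += np.einsum("nol,ncl->oc", dy, xp[:, :, kk : kk + l_out])
            dxp[:, :, kk : kk + l_out] += np.einsum("nol,oc->ncl", dy, w[:, :, kk])
        p = self.padding
        return dxp[:, :, p : dxp.shape[2] - p] if p else dxp


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool1d(Layer):
    """Non-overlapping max pooling along the last axis; trims the remainder."""

    def __init__(self, width: int):
        self.width = width

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.width == 1:
            self._passthrough = True
            return x
        self._passthrough = False
        n, c, l = x.shape
        t = l // self.width
        xr = x[:, :, : t * self.width].reshape(n, c, t, self.width)
        self._argmax = xr.argmax(axis=3)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._argmax[..., None], axis=3)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._passthrough:
            return dy
        n, c, l = self._in_shape
        t = dy.shape[2]
        dxr = np.zeros((n, c, t, self.width), dtype=dy.dtype)
        np.put_along_axis(dxr, self._argmax[..., None], dy[..., None], axis=3)
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        dx[:, :, : t * self.width] = dxr.reshape(n, c, t * self.width)
        return dx


class ToSequence(Layer):
    """(N, C, T) feature block -> (N, T, C) sequence."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.ascontiguousarray(x.transpose(0, 2, 1))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.ascontiguousarray(dy.transpose(0, 2, 1))


class MultiHeadSelfAttention(Layer):
    """Scaled dot-product self-attention with ``h`` heads over (N, T, d)."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator, dtype: np.dtype):
        if d_model % n_heads:
            raise ShapeError("d_model must be divisible by n_heads")
        self.d = d_model
        self.h = n_heads
        self.dh = d_model // n_heads
        bound = np.sqrt(6.0 / (2 * d_model))  # Xavier-uniform for square maps
        def mk(name):
            return Param(name, rng.uniform(-bound, bound, (d_model, d_model)).astype(dtype))
        self.wq, self.wk, self.wv, self.wo = mk("attn.wq"), mk("attn.wk"), mk("attn.wv"), mk("attn.wo")
        self.bq = Param("attn.bq", np.zeros(d_model, dtype=dtype))
        self.bk = Param("attn.bk", np.zeros(d_model, dtype=dtype))
        self.bv = Param("attn.bv", np.zeros(d_model, dtype=dtype))
        self.bo = Param("attn.bo", np.zeros(d_model, dtype=dtype))

    def params(self) -> list[Param]:
        return [self.wq, self.wk, self.wv, self.wo, self.bq, self.bk, self.bv, self.bo]

    def _split(self, x: np.ndarray) -> np.ndarray:
        n, t, _ = x.shape
        return x.reshape(n, t, self.h, self.dh).transpose(0, 2, 1, 3)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        n, h, t, dh = x.shape
        return np.ascontiguousarray(x.transpose(0, 2, 1, 3)).reshape(n, t, h * dh)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        q = self._split(x @ self.wq.value + self.bq.value)
        k = self._split(x @ self.wk.value + self.bk.value)
        v = self._split(x @ self.wv.value + self.bv.value)
        scale = 1.0 / np.sqrt(self.dh)
        scores = (q @ k.transpose(0, 1, 3, 2)) * scale
        attn = softmax(scores, axis=-1)
        z = self._merge(attn @ v)
        self._cache = (q, k, v, attn, z, scale)
        return z @ self.wo.value + self.bo.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        q, k, v, attn, z, scale = self._cache
        n, t, d = x.shape
        dy2 = dy.reshape(-1, d)
        self.wo.grad += z.reshape(-1, d).T @ dy2
        self.bo.grad += dy2.sum(axis=0)
        dz = self._split(dy @ self.wo.value.T)
        dattn = dz @ v.transpose(0, 1, 3, 2)
        dv = attn.transpose(0, 1, 3, 2) @ dz
        dscores = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
        dscores *= scale
        dq = dscores @ k
        dk = dscores.transpose(0, 1, 3, 2) @ q
        dx = np.zeros_like(x)
        x2 = x.reshape(-1, d)
        for dmat, w, b in ((dq, self.wq, self.bq), (dk, self.wk, self.bk), (dv, self.wv, self.bv)):
            dflat = self._merge(dmat).reshape(-1, d)
            w.grad += x2.T @ dflat
            b.grad += dflat.sum(axis=0)
            dx += (dflat @ w.value.T).reshape(n, t, d)
        return dx


class ECA(Layer):
    """Efficient channel attention over the feature channels of (N, T, C).

    Global average pool over positions -> zero-padded 1-D convolution of
    adaptive odd width k across the channel axis -> sigmoid gate -> rescale
    each channel of the input.  Shape preserving.
    """

    def __init__(self, spec: EcaSpec, dtype: np.dtype):
        self.spec = spec
        self.k = spec.kernel_k
        # Identity-leaning init: small kernel so gates start near sigmoid(0)=0.5.
        self.w = Param("eca.w", np.zeros(self.k, dtype=dtype))

    def params(self) -> list[Param]:
        return [self.w]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[2] != self.spec.channels:
            raise ShapeError(f"expected {self.spec.channels} channels, got {x.shape[2]}")
        n, t, c = x.shape
        s = x.mean(axis=1)
        pad = self.k // 2
        sp = np.pad(s, ((0, 0), (pad, pad)))
        u = np.zeros_like(s)
        for j in range(self.k):
            u += self.w.value[j] * sp[:, j : j + c]
        g = 1.0 / (1.0 + np.exp(-u))
        self._cache = (x, sp, g)
        return x * g[:, None, :]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, sp, g = self._cache
        n, t, c = x.shape
        pad = self.k // 2
        dg = (dy * x).sum(axis=1)
        dx = dy * g[:, None, :]
        du = dg * g * (1.0 - g)
        dsp = np.zeros_like(sp)
        for j in range(self.k):
            self.w.grad[j] += float((du * sp[:, j : j + c]).sum())
            dsp[:, j : j + c] += self.w.value[j] * du
        ds = dsp[:, pad : pad + c] if pad else dsp
        dx += ds[:, None, :] / t
        return dx


class GlobalAveragePool(Layer):
    """(N, T, C) -> (N, C) mean over positions."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._t = x.shape[1]
        self._dtype = x.dtype
        return x.mean(axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(dy[:, None, :] / self._t, self._t, axis=1).astype(self._dtype)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, dtype: np.dtype):
        bound = np.sqrt(6.0 / (d_in + d_out))
        self.w = Param("dense.w", rng.uniform(-bound, bound, (d_in, d_out)).astype(dtype))
        self.b = Param("dense.b", np.zeros(d_out, dtype=dtype))

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T


def eca_forward(features: np.ndarray, spec: EcaSpec) -> np.ndarray:
    """Functional ECA with the current (zero) kernel semantics for inspection.

    Applies a freshly initialised ECA gate to ``features`` of shape
    ``(N, T, C)`` and returns the same-shape re-weighted block.
    """
    layer = ECA(spec, dtype=np.asarray(features).dtype)
    return layer.forward(np.asarray(features))
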