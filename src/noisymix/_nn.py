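"""Minimal NumPy neural-network core: layers with explicit backprop and SGD.

Everything runs in float32 and routes the heavy lifting through BLAS matmuls
(im2col convolutions), which is fast enough for the desk-scale CNNs this
package trains.  Layers cache what their backward pass needs; ``backward``
must be called with the same batch that was last forwarded.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


class Param:
    """A learnable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(F32)


class Conv2d:
    """3x3-style convolution via im2col, stride 1, symmetric zero padding."""

    def __init__(self, in_ch: int, out_ch: int, ksize: int = 3, pad: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch, self.ksize, self.pad = in_ch, out_ch, ksize, pad
        fan_in = in_ch * ksize * ksize
        self.W = Param(he_init(rng, (out_ch, in_ch, ksize, ksize), fan_in))
        self.b = Param(np.zeros(out_ch, dtype=F32))
        self._cols = None
        self._xshape = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, p = self.ksize, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (n,c,ho,wo,k,k)
        ho, wo = win.shape[2], win.shape[3]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))
        cols = cols.reshape(n * ho * wo, c * k * k)
        wmat = self.W.value.reshape(self.out_ch, -1)
        out = cols @ wmat.T + self.b.value
        self._cols, self._xshape, self._hw = cols, x.shape, (ho, wo)
        return out.reshape(n, ho, wo, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._xshape
        k, p = self.ksize, self.pad
        ho, wo = self._hw
        dmat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(-1, self.out_ch)
        wmat = self.W.value.reshape(self.out_ch, -1)
        self.W.grad += (dmat.T @ self._cols).reshape(self.W.value.shape)
        self.b.grad += dmat.sum(axis=0)
        dcols = (dmat @ wmat).reshape(n, ho, wo, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=F32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + ho, j:j + wo] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        self._cols = None
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class ReLU:
    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, F32(0.0))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, F32(0.0))


class MaxPool2:
    """2x2 max pooling, stride 2; spatial dims must be even."""

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = np.ascontiguousarray(xr).reshape(n, c, h // 2, w // 2, 4)
        self._arg = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dr = np.zeros((n, c, h // 2, w // 2, 4), dtype=F32)
        np.put_along_axis(dr, self._arg[..., None], dout[..., None], axis=-1)
        dr = dr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(dr).reshape(n, c, h, w)


class Dropout:
    """Inverted dropout; active only when a train-mode rng is supplied."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0,1), got {p}")
        self.p = p
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        if rng is None or self.p == 0.0:
            self._mask = None
            return x
        keep = F32(1.0 - self.p)
        self._mask = (rng.random(x.shape) >= self.p).astype(F32) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None,
                 zero_init: bool = False):
        rng = rng or np.random.default_rng(0)
        if zero_init:
            w = np.zeros((n_in, n_out), dtype=F32)
        else:
            w = he_init(rng, (n_in, n_out), n_in)
        self.W = Param(w)
        self.b = Param(np.zeros(n_out, dtype=F32))

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


def global_avg_pool(x: np.ndarray) -> np.ndarray:
    """(n,c,h,w) -> (n,c) mean over the spatial grid."""
    return x.mean(axis=(2, 3))


def global_avg_pool_backward(dout: np.ndarray, spatial: tuple[int, int]) -> np.ndarray:
    h, w = spatial
    scale = F32(1.0 / (h * w))
    return np.broadcast_to((dout * scale)[:, :, None, None],
                           dout.shape + spatial).astype(F32)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out.astype(z.dtype) if z.dtype == F32 else out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray):
    """Mean binary cross-entropy over all entries; returns (loss, dloss/dlogits)."""
    z = logits.astype(np.float64)
    y = targets.astype(np.float64)
    loss = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    n = z.size
    grad = ((sigmoid(z) - y) / n).astype(F32)
    return float(loss.mean()), grad


class SGD:
    """SGD with classical momentum and decoupled-from-nothing L2 weight decay
    (decay is added to the gradient, matching the standard deep-learning recipe)."""

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._vel = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        for p, v in zip(self.params, self._vel):
            g = p.grad
            if self.weight_decay:
                g = g + F32(self.weight_decay) * p.value
            v *= F32(self.momentum)
            v -= F32(self.lr) * g
            p.value += v


def bilinear_resize_matrix(n_in: int, n_out: int) -> np.ndarray:
    """1-D bilinear interpolation operator (n_out x n_in), half-pixel centers.

    Upsampling a 2-D map is then ``P_h @ m @ P_w.T`` — a pair of small matmuls.
    """
    out = np.zeros((n_out, n_in), dtype=np.float64)
    scale = n_in / n_out
    for o in range(n_out):
        src = (o + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        lo = int(np.floor(src))
        hi = min(lo + 1, n_in - 1)
        frac = src - lo
        out[o, lo] += 1.0 - frac
        out[o, hi] += frac
    return out
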