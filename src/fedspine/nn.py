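"""Minimal numpy neural-network primitives with hand-written backprop.

Only what the landmark localizer needs: 2-D convolution (odd kernels,
same-padding, stride 1 or 2), ReLU, nearest-neighbour ×2 upsampling, a
per-channel spatial softmax, and an Adam optimizer over named parameter
dictionaries.  Forward functions return a cache consumed by the matching
backward function.  Everything is deterministic given the input arrays.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np


class ParamVector:
    """Ordered, named view of all trainable parameters.

    The unit of federated exchange: two ``ParamVector`` instances built from
    the same model configuration are elementwise combinable.
    """

    def __init__(self, arrays: "OrderedDict[str, np.ndarray] | dict[str, np.ndarray]"):
        self.arrays: "OrderedDict[str, np.ndarray]" = OrderedDict(arrays)

    @property
    def total_count(self) -> int:
        return int(sum(a.size for a in self.arrays.values()))

    def copy(self) -> "ParamVector":
        return ParamVector(OrderedDict((k, v.copy()) for k, v in self.arrays.items()))

    def keys(self):
        return self.arrays.keys()

    def items(self):
        return self.arrays.items()

    def __getitem__(self, key: str) -> np.ndarray:
        return self.arrays[key]

    def _binary(self, other, op) -> "ParamVector":
        if list(other.arrays) != list(self.arrays):
            raise ValueError("parameter vectors have different layouts")
        return ParamVector(
            OrderedDict((k, op(v, other.arrays[k])) for k, v in self.arrays.items())
        )

    def __add__(self, other: "ParamVector") -> "ParamVector":
        return self._binary(other, np.add)

    def __sub__(self, other: "ParamVector") -> "ParamVector":
        return self._binary(other, np.subtract)

    def scale(self, factor: float) -> "ParamVector":
        return ParamVector(
            OrderedDict((k, v * factor) for k, v in self.arrays.items())
        )

    def sq_norm(self) -> float:
        return float(sum(np.sum(v.astype(np.float64) ** 2) for v in self.arrays.values()))

    def allclose(self, other: "ParamVector", rtol=1e-7, atol=0.0) -> bool:
        return all(
            np.allclose(v, other.arrays[k], rtol=rtol, atol=atol)
            for k, v in self.arrays.items()
        )

    def equal(self, other: "ParamVector") -> bool:
        return all(np.array_equal(v, other.arrays[k]) for k, v in self.arrays.items())


# --------------------------------------------------------------------------
# Layers
# --------------------------------------------------------------------------


def conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int = 1):
    """Same-padded 2-D convolution; x (N,C,H,W), w (F,C,kh,kw)."""
    n, c, h, wd = x.shape
    f, _, kh, kw = w.shape
    ph, pw = (kh - 1) // 2, (kw - 1) // 2
    ho = (h + 2 * ph - kh) // stride + 1
    wo = (wd + 2 * pw - kw) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    out = np.empty((n, f, ho, wo), dtype=x.dtype)
    out[:] = b[None, :, None, None]
    for di in range(kh):
        for dj in range(kw):
            xs = xp[:, :, di : di + stride * ho : stride, dj : dj + stride * wo : stride]
            out += np.einsum("nchw,fc->nfhw", xs, w[:, :, di, dj], optimize=True)
    cache = (xp, w, stride, (ph, pw), x.shape, (ho, wo))
    return out, cache


def conv2d_backward(dout: np.ndarray, cache):
    xp, w, stride, (ph, pw), x_shape, (ho, wo) = cache
    f, c, kh, kw = w.shape
    dw = np.zeros_like(w)
    dxp = np.zeros_like(xp)
    for di in range(kh):
        for dj in range(kw):
            sl = np.s_[:, :, di : di + stride * ho : stride, dj : dj + stride * wo : stride]
            dw[:, :, di, dj] = np.einsum("nfhw,nchw->fc", dout, xp[sl], optimize=True)
            dxp[sl] += np.einsum("nfhw,fc->nchw", dout, w[:, :, di, dj], optimize=True)
    db = dout.sum(axis=(0, 2, 3))
    n, cc, h, wd = x_shape
    dx = dxp[:, :, ph : ph + h, pw : pw + wd]
    return dx, dw, db


def relu(x: np.ndarray):
    mask = x > 0
    return x * mask, mask


def relu_backward(dout: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return dout * mask


def upsample2(x: np.ndarray) -> np.ndarray:
    """Nearest-neighbour ×2 upsampling."""
    return x.repeat(2, axis=2).repeat(2, axis=3)


def upsample2_backward(dout: np.ndarray) -> np.ndarray:
    n, c, h, w = dout.shape
    return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def spatial_softmax(raw: np.ndarray) -> np.ndarray:
    """Per-landmark softmax over the spatial dimensions; raw (N,L,h,w)."""
    z = raw - raw.max(axis=(2, 3), keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=(2, 3), keepdims=True)


def spatial_softmax_backward(dhm: np.ndarray, hm: np.ndarray) -> np.ndarray:
    inner = (dhm * hm).sum(axis=(2, 3), keepdims=True)
    return hm * (dhm - inner)


# --------------------------------------------------------------------------
# Optimizer
# --------------------------------------------------------------------------


class Adam:
    """Adam over a named parameter dictionary (betas 0.9/0.999, eps 1e-8)."""

    def __init__(self, params: ParamVector, beta1=0.9, beta2=0.999, eps=1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: ParamVector, grads: ParamVector, lr: float) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            p -= (lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)).astype(
                p.dtype
            )
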