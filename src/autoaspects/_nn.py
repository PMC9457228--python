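"""Minimal NumPy layer framework for the 2.5-D stroke classifier.

Implements exactly the layer types the network needs — per-slice 2-D
convolution expressed as a 3-D convolution with a 3x3x1 kernel, adaptive
3-D max pooling, dense (1x1xK / HxWx1) convolutions, ReLU, dropout — each
with an explicit backward pass, plus an Adam optimizer.  Arrays are laid
out as ``(N, C, H, W, Z)`` with Z the through-plane (slice) axis.

All randomness flows through ``numpy.random.Generator`` objects supplied by
the caller, so training is bit-reproducible under a fixed seed on one
platform with a fixed BLAS.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "ConvSlice2D",
    "ReLU",
    "AdaptiveMaxPool3D",
    "DepthConv",
    "DenseConv",
    "Dropout",
    "Linear",
    "GlobalSliceMaxPool",
    "Adam",
    "sigmoid",
    "bce_with_logits",
    "kaiming_uniform",
]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str):
        self.value = np.ascontiguousarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0

    @property
    def size(self) -> int:
        return self.value.size


def kaiming_uniform(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient w.r.t. the logits."""
    logits = np.asarray(logits, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    # log(1+e^x) computed stably
    loss = np.mean(np.maximum(logits, 0) - logits * targets + np.log1p(np.exp(-np.abs(logits))))
    grad = (sigmoid(logits) - targets) / logits.size
    return float(loss), grad


class ConvSlice2D:
    """3-D convolution with a ``kh x kw x 1`` kernel: an in-plane 2-D
    convolution applied independently to every slice.

    Stride acts in-plane only; through-plane stride is 1 and through-plane
    padding 0, so the slice count is preserved.
    """

    def __init__(self, c_in: int, c_out: int, *, kernel: int = 3, stride: int = 1,
                 pad: int = 1, rng: np.random.Generator | None = None, name: str = "conv"):
        self.c_in, self.c_out = c_in, c_out
        self.k, self.stride, self.pad = kernel, stride, pad
        fan_in = c_in * kernel * kernel
        rng = rng or np.random.default_rng(0)
        self.W = Param(kaiming_uniform(rng, (c_out, c_in * kernel * kernel), fan_in), f"{name}.W")
        self.b = Param(np.zeros(c_out), f"{name}.b")
        self._cache = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        N, C, H, W, Z = x.shape
        k, s, p = self.k, self.stride, self.pad
        xt = x.transpose(0, 4, 1, 2, 3).reshape(N * Z, C, H, W)
        xp = np.pad(xt, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]                       # (NZ, C, OH, OW, k, k)
        OH, OW = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N * Z, OH * OW, C * k * k)
        y = cols @ self.W.value.T + self.b.value        # (NZ, OH*OW, c_out)
        y = y.reshape(N, Z, OH, OW, self.c_out).transpose(0, 4, 2, 3, 1)
        self._cache = (cols, (N, C, H, W, Z, OH, OW))
        return np.ascontiguousarray(y)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        cols, (N, C, H, W, Z, OH, OW) = self._cache
        k, s, p = self.k, self.stride, self.pad
        g = gy.transpose(0, 4, 2, 3, 1).reshape(N * Z, OH * OW, self.c_out)
        self.W.grad += np.einsum("bpo,bpc->oc", g, cols)
        self.b.grad += g.sum(axis=(0, 1))
        dcols = g @ self.W.value                        # (NZ, OH*OW, C*k*k)
        dwin = dcols.reshape(N * Z, OH, OW, C, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((N * Z, C, H + 2 * p, W + 2 * p))
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki:ki + s * OH:s, kj:kj + s * OW:s] += dwin[:, :, :, :, ki, kj]
        dxt = dxp[:, :, p:p + H, p:p + W] if p else dxp
        return dxt.reshape(N, Z, C, H, W).transpose(0, 2, 3, 4, 1)


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x, training: bool = False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask


def _bin_edges(n_in: int, n_out: int) -> list[tuple[int, int]]:
    """Adaptive-pooling bin boundaries; when ``n_in < n_out`` bins overlap
    and values are effectively repeated, so any slice count >= 1 is legal."""
    return [(int(np.floor(i * n_in / n_out)),
             int(np.ceil((i + 1) * n_in / n_out))) for i in range(n_out)]


class AdaptiveMaxPool3D:
    """Max pooling to a fixed output grid regardless of input size."""

    def __init__(self, out_size: tuple[int, int, int]):
        self.out_size = out_size
        self._cache = None

    def params(self):
        return []

    def forward(self, x, training: bool = False):
        N, C, H, W, Z = x.shape
        oh, ow, oz = self.out_size
        hb, wb, zb = _bin_edges(H, oh), _bin_edges(W, ow), _bin_edges(Z, oz)
        out = np.empty((N, C, oh, ow, oz))
        idx = np.empty((N, C, oh, ow, oz), dtype=np.int64)
        strides = np.array([W * Z, Z, 1])
        for i, (h0, h1) in enumerate(hb):
            for j, (w0, w1) in enumerate(wb):
                for m, (z0, z1) in enumerate(zb):
                    sub = x[:, :, h0:h1, w0:w1, z0:z1]
                    flat = sub.reshape(N, C, -1)
                    am = flat.argmax(axis=2)
                    out[:, :, i, j, m] = np.take_along_axis(flat, am[:, :, None], axis=2)[:, :, 0]
                    sh, sw, sz = sub.shape[2:]
                    ai, rem = np.divmod(am, sw * sz)
                    aj, ak = np.divmod(rem, sz)
                    idx[:, :, i, j, m] = ((h0 + ai) * strides[0]
                                          + (w0 + aj) * strides[1] + (z0 + ak))
        self._cache = (idx, (N, C, H, W, Z))
        return out

    def backward(self, gy):
        idx, (N, C, H, W, Z) = self._cache
        dx = np.zeros((N, C, H * W * Z))
        flat_idx = idx.reshape(N, C, -1)
        flat_g = gy.reshape(N, C, -1)
        for n in range(N):
            for c in range(C):
                np.add.at(dx[n, c], flat_idx[n, c], flat_g[n, c])
        return dx.reshape(N, C, H, W, Z)


class DepthConv:
    """``c_out @ 1 x 1 x K`` convolution collapsing the through-plane axis.

    Input ``(N, c_in, H, W, K)`` -> output ``(N, c_out, H, W, 1)``.
    """

    def __init__(self, c_in: int, c_out: int, depth: int,
                 rng: np.random.Generator | None = None, name: str = "depthconv"):
        self.c_in, self.c_out, self.depth = c_in, c_out, depth
        rng = rng or np.random.default_rng(0)
        self.W = Param(kaiming_uniform(rng, (c_out, c_in, depth), c_in * depth), f"{name}.W")
        self.b = Param(np.zeros(c_out), f"{name}.b")
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training: bool = False):
        if x.shape[4] != self.depth:
            raise ValueError(f"expected through-plane extent {self.depth}, got {x.shape[4]}")
        self._x = x
        y = np.einsum("nchwz,ocz->nohw", x, self.W.value) + self.b.value[None, :, None, None]
        return y[..., None]

    def backward(self, gy):
        g = gy[..., 0]
        self.W.grad += np.einsum("nohw,nchwz->ocz", g, self._x)
        self.b.grad += g.sum(axis=(0, 2, 3))
        return np.einsum("nohw,ocz->nchwz", g, self.W.value)


class DenseConv:
    """``c_out @ kh x kw x 1`` valid convolution consuming the full in-plane
    grid (a fully connected map over the pooled features).

    Input ``(N, c_in, kh, kw, 1)`` -> output ``(N, c_out, 1, 1, 1)``.
    """

    def __init__(self, c_in: int, c_out: int, kh: int, kw: int,
                 rng: np.random.Generator | None = None, name: str = "denseconv"):
        self.c_in, self.c_out, self.kh, self.kw = c_in, c_out, kh, kw
        fan_in = c_in * kh * kw
        rng = rng or np.random.default_rng(0)
        self.W = Param(kaiming_uniform(rng, (c_out, fan_in), fan_in), f"{name}.W")
        self.b = Param(np.zeros(c_out), f"{name}.b")
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training: bool = False):
        N = x.shape[0]
        if x.shape[1:] != (self.c_in, self.kh, self.kw, 1):
            raise ValueError(f"expected input {(self.c_in, self.kh, self.kw, 1)}, got {x.shape[1:]}")
        self._x = x.reshape(N, -1)
        y = self._x @ self.W.value.T + self.b.value
        return y[:, :, None, None, None]

    def backward(self, gy):
        g = gy[:, :, 0, 0, 0]
        self.W.grad += g.T @ self._x
        self.b.grad += g.sum(axis=0)
        dx = g @ self.W.value
        return dx.reshape(self._x.shape[0], self.c_in, self.kh, self.kw, 1)


class Dropout:
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng: np.random.Generator | None = None
        self._mask = None

    def params(self):
        return []

    def forward(self, x, training: bool = False):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        if self.rng is None:
            raise RuntimeError("dropout used in training mode without an rng attached")
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, gy):
        return gy if self._mask is None else gy * self._mask


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None,
                 name: str = "linear"):
        rng = rng or np.random.default_rng(0)
        self.W = Param(kaiming_uniform(rng, (n_out, n_in), n_in), f"{name}.W")
        self.b = Param(np.zeros(n_out), f"{name}.b")
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training: bool = False):
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, gy):
        g2 = gy.reshape(-1, gy.shape[-1])
        x2 = self._x.reshape(-1, self._x.shape[-1])
        self.W.grad += g2.T @ x2
        self.b.grad += g2.sum(axis=0)
        return gy @ self.W.value


class GlobalSliceMaxPool:
    """Global in-plane max per slice: ``(N, C, H, W, Z)`` -> ``(N, Z, C)``."""

    def __init__(self):
        self._cache = None

    def params(self):
        return []

    def forward(self, x, training: bool = False):
        N, C, H, W, Z = x.shape
        flat = x.transpose(0, 4, 1, 2, 3).reshape(N, Z, C, H * W)
        am = flat.argmax(axis=3)
        out = np.take_along_axis(flat, am[..., None], axis=3)[..., 0]
        self._cache = (am, (N, C, H, W, Z))
        return out

    def backward(self, gy):
        am, (N, C, H, W, Z) = self._cache
        dflat = np.zeros((N, Z, C, H * W))
        np.put_along_axis(dflat, am[..., None], gy[..., None], axis=3)
        return dflat.reshape(N, Z, C, H, W).transpose(0, 2, 3, 4, 1)


class Adam:
    """Adam with bias correction; conventional beta/epsilon defaults."""

    def __init__(self, params: list[Param], lr: float = 5e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
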