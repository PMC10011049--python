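"""A compact NumPy neural-network engine for 3D encoder-decoder models.

Implements exactly the layers the segmentation networks need — 3D convolution
(im2col + BLAS matmul), group normalization, leaky ReLU, 2x max-pooling,
nearest-neighbour upsampling, strided transposed convolution, sigmoid — each
with a hand-derived backward pass, plus the Adam optimizer.  Everything runs
in float32; half precision is deliberately not supported because the compound
Dice+BCE loss underflows there.

Layers follow a uniform protocol: ``forward(x)`` caches what backward needs,
``backward(dy)`` returns ``dx`` and fills ``layer.grads`` parallel to
``layer.params``.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32

# im2col buffers above this many float32 elements are processed in depth slabs
_COL_BUDGET = 64_000_000


class Layer:
    """Base class: parameter-free identity-ish layer protocol."""

    def __init__(self):
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(F32)


class Conv3d(Layer):
    """3D convolution, kernel 1 or 3, stride 1, 'same' padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        fan_in = c_in * kernel ** 3
        self.W = _he_init(rng, (c_out, c_in, kernel, kernel, kernel), fan_in)
        self.b = np.zeros(c_out, dtype=F32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    # -- kernel-3 path: im2col over depth slabs to bound memory ------------
    def _slabs(self, shape):
        n, _, d, h, w = shape
        per_z = n * self.c_in * 27 * h * w
        step = max(1, int(_COL_BUDGET // max(per_z, 1)))
        return [(z0, min(z0 + step, d)) for z0 in range(0, d, step)]

    @staticmethod
    def _im2col(xp, z0, z1, h, w):
        # xp: padded input (N, C, D+2, H+2, W+2); rows ordered (c, kz, ky, kx)
        # to match W.reshape(c_out, c*27)
        n, c = xp.shape[:2]
        dz = z1 - z0
        cols = np.empty((n, c, 27, dz, h, w), dtype=F32)
        j = 0
        for kz in range(3):
            for ky in range(3):
                for kx in range(3):
                    cols[:, :, j] = xp[:, :, z0 + kz:z0 + kz + dz, ky:ky + h, kx:kx + w]
                    j += 1
        return cols

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=F32)
        n, c, d, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        if self.k == 1:
            self._cache = x
            xf = x.reshape(n, c, -1)
            y = np.matmul(self.W.reshape(self.c_out, c), xf).reshape(
                n, self.c_out, d, h, w
            )
            return y + self.b[None, :, None, None, None]
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
        Wm = self.W.reshape(self.c_out, c * 27)
        out = np.empty((n, self.c_out, d, h, w), dtype=F32)
        slabs = self._slabs(x.shape)
        cols_cache = []
        for z0, z1 in slabs:
            cols = self._im2col(xp, z0, z1, h, w)
            cols_cache.append(cols)
            colsf = cols.reshape(n, c * 27, (z1 - z0) * h * w)
            out[:, :, z0:z1] = (Wm @ colsf).reshape(n, self.c_out, z1 - z0, h, w)
        out += self.b[None, :, None, None, None]
        self._cache = (x.shape, slabs, cols_cache)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = np.ascontiguousarray(dy, dtype=F32)
        if self.k == 1:
            x = self._cache
            n, _, d, h, w = x.shape
            dyf = dy.reshape(n, self.c_out, -1)
            xf = x.reshape(n, self.c_in, -1)
            dW = np.tensordot(dyf, xf, axes=([0, 2], [0, 2]))
            self.grads[0][...] = dW.reshape(self.W.shape)
            self.grads[1][...] = dy.sum(axis=(0, 2, 3, 4))
            dx = np.matmul(self.W.reshape(self.c_out, self.c_in).T, dyf)
            return dx.reshape(x.shape)
        (xshape, slabs, cols_cache) = self._cache
        n, c, d, h, w = xshape
        Wm = self.W.reshape(self.c_out, c * 27)
        dW = np.zeros_like(Wm)
        dxp = np.zeros((n, c, d + 2, h + 2, w + 2), dtype=F32)
        for (z0, z1), cols in zip(slabs, cols_cache):
            v = (z1 - z0) * h * w
            dyf = np.ascontiguousarray(dy[:, :, z0:z1]).reshape(n, self.c_out, v)
            colsf = cols.reshape(n, c * 27, v)
            # dW += sum_n dyf[n] @ cols[n].T; the transpose is a gemm flag,
            # not a copy
            dW += np.matmul(dyf, colsf.transpose(0, 2, 1)).sum(axis=0)
            dcols = (Wm.T @ dyf).reshape(n, c, 27, z1 - z0, h, w)
            j = 0
            for kz in range(3):
                for ky in range(3):
                    for kx in range(3):
                        dxp[:, :, z0 + kz:z0 + kz + (z1 - z0), ky:ky + h, kx:kx + w] += dcols[:, :, j]
                        j += 1
        self.grads[0][...] = dW.reshape(self.W.shape)
        self.grads[1][...] = dy.sum(axis=(0, 2, 3, 4))
        self._cache = None
        return np.ascontiguousarray(dxp[:, :, 1:-1, 1:-1, 1:-1])


class ConvTranspose3d(Layer):
    """Transposed convolution, kernel 2, stride 2 (the learned-upsampling

    alternative to parameter-free interpolation in the decoder)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.W = _he_init(rng, (c_in, c_out, 2, 2, 2), c_in)
        self.b = np.zeros(c_out, dtype=F32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=F32)
        n, c, d, h, w = x.shape
        self._cache = x
        out = np.empty((n, self.c_out, 2 * d, 2 * h, 2 * w), dtype=F32)
        for a in range(2):
            for bb in range(2):
                for cc in range(2):
                    out[:, :, a::2, bb::2, cc::2] = np.einsum(
                        "io,nidhw->nodhw", self.W[:, :, a, bb, cc], x
                    )
        return out + self.b[None, :, None, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache
        dx = np.zeros_like(x)
        dW = np.zeros_like(self.W)
        for a in range(2):
            for bb in range(2):
                for cc in range(2):
                    sl = dy[:, :, a::2, bb::2, cc::2]
                    dW[:, :, a, bb, cc] = np.einsum("nodhw,nidhw->io", sl, x)
                    dx += np.einsum("io,nodhw->nidhw", self.W[:, :, a, bb, cc], sl)
        self.grads[0][...] = dW
        self.grads[1][...] = dy.sum(axis=(0, 2, 3, 4))
        self._cache = None
        return dx


class GroupNorm(Layer):
    """Group normalization with per-channel affine; stable at batch size 1."""

    def __init__(self, channels: int, groups: int = 8, eps: float = 1e-5):
        super().__init__()
        if channels % groups:
            raise ValueError(f"groups ({groups}) must divide channels ({channels})")
        self.c, self.g, self.eps = channels, groups, eps
        self.gamma = np.ones(channels, dtype=F32)
        self.beta = np.zeros(channels, dtype=F32)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c = x.shape[:2]
        spatial = x.shape[2:]
        xg = x.reshape(n, self.g, -1)
        mu = xg.mean(axis=2, keepdims=True)
        var = xg.var(axis=2, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = ((xg - mu) * inv).astype(F32)
        self._cache = (xhat, inv.astype(F32), (n, c) + spatial)
        y = xhat.reshape(n, c, -1) * self.gamma[None, :, None] + self.beta[None, :, None]
        return y.reshape(n, c, *spatial).astype(F32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        n, c = shape[:2]
        dyf = dy.reshape(n, c, -1)
        self.grads[0][...] = (dyf * xhat.reshape(n, c, -1)).sum(axis=(0, 2))
        self.grads[1][...] = dyf.sum(axis=(0, 2))
        dxhat = (dyf * self.gamma[None, :, None]).reshape(n, self.g, -1)
        m = dxhat.shape[2]
        dx = inv * (
            dxhat
            - dxhat.mean(axis=2, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=2, keepdims=True)
        )
        self._cache = None
        return dx.reshape(shape).astype(F32)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        super().__init__()
        self.slope = F32(slope)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._neg = x < 0
        return np.where(self._neg, x * self.slope, x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.where(self._neg, dy * self.slope, dy)
        self._neg = None
        return dx


class MaxPool2(Layer):
    """2x2x2 max pooling, stride 2; gradient split evenly among ties."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"spatial extents must be even for 2x pooling, got {(d, h, w)}")
        xr = x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        y = xr.max(axis=(3, 5, 7))
        self._cache = (xr, y)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xr, y = self._cache
        mask = (xr == y[:, :, :, None, :, None, :, None]).astype(F32)
        mask /= mask.sum(axis=(3, 5, 7), keepdims=True)
        dx = mask * dy[:, :, :, None, :, None, :, None]
        n, c = dx.shape[:2]
        self._cache = None
        return dx.reshape(n, c, xr.shape[2] * 2, xr.shape[4] * 2, xr.shape[6] * 2)


class UpsampleNearest2(Layer):
    """Parameter-free nearest-neighbour 2x upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        y = x.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, d, h, w = self._shape
        dyr = dy.reshape(n, c, d, 2, h, 2, w, 2)
        return np.ascontiguousarray(dyr.sum(axis=(3, 5, 7)))


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        # numerically stable logistic
        y = np.empty_like(x)
        pos = x >= 0
        y[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        y[~pos] = ex / (1.0 + ex)
        self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._y * (1.0 - self._y)
        self._y = None
        return dx


class Adam:
    """Adam optimizer over a flat list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= (self.lr / b1t) * m / (np.sqrt(v / b2t) + self.eps)
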