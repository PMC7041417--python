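"""Minimal deterministic 3D CNN building blocks on numpy.

Forward and backward passes for the handful of layer types the U-Net needs:
stride-1 zero-padded 3D convolution, ReLU, 2x max-pooling, nearest-neighbour
2x upsampling, inverted dropout and an optional batch-norm.

All layers operate on channels-last activations (N, D, H, W, C), which lets
convolution run directly on a flat position-major view of the zero-padded
batch: for each of the k^3 kernel offsets the shifted window is a contiguous
slice, so each offset contributes one accumulating ``sgemm`` and no im2col
buffer is ever materialised. Windows that straddle two stacked samples
anchor at flat positions no valid output reads. All arithmetic is float32
and bit-reproducible on a fixed machine.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from numpy.lib.stride_tricks import as_strided
from scipy.linalg.blas import sgemm


class _StackGeometry:
    """Flat-index bookkeeping for a padded batch stacked along depth."""

    def __init__(self, n: int, spatial: tuple[int, int, int], k: int):
        self.n = n
        self.k = k
        self.p = k // 2
        self.d, self.h, self.w = spatial
        self.dp, self.hp, self.wp = (s + 2 * self.p for s in spatial)
        self.s1 = self.hp * self.wp
        self.s2 = self.wp
        total = n * self.dp * self.s1
        self.q = total - (k - 1) * (self.s1 + self.s2 + 1)

    def pad(self, x: np.ndarray) -> np.ndarray:
        """(N, D, H, W, C) -> flat position-major (N*P, C), zero padded."""
        p, c = self.p, x.shape[-1]
        xp = np.zeros((self.n, self.dp, self.hp, self.wp, c), np.float32)
        xp[:, p:self.dp - p, p:self.hp - p, p:self.wp - p] = x
        return xp.reshape(-1, c)

    def valid_view(self, flat: np.ndarray) -> np.ndarray:
        """Strided (N, D, H, W, C) window onto a C-ordered flat (Q, C) array."""
        c = flat.shape[1]
        es = flat.itemsize
        row = c * es
        return as_strided(
            flat,
            shape=(self.n, self.d, self.h, self.w, c),
            strides=(self.dp * self.s1 * row, self.s1 * row, self.s2 * row, row, es),
        )


def _conv3d_cl(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Channels-last convolution. x: (N,D,H,W,C), w: (O,C,k,k,k) -> (N,D,H,W,O)."""
    o_ch, c_ch, k = w.shape[:3]
    if k == 1:
        out = x.reshape(-1, c_ch) @ np.ascontiguousarray(w.reshape(o_ch, c_ch).T)
        return out.reshape(x.shape[:4] + (o_ch,))
    geo = _StackGeometry(x.shape[0], x.shape[1:4], k)
    xt = geo.pad(x)
    # y is C-ordered (Q, O); computed as its F-ordered transpose so every
    # offset is a single accumulating BLAS call on contiguous views
    yt = np.zeros((o_ch, geo.q), np.float32, order="F")
    for dz, dy, dx in product(range(k), repeat=3):
        off = dz * geo.s1 + dy * geo.s2 + dx
        a = np.asfortranarray(w[:, :, dz, dy, dx])  # (O, C)
        b = xt[off:off + geo.q].T  # (C, Q) F-contiguous view
        sgemm(1.0, a, b, beta=1.0, c=yt, overwrite_c=1)
    return np.ascontiguousarray(geo.valid_view(yt.T))


def conv3d(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Same-size zero-padded cross-correlation on channels-first arrays.

    x: (N, C, D, H, W), w: (O, C, k, k, k) -> (N, O, D, H, W).
    """
    xcl = np.ascontiguousarray(x.transpose(0, 2, 3, 4, 1), np.float32)
    out = _conv3d_cl(xcl, np.asarray(w, np.float32))
    return np.ascontiguousarray(out.transpose(0, 4, 1, 2, 3))


class Conv3d:
    """3D convolution with bias, He-initialised, same-size zero padding."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (in_ch * kernel ** 3))
        self.w = rng.normal(0.0, std, (out_ch, in_ch, kernel, kernel, kernel)).astype(np.float32)
        self.b = np.zeros(out_ch, np.float32)
        self.gw = None
        self.gb = None
        self._x = None

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return _conv3d_cl(x, self.w) + self.b

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x, self._x = self._x, None
        o_ch, c_ch, k = self.w.shape[:3]
        self.gb = gy.reshape(-1, o_ch).sum(axis=0)
        if k == 1:
            gf = gy.reshape(-1, o_ch)
            xf = x.reshape(-1, c_ch)
            self.gw = (gf.T @ xf).reshape(self.w.shape)
            gx = gf @ self.w.reshape(o_ch, c_ch)
            return gx.reshape(x.shape)
        geo = _StackGeometry(x.shape[0], x.shape[1:4], k)
        xt = geo.pad(x)
        # scatter gy into the flat window-anchor layout (zeros elsewhere)
        gf = np.zeros((geo.q, o_ch), np.float32)
        geo.valid_view(gf)[...] = gy
        gw = np.zeros((o_ch, c_ch, k, k, k), np.float32)
        gwf = np.zeros((c_ch, o_ch), np.float32, order="F")
        for dz, dy, dx in product(range(k), repeat=3):
            off = dz * geo.s1 + dy * geo.s2 + dx
            a = xt[off:off + geo.q].T  # (C, Q) F-contiguous view
            sgemm(1.0, a, gf.T, beta=0.0, c=gwf, trans_b=1, overwrite_c=1)
            gw[:, :, dz, dy, dx] = gwf.T
        self.gw = gw
        # gradient w.r.t. input: correlate with the flipped, channel-transposed kernel
        wf = np.ascontiguousarray(
            self.w[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4))
        return _conv3d_cl(gy, wf)

    def params_and_grads(self):
        return [("w", self.w, self.gw), ("b", self.b, self.gb)]


class ReLU:
    def forward(self, x, train=False):
        if train:
            self._m = x > 0
        return np.maximum(x, 0.0)

    def backward(self, gy):
        return gy * self._m


class MaxPool3d:
    """2x2x2 max pooling; ties route to the first (lowest flat index) maximum."""

    def forward(self, x, train=False):
        n, d, h, w, c = x.shape
        v = x.reshape(n, d // 2, 2, h // 2, 2, w // 2, 2, c)
        v = v.transpose(0, 1, 3, 5, 7, 2, 4, 6).reshape(n, d // 2, h // 2, w // 2, c, 8)
        idx = v.argmax(-1)
        out = np.take_along_axis(v, idx[..., None], -1)[..., 0]
        if train:
            self._idx = idx
            self._shape = (n, d, h, w, c)
        return out

    def backward(self, gy):
        n, d, h, w, c = self._shape
        g = np.zeros((n, d // 2, h // 2, w // 2, c, 8), np.float32)
        np.put_along_axis(g, self._idx[..., None], gy[..., None], -1)
        g = g.reshape(n, d // 2, h // 2, w // 2, c, 2, 2, 2)
        g = g.transpose(0, 1, 5, 2, 6, 3, 7, 4)
        return np.ascontiguousarray(g).reshape(n, d, h, w, c)


class Upsample3d:
    """Nearest-neighbour 2x upsampling along the three spatial axes."""

    def forward(self, x, train=False):
        return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, gy):
        n, d, h, w, c = gy.shape
        v = gy.reshape(n, d // 2, 2, h // 2, 2, w // 2, 2, c)
        return v.sum(axis=(2, 4, 6))


class Dropout:
    """Inverted dropout; identity unless ``train`` and a generator is attached."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng: np.random.Generator | None = None
        self._m = None

    def forward(self, x, train=False):
        if not train or self.rate == 0.0 or self.rng is None:
            self._m = None
            return x
        keep = 1.0 - self.rate
        self._m = (self.rng.random(x.shape, dtype=np.float32) < keep).astype(np.float32) / keep
        return x * self._m

    def backward(self, gy):
        if self._m is None:
            return gy
        return gy * self._m


class BatchNorm3d:
    """Per-channel batch normalisation (optional; the default network omits it)."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = np.ones(channels, np.float32)
        self.beta = np.zeros(channels, np.float32)
        self.eps = eps
        self.momentum = momentum
        self.run_mean = np.zeros(channels, np.float32)
        self.run_var = np.ones(channels, np.float32)
        self.ggamma = None
        self.gbeta = None

    @property
    def n_params(self) -> int:
        return self.gamma.size + self.beta.size

    def forward(self, x, train=False):
        axes = (0, 1, 2, 3)
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = (1 - self.momentum) * self.run_mean + self.momentum * mu
            self.run_var = (1 - self.momentum) * self.run_var + self.momentum * var
        else:
            mu, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        if train:
            self._xhat, self._inv = xhat, inv
        return self.gamma * xhat + self.beta

    def backward(self, gy):
        axes = (0, 1, 2, 3)
        m = gy.size / gy.shape[-1]
        self.gbeta = gy.sum(axis=axes)
        self.ggamma = (gy * self._xhat).sum(axis=axes)
        gh = gy * self.gamma
        t1 = gh - gh.mean(axis=axes, keepdims=True)
        t2 = self._xhat * (gh * self._xhat).sum(axis=axes, keepdims=True) / m
        return self._inv * (t1 - t2)

    def params_and_grads(self):
        return [("gamma", self.gamma, self.ggamma), ("beta", self.beta, self.gbeta)]


def softmax_channels(z: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax over the class axis."""
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_backward(p: np.ndarray, gp: np.ndarray, axis: int = -1) -> np.ndarray:
    """Given probabilities p and dL/dp, return dL/dlogits."""
    return p * (gp - (gp * p).sum(axis=axis, keepdims=True))
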