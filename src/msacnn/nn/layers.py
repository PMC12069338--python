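"""Minimal NHWC neural-network layers with manual backpropagation.

Feature maps are rank-4 float arrays shaped (batch, H, W, C). Every layer
implements ``forward(x, train=False)`` and ``backward(dy)``; stateful layers
keep their parameters in ``self.P`` and the matching gradients in ``self.G``
so an optimizer can walk ``leaves()`` and update in place.
"""

from __future__ import annotations

import numpy as np


def relu(x):
    """Elementwise max(0, x)."""
    return np.maximum(0.0, x)


def same_pad_amount(size: int, k: int, s: int) -> tuple[int, int]:
    # TF convention: pad the extra sample at the end
    out = -(-size // s)
    pad = max((out - 1) * s + k - size, 0)
    return pad // 2, pad - pad // 2


def im2col(x, kh, kw, sh, sw):
    """View sliding (kh, kw) patches of a padded NHWC array as columns."""
    n, h, w, c = x.shape
    oh = (h - kh) // sh + 1
    ow = (w - kw) // sw + 1
    s0, s1, s2, s3 = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x, (n, oh, ow, kh, kw, c), (s0, s1 * sh, s2 * sw, s1, s2, s3),
        writeable=False,
    )
    return cols.reshape(n, oh * ow, kh * kw * c), oh, ow


def col2im_add(dcols, x_padded_shape, kh, kw, sh, sw, oh, ow):
    """Scatter-add column gradients back onto the padded input grid."""
    n, hp, wp, c = x_padded_shape
    dxp = np.zeros(x_padded_shape, dtype=dcols.dtype)
    d = dcols.reshape(n, oh, ow, kh, kw, c)
    for i in range(kh):
        for j in range(kw):
            dxp[:, i:i + oh * sh:sh, j:j + ow * sw:sw, :] += d[:, :, :, i, j, :]
    return dxp


def glorot_uniform(shape, fan_in, fan_out, rng):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    P: dict
    G: dict

    def __init__(self):
        self.P = {}
        self.G = {}

    def forward(self, x, train=False):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - abstract
        raise NotImplementedError

    def leaves(self):
        return [self]

    # extra non-trainable state (e.g. BN running stats) included in checkpoints
    def state_items(self):
        return self.P


class Conv2D(Layer):
    """2-D convolution (cross-correlation, the deep-learning convention)."""

    def __init__(self, filters, kernel_size, in_channels, stride=(1, 1),
                 padding="same", use_bias=True, rng=None):
        super().__init__()
        if padding not in ("same", "valid"):
            raise ValueError(f"padding must be 'same' or 'valid', got {padding!r}")
        rng = rng or np.random.default_rng()
        kh, kw = kernel_size
        self.kh, self.kw = kh, kw
        self.stride = stride
        self.padding = padding
        self.in_channels = in_channels
        self.filters = filters
        fan_in = kh * kw * in_channels
        self.P["k"] = glorot_uniform((kh, kw, in_channels, filters), fan_in, filters, rng)
        self.G["k"] = np.zeros_like(self.P["k"])
        self.use_bias = use_bias
        if use_bias:
            self.P["b"] = np.zeros(filters)
            self.G["b"] = np.zeros(filters)

    def _pad(self, x):
        n, h, w, c = x.shape
        sh, sw = self.stride
        if self.padding == "same":
            pt, pb = same_pad_amount(h, self.kh, sh)
            pl, pr = same_pad_amount(w, self.kw, sw)
        else:
            pt = pb = pl = pr = 0
            if h < self.kh or w < self.kw:
                raise ValueError(
                    f"kernel ({self.kh},{self.kw}) larger than input ({h},{w}) "
                    "under valid padding")
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        return xp

    def forward(self, x, train=False):
        xp = self._pad(x)
        sh, sw = self.stride
        cols, oh, ow = im2col(xp, self.kh, self.kw, sh, sw)
        kmat = self.P["k"].reshape(-1, self.filters)
        y = cols @ kmat
        if self.use_bias:
            y = y + self.P["b"]
        self._cache = (x.shape, xp.shape, cols, oh, ow)
        return y.reshape(x.shape[0], oh, ow, self.filters)

    def backward(self, dy):
        x_shape, xp_shape, cols, oh, ow = self._cache
        n = x_shape[0]
        sh, sw = self.stride
        dyf = dy.reshape(n, oh * ow, self.filters)
        kmat = self.P["k"].reshape(-1, self.filters)
        self.G["k"][...] = np.einsum("npk,npf->kf", cols, dyf).reshape(self.P["k"].shape)
        if self.use_bias:
            self.G["b"][...] = dyf.sum(axis=(0, 1))
        dcols = dyf @ kmat.T
        dxp = col2im_add(dcols, xp_shape, self.kh, self.kw, sh, sw, oh, ow)
        # strip padding
        pt = (xp_shape[1] - x_shape[1])
        pl = (xp_shape[2] - x_shape[2])
        pt0, pl0 = pt // 2, pl // 2
        return dxp[:, pt0:pt0 + x_shape[1], pl0:pl0 + x_shape[2], :]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class BatchNorm(Layer):
    """Per-channel batch normalization with running statistics for inference."""

    def __init__(self, channels, momentum=0.9, eps=1e-3):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.P["gamma"] = np.ones(channels)
        self.P["beta"] = np.zeros(channels)
        self.G["gamma"] = np.zeros(channels)
        self.G["beta"] = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def state_items(self):
        return {**self.P, "running_mean": self.running_mean,
                "running_var": self.running_var}

    def forward(self, x, train=False):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean) / std
        self._cache = (xhat, std, axes, train, x.shape)
        return self.P["gamma"] * xhat + self.P["beta"]

    def backward(self, dy):
        xhat, std, axes, train, shape = self._cache
        self.G["gamma"][...] = (dy * xhat).sum(axis=axes)
        self.G["beta"][...] = dy.sum(axis=axes)
        g = self.P["gamma"]
        if not train:
            return dy * g / std
        m = np.prod([shape[a] for a in axes])
        s1 = dy.sum(axis=axes)
        s2 = (dy * xhat).sum(axis=axes)
        return (g / (std * m)) * (m * dy - s1 - xhat * s2)


class MaxPool2D(Layer):
    """Non-overlapping max pooling; trailing rows/cols that do not fill a
    window are dropped (valid pooling)."""

    def __init__(self, pool=(2, 2)):
        super().__init__()
        self.pool = pool

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        ph, pw = self.pool
        oh, ow = h // ph, w // pw
        if oh == 0 or ow == 0:
            raise ValueError(f"pool {self.pool} exceeds spatial dims ({h},{w})")
        xc = x[:, :oh * ph, :ow * pw, :]
        xr = (xc.reshape(n, oh, ph, ow, pw, c)
                .transpose(0, 1, 3, 2, 4, 5)
                .reshape(n, oh, ow, ph * pw, c))
        self._arg = xr.argmax(axis=3)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._arg[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, dy):
        n, h, w, c = self._in_shape
        ph, pw = self.pool
        oh, ow = h // ph, w // pw
        dxr = np.zeros((n, oh, ow, ph * pw, c), dtype=dy.dtype)
        np.put_along_axis(dxr, self._arg[:, :, :, None, :], dy[:, :, :, None, :], axis=3)
        dxc = (dxr.reshape(n, oh, ow, ph, pw, c)
                  .transpose(0, 1, 3, 2, 4, 5)
                  .reshape(n, oh * ph, ow * pw, c))
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        dx[:, :oh * ph, :ow * pw, :] = dxc
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate, rng=None):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng()

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class GlobalAvgPool(Layer):
    def forward(self, x, train=False):
        self._in_shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy):
        n, h, w, c = self._in_shape
        return np.broadcast_to(dy[:, None, None, :] / (h * w), self._in_shape).copy()


class Flatten(Layer):
    def forward(self, x, train=False):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._in_shape)


class Dense(Layer):
    def __init__(self, units, in_dim, use_bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.P["w"] = glorot_uniform((in_dim, units), in_dim, units, rng)
        self.G["w"] = np.zeros_like(self.P["w"])
        self.use_bias = use_bias
        if use_bias:
            self.P["b"] = np.zeros(units)
            self.G["b"] = np.zeros(units)

    def forward(self, x, train=False):
        self._x = x
        y = x @ self.P["w"]
        if self.use_bias:
            y = y + self.P["b"]
        return y

    def backward(self, dy):
        self.G["w"][...] = self._x.T @ dy
        if self.use_bias:
            self.G["b"][...] = dy.sum(axis=0)
        return dy @ self.P["w"].T


class Sequential(Layer):
    """A simple layer chain; backward runs in reverse order."""

    def __init__(self, layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def leaves(self):
        out = []
        for layer in self.layers:
            out.extend(layer.leaves())
        return out
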