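"""Adaptive convolutional layer (ACNL): attention-reweighted kernels.

The layer derives one attention weight per filter from the input itself:

1. the input feature map is global-average-pooled to one scalar per input
   channel, ``gap[b, c] = mean(X[b, :, :, c])``;
2. a fully connected layer followed by a softmax maps the pooled vector to
   attention weights ``a[b]`` of length F (one per filter), positive and
   summing to 1;
3. the attention vector is broadcast to the shape of the kernel bank and
   multiplied elementwise, giving per-sample kernels ``K'[..., f] = a[f] K[..., f]``;
4. a standard convolution with ``K'`` produces the output.

Because convolution is linear in the kernel, step 3-4 is implemented as a
single convolution with the shared bank ``K`` followed by per-channel scaling
of the output by ``a[b, f]`` — mathematically identical, but it avoids
materialising a kernel bank per sample. The optional convolution bias is
added after the scaling, so attention modulates only the linear response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.layers import (
    Layer, col2im_add, glorot_uniform, im2col, same_pad_amount,
)
from .nn.losses import softmax


@dataclass
class KernelBank:
    """Kernel bank K plus the attention head that reweights it.

    k          : (kh, kw, C_in, F) convolution kernels
    attn_dense : (C_in, F) fully connected weights producing attention logits
    attn_bias  : (F,) or None — bias of the attention dense layer
    conv_bias  : (F,) or None — bias added after attention scaling
    """

    k: np.ndarray
    attn_dense: np.ndarray
    attn_bias: np.ndarray | None = None
    conv_bias: np.ndarray | None = None

    def __post_init__(self):
        kh, kw, c_in, f = self.k.shape
        if kh < 1 or kw < 1 or f < 1:
            raise ValueError("kernel bank must have kh, kw, F >= 1")
        if self.attn_dense.shape != (c_in, f):
            raise ValueError(
                f"attn_dense shape {self.attn_dense.shape} does not match "
                f"kernel bank (C_in={c_in}, F={f})")

    @property
    def filters(self) -> int:
        return self.k.shape[3]


def global_avg_pool(x: np.ndarray) -> np.ndarray:
    """Mean over the spatial axes: (batch, H, W, C) -> (batch, C)."""
    if x.ndim != 4:
        raise ValueError(f"expected rank-4 feature map, got rank {x.ndim}")
    if x.shape[1] == 0 or x.shape[2] == 0:
        raise ValueError("feature map has empty spatial extent")
    return x.mean(axis=(1, 2))


def attention_weights(gap: np.ndarray, bank: KernelBank) -> np.ndarray:
    """Per-sample attention over the filter axis: softmax(gap @ W + b)."""
    if gap.shape[1] != bank.attn_dense.shape[0]:
        raise ValueError(
            f"gap has {gap.shape[1]} channels but attn_dense expects "
            f"{bank.attn_dense.shape[0]}")
    logits = gap @ bank.attn_dense
    if bank.attn_bias is not None:
        logits = logits + bank.attn_bias
    return softmax(logits, axis=1)


def reweight_kernels(bank: KernelBank, a: np.ndarray, sample_index: int) -> np.ndarray:
    """Broadcast one sample's attention vector onto the bank: K'[..., f] = a[f] K[..., f]."""
    av = np.asarray(a)
    if av.ndim == 2:
        av = av[sample_index]
    if av.shape != (bank.filters,):
        raise ValueError(f"attention length {av.shape} != filters {bank.filters}")
    return bank.k * av[None, None, None, :]


def adaptive_conv_forward(x: np.ndarray, bank: KernelBank,
                          stride=(1, 1), padding="same") -> np.ndarray:
    """Forward pass of the adaptive convolution (inference semantics).

    Equivalent to convolving each sample with its own reweighted bank K';
    implemented as conv-then-scale via linearity.
    """
    y, _ = _forward_with_cache(x, bank, stride, padding)
    return y


def _forward_with_cache(x, bank, stride, padding):
    if padding not in ("same", "valid"):
        raise ValueError(f"padding must be 'same' or 'valid', got {padding!r}")
    kh, kw, c_in, f = bank.k.shape
    sh, sw = stride
    n, h, w, c = x.shape
    if c != c_in:
        raise ValueError(f"input depth {c} != kernel C_in {c_in}")
    if padding == "same":
        pt, pb = same_pad_amount(h, kh, sh)
        pl, pr = same_pad_amount(w, kw, sw)
    else:
        if h < kh or w < kw:
            raise ValueError(
                f"kernel ({kh},{kw}) larger than input ({h},{w}) under valid padding")
        pt = pb = pl = pr = 0
    xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    cols, oh, ow = im2col(xp, kh, kw, sh, sw)
    z = (cols @ bank.k.reshape(-1, f)).reshape(n, oh, ow, f)
    gap = global_avg_pool(x)
    a = attention_weights(gap, bank)
    y = a[:, None, None, :] * z
    if bank.conv_bias is not None:
        y = y + bank.conv_bias
    cache = (x.shape, xp.shape, cols, z, gap, a, oh, ow)
    return y, cache


class AdaptiveConv(Layer):
    """Trainable ACNL layer wrapping the functional forward pass.

    Parameters: kernel bank ``k``, attention dense weights ``attn_w`` (+
    optional ``attn_b``), optional convolution bias ``b``.
    """

    def __init__(self, filters, kernel_size, in_channels, stride=(1, 1),
                 padding="same", use_conv_bias=True, use_attn_bias=True,
                 rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        kh, kw = kernel_size
        self.stride = stride
        self.padding = padding
        self.filters = filters
        fan_in = kh * kw * in_channels
        self.P["k"] = glorot_uniform((kh, kw, in_channels, filters), fan_in, filters, rng)
        self.P["attn_w"] = glorot_uniform((in_channels, filters), in_channels, filters, rng)
        self.G["k"] = np.zeros_like(self.P["k"])
        self.G["attn_w"] = np.zeros_like(self.P["attn_w"])
        self.use_attn_bias = use_attn_bias
        self.use_conv_bias = use_conv_bias
        if use_attn_bias:
            self.P["attn_b"] = np.zeros(filters)
            self.G["attn_b"] = np.zeros(filters)
        if use_conv_bias:
            self.P["b"] = np.zeros(filters)
            self.G["b"] = np.zeros(filters)

    def bank(self) -> KernelBank:
        return KernelBank(
            k=self.P["k"],
            attn_dense=self.P["attn_w"],
            attn_bias=self.P.get("attn_b"),
            conv_bias=self.P.get("b"),
        )

    def forward(self, x, train=False):
        y, self._cache = _forward_with_cache(x, self.bank(), self.stride, self.padding)
        return y

    def backward(self, dy):
        x_shape, xp_shape, cols, z, gap, a, oh, ow = self._cache
        n, h, w, c_in = x_shape
        kh, kw, _, f = self.P["k"].shape
        sh, sw = self.stride

        if self.use_conv_bias:
            self.G["b"][...] = dy.sum(axis=(0, 1, 2))
        # attention path
        da = (dy * z).sum(axis=(1, 2))                    # (n, F)
        dlogits = a * (da - (da * a).sum(axis=1, keepdims=True))
        self.G["attn_w"][...] = gap.T @ dlogits
        if self.use_attn_bias:
            self.G["attn_b"][...] = dlogits.sum(axis=0)
        dgap = dlogits @ self.P["attn_w"].T               # (n, C_in)
        dx_gap = np.broadcast_to(
            dgap[:, None, None, :] / (h * w), x_shape).copy()
        # convolution path
        dz = (a[:, None, None, :] * dy).reshape(n, oh * ow, f)
        self.G["k"][...] = np.einsum("npk,npf->kf", cols, dz).reshape(self.P["k"].shape)
        dcols = dz @ self.P["k"].reshape(-1, f).T
        dxp = col2im_add(dcols, xp_shape, kh, kw, sh, sw, oh, ow)
        pt0 = (xp_shape[1] - h) // 2
        pl0 = (xp_shape[2] - w) // 2
        dx_conv = dxp[:, pt0:pt0 + h, pl0:pl0 + w, :]
        return dx_conv + dx_gap
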