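"""Residual block: two (2,1) convolutions with BN/ReLU and a 1x1 shortcut.

The block computes ``Y = relu(shortcut(X) + F(X))`` where the main path is
conv(2,1) -> BN -> ReLU -> conv(2,1) -> BN and the shortcut is a 1x1
convolution projecting the input to the block's filter count. Stride is 1
and padding is SAME throughout, so spatial dimensions are preserved and only
the depth changes. The shortcut projection is always present, even when the
input depth already matches, and carries neither bias nor BN; main-path
convolutions are bias-free because BN immediately follows them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn.layers import BatchNorm, Conv2D, Layer, relu


@dataclass
class ResidualBlockSpec:
    filters: int
    kernel: tuple = (2, 1)
    stride: int = 1
    padding: str = "same"

    def __post_init__(self):
        if self.filters < 1:
            raise ValueError("filters must be >= 1")


class ResidualBlock(Layer):
    def __init__(self, filters, in_channels, rng=None, kernel=(2, 1)):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.spec = ResidualBlockSpec(filters=filters, kernel=kernel)
        self.conv1 = Conv2D(filters, kernel, in_channels, use_bias=False, rng=rng)
        self.bn1 = BatchNorm(filters)
        self.conv2 = Conv2D(filters, kernel, filters, use_bias=False, rng=rng)
        self.bn2 = BatchNorm(filters)
        self.shortcut = Conv2D(filters, (1, 1), in_channels, use_bias=False, rng=rng)

    def leaves(self):
        return [self.conv1, self.bn1, self.conv2, self.bn2, self.shortcut]

    def forward(self, x, train=False):
        h = self.conv1.forward(x, train=train)
        h = self.bn1.forward(h, train=train)
        self._relu1_mask = h > 0
        h = np.where(self._relu1_mask, h, 0.0)
        h = self.conv2.forward(h, train=train)
        h = self.bn2.forward(h, train=train)
        s = self.shortcut.forward(x, train=train)
        y = h + s
        self._out_mask = y > 0
        return np.where(self._out_mask, y, 0.0)

    def backward(self, dy):
        dy = np.where(self._out_mask, dy, 0.0)
        dh = self.bn2.backward(dy)
        dh = self.conv2.backward(dh)
        dh = np.where(self._relu1_mask, dh, 0.0)
        dh = self.bn1.backward(dh)
        dx_main = self.conv1.backward(dh)
        dx_short = self.shortcut.backward(dy)
        return dx_main + dx_short


def residual_block_forward(x, block: ResidualBlock, mode: str = "infer"):
    """Run a residual block in ``train`` or ``infer`` mode."""
    if mode not in ("train", "infer"):
        raise ValueError(f"mode must be 'train' or 'infer', got {mode!r}")
    return block.forward(x, train=(mode == "train"))
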