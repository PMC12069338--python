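"""Assembly of the three-stream MSACNN-RM classifier and its ablation variants.

Windows enter as (batch, T, C, 1): time is the height axis, electrode
channel the width axis, so the (2,1) kernels span adjacent time samples
within one channel. The three streams see identical copies of the input:

* stream 1 (deep + adaptive): conv64(2,1) -> ReLU -> BN -> MaxPool -> MRN
  (residual blocks of 64/128/256/512 filters) -> 3 x ACB (ACNL(32, 1x1) ->
  BN -> ReLU -> MaxPool) -> dropout(0.5) -> global average pool;
* stream 2 (shallow adaptive): 3 x ACB -> dropout(0.5) -> flatten;
* stream 3 (deep): conv64(2,1) -> ReLU -> BN -> MaxPool -> MRN -> global
  average pool.

The flattened stream outputs are fused column-wise (concatenated) and fed
to a softmax output layer (52 classes by default).

Two artifact knobs not part of the printed architecture: ``width_scale``
multiplies every filter count so the graph can train on a CPU, and the 2x2
pooling window degrades to (2,1)/(1,2) when a spatial dimension has shrunk
to 1 (and to identity when both have), which keeps the printed pooling
cascade buildable on 10-12 channel inputs.

Ablation variants (test1..test7) toggle BN, MaxPooling, ACNL and residual
blocks on this same topology; ``full`` is an alias for test7.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .adaptive_conv import AdaptiveConv
from .nn.layers import (
    BatchNorm, Conv2D, Dense, Dropout, Flatten, GlobalAvgPool, MaxPool2D,
    ReLU, Sequential,
)
from .nn.losses import softmax
from .residual import ResidualBlock

VARIANT_FLAGS = {
    #          bn,    pool,  acnl,  res,   stream1 keeps its ACB section
    "test1": (False, False, False, False, True),
    "test2": (True, False, False, False, True),
    "test3": (True, True, False, False, True),
    "test4": (True, True, True, False, True),
    "test5": (True, True, False, True, True),
    "test6": (True, True, True, True, False),
    "test7": (True, True, True, True, True),
}


@dataclass
class ModelConfig:
    num_classes: int = 52
    input_shape: tuple = (512, 10, 1)
    width_scale: float = 1.0
    variant: str = "full"
    dropout_rate: float = 0.5
    acnl_filters: int = 32
    mrn_filters: tuple = (64, 128, 256, 512)
    stem_filters: int = 64
    pool: tuple = (2, 2)

    def __post_init__(self):
        if self.variant != "full" and self.variant not in VARIANT_FLAGS:
            raise ValueError(
                f"unknown variant {self.variant!r}; expected test1..test7 or 'full'")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        for f in (*self.mrn_filters, self.acnl_filters, self.stem_filters):
            if round(self.width_scale * f) < 1:
                raise ValueError(
                    f"width_scale={self.width_scale} scales {f} filters below 1")
        t, c = self.input_shape[0], self.input_shape[1]
        if t < 2 or c < 1:
            raise ValueError(
                f"input shape ({t}, {c}) too small for the pooling cascade; "
                "minimum (T, C) = (2, 1)")

    def scaled(self, filters: int) -> int:
        return int(round(self.width_scale * filters))

    @property
    def flags(self):
        key = "test7" if self.variant == "full" else self.variant
        return VARIANT_FLAGS[key]


class _Builder:
    """Accumulates layers while tracking the (H, W, C) shape."""

    def __init__(self, cfg: ModelConfig, rng):
        self.cfg = cfg
        self.rng = rng
        self.layers = []
        self.h, self.w, self.c = cfg.input_shape

    def pool(self):
        ph = min(self.cfg.pool[0], 2) if self.h >= 2 else 1
        pw = min(self.cfg.pool[1], 2) if self.w >= 2 else 1
        if (ph, pw) == (1, 1):
            return  # both spatial dims exhausted: pooling degrades to identity
        self.layers.append(MaxPool2D((ph, pw)))
        self.h //= ph
        self.w //= pw

    def stem(self, bn, pool):
        f = self.cfg.scaled(self.cfg.stem_filters)
        self.layers.append(Conv2D(f, (2, 1), self.c, padding="same",
                                  use_bias=not bn, rng=self.rng))
        self.layers.append(ReLU())
        if bn:
            self.layers.append(BatchNorm(f))
        self.c = f
        if pool:
            self.pool()

    def mrn(self, res, bn):
        for filters in self.cfg.mrn_filters:
            f = self.cfg.scaled(filters)
            if res:
                self.layers.append(ResidualBlock(f, self.c, rng=self.rng))
            else:
                # plain two-conv stand-in used by the ablation baselines
                self.layers.append(Conv2D(f, (2, 1), self.c,
                                          use_bias=not bn, rng=self.rng))
                if bn:
                    self.layers.append(BatchNorm(f))
                self.layers.append(ReLU())
                self.layers.append(Conv2D(f, (2, 1), f,
                                          use_bias=not bn, rng=self.rng))
                if bn:
                    self.layers.append(BatchNorm(f))
                self.layers.append(ReLU())
            self.c = f

    def acb(self, acnl, bn, pool):
        f = self.cfg.scaled(self.cfg.acnl_filters)
        if acnl:
            self.layers.append(AdaptiveConv(f, (1, 1), self.c, rng=self.rng))
        else:
            self.layers.append(Conv2D(f, (1, 1), self.c, rng=self.rng))
        if bn:
            self.layers.append(BatchNorm(f))
        self.layers.append(ReLU())
        self.c = f
        if pool:
            self.pool()

    def dropout(self):
        self.layers.append(Dropout(self.cfg.dropout_rate, rng=self.rng))

    def gap(self):
        self.layers.append(GlobalAvgPool())

    def flatten(self):
        self.layers.append(Flatten())

    def finish(self, flat_dim):
        stream = Stream(self.layers)
        stream.output_dim = flat_dim
        return stream


class Stream(Sequential):
    """One convolutional stream; emits a rank-2 (batch, features) array."""

    output_dim: int = 0


def build_stream1(cfg: ModelConfig, rng=None) -> Stream:
    """Deep adaptive stream: stem -> MRN -> 3 x ACB -> dropout -> GAP."""
    bn, pool, acnl, res, s1_acb = cfg.flags
    b = _Builder(cfg, rng or np.random.default_rng())
    b.stem(bn, pool)
    b.mrn(res, bn)
    if s1_acb:
        for _ in range(3):
            b.acb(acnl, bn, pool)
    b.dropout()
    b.gap()
    return b.finish(b.c)


def build_stream2(cfg: ModelConfig, rng=None) -> Stream:
    """Shallow adaptive stream: 3 x ACB -> dropout -> flatten."""
    bn, pool, acnl, _res, _ = cfg.flags
    b = _Builder(cfg, rng or np.random.default_rng())
    for _ in range(3):
        b.acb(acnl, bn, pool)
    b.dropout()
    b.flatten()
    return b.finish(b.h * b.w * b.c)


def build_stream3(cfg: ModelConfig, rng=None) -> Stream:
    """Deep residual stream: stem -> MRN -> GAP."""
    bn, pool, _acnl, res, _ = cfg.flags
    b = _Builder(cfg, rng or np.random.default_rng())
    b.stem(bn, pool)
    b.mrn(res, bn)
    b.gap()
    return b.finish(b.c)


def fuse_features(v1, v2, v3):
    """Column-wise fusion: concatenate flat features in stream order."""
    if not (v1.shape[0] == v2.shape[0] == v3.shape[0]):
        raise ValueError(
            f"batch sizes differ: {v1.shape[0]}, {v2.shape[0]}, {v3.shape[0]}")
    return np.concatenate([v1, v2, v3], axis=1)


class MultiStreamModel:
    """Three streams -> column-wise fusion -> dense softmax head."""

    def __init__(self, streams, head: Dense, cfg: ModelConfig):
        self.streams = list(streams)
        self.head = head
        self.cfg = cfg

    def forward(self, inputs, train=False):
        """Logits for a triple of identical window stacks (or one array)."""
        if isinstance(inputs, np.ndarray):
            inputs = (inputs, inputs, inputs)
        feats = [s.forward(x, train=train) for s, x in zip(self.streams, inputs)]
        self._dims = [f.shape[1] for f in feats]
        fused = fuse_features(*feats)
        return self.head.forward(fused, train=train)

    def predict_proba(self, inputs):
        return softmax(self.forward(inputs, train=False))

    def predict(self, inputs):
        return self.predict_proba(inputs).argmax(axis=1)

    def backward(self, dlogits):
        dfused = self.head.backward(dlogits)
        cuts = np.cumsum(self._dims)[:-1]
        parts = np.split(dfused, cuts, axis=1)
        return tuple(s.backward(d) for s, d in zip(self.streams, parts))

    def leaves(self):
        out = []
        for s in self.streams:
            out.extend(s.leaves())
        out.extend(self.head.leaves())
        return out

    def param_count(self) -> int:
        return int(sum(p.size for leaf in self.leaves() for p in leaf.P.values()))

    def get_weights(self):
        return [{k: np.array(v, copy=True) for k, v in leaf.state_items().items()}
                for leaf in self.leaves()]

    def set_weights(self, weights):
        for leaf, stored in zip(self.leaves(), weights):
            for k, ref in leaf.state_items().items():
                ref[...] = stored[k]

    def summary(self) -> list[dict]:
        rows = []
        for i, s in enumerate(self.streams, start=1):
            for layer in s.layers:
                rows.append({
                    "stream": i,
                    "layer": type(layer).__name__,
                    "params": int(sum(p.size for l in layer.leaves()
                                      for p in l.P.values())),
                })
        rows.append({"stream": "head", "layer": "Dense",
                     "params": int(sum(p.size for p in self.head.P.values()))})
        return rows


def build_msacnn_rm(cfg: ModelConfig, seed: int = 0) -> MultiStreamModel:
    """Build the full (or variant) three-stream model with a seeded init."""
    rng = np.random.default_rng(seed)
    s1 = build_stream1(cfg, rng)
    s2 = build_stream2(cfg, rng)
    s3 = build_stream3(cfg, rng)
    fused_dim = s1.output_dim + s2.output_dim + s3.output_dim
    head = Dense(cfg.num_classes, fused_dim, rng=rng)
    return MultiStreamModel([s1, s2, s3], head, cfg)


def build_ablation_variant(test_id: str, cfg: ModelConfig,
                           seed: int = 0) -> MultiStreamModel:
    """Build one of the ablation variants test1..test7 on the same config."""
    if test_id not in VARIANT_FLAGS:
        raise ValueError(f"unknown ablation id {test_id!r}; expected test1..test7")
    variant_cfg = ModelConfig(
        num_classes=cfg.num_classes, input_shape=cfg.input_shape,
        width_scale=cfg.width_scale, variant=test_id,
        dropout_rate=cfg.dropout_rate, acnl_filters=cfg.acnl_filters,
        mrn_filters=cfg.mrn_filters, stem_filters=cfg.stem_filters,
        pool=cfg.pool)
    return build_msacnn_rm(variant_cfg, seed=seed)
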