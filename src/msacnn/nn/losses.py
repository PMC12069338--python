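"""Softmax + categorical cross-entropy with a fused backward pass."""

from __future__ import annotations

import numpy as np


def softmax(z, axis=-1):
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits, onehot):
    """Mean categorical cross-entropy over the batch.

    Returns (loss, dlogits) where dlogits is the gradient of the mean loss
    with respect to the logits: (softmax(z) - y) / n.
    """
    n = logits.shape[0]
    p = softmax(logits)
    eps = 1e-12
    loss = -np.sum(onehot * np.log(p + eps)) / n
    return loss, (p - onehot) / n
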