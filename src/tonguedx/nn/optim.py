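"""Optimizers and loss functions for the numpy network stack."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["SGD", "bce_with_logits", "soft_dice_loss", "softmax_cross_entropy", "softmax"]


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: list[Tensor], lr: float, momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self._velocity = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            v *= self.momentum
            v -= self.lr * p.grad
            p.data += v

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Numerically stable mean binary cross-entropy from raw logits."""
    z = logits.data
    t = np.asarray(targets, dtype=np.float32)
    # loss = max(z,0) - z*t + log(1 + exp(-|z|)), averaged
    val = np.maximum(z, 0.0) - z * t + np.log1p(np.exp(-np.abs(z)))
    out = Tensor(val.mean(), parents=(logits,))

    def bwd(g: np.ndarray) -> None:
        if logits.requires_grad:
            s = 1.0 / (1.0 + np.exp(-z))
            logits._accumulate(g * (s - t) / z.size)

    out._backward = bwd
    return out


def soft_dice_loss(logits: Tensor, targets: np.ndarray, eps: float = 1.0) -> Tensor:
    """1 - soft Dice overlap between sigmoid(logits) and a binary target."""
    p = logits.sigmoid()
    t = Tensor(np.asarray(targets, dtype=np.float32))
    inter = (p * t).sum()
    denom = p.sum() + t.sum() + eps
    return 1.0 - (2.0 * inter + eps) / denom


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: Tensor, labels: np.ndarray, class_weights: np.ndarray | None = None
) -> Tensor:
    """Class-weighted categorical cross-entropy from raw logits.

    ``labels`` are integer class indices; ``class_weights`` (optional) scales
    each sample's loss by the weight of its true class, normalized so the loss
    stays an average.
    """
    z = logits.data
    n = z.shape[0]
    labels = np.asarray(labels, dtype=np.int64)
    p = softmax(z)
    logp = np.log(np.clip(p[np.arange(n), labels], 1e-12, None))
    if class_weights is None:
        w = np.ones(n, dtype=np.float32)
    else:
        w = np.asarray(class_weights, dtype=np.float32)[labels]
    wsum = w.sum()
    out = Tensor(-(w * logp).sum() / wsum, parents=(logits,))

    def bwd(g: np.ndarray) -> None:
        if logits.requires_grad:
            grad = p.copy()
            grad[np.arange(n), labels] -= 1.0
            grad *= (w / wsum)[:, None]
            logits._accumulate(g * grad)

    out._backward = bwd
    return out
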