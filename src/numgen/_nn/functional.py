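"""Stateless numerical primitives shared by the layer classes."""

from __future__ import annotations

import numpy as np


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax along ``axis``."""
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def log_softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - np.max(x, axis=axis, keepdims=True)
    return z - np.log(np.sum(np.exp(z), axis=axis, keepdims=True))


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def cross_entropy(logits: np.ndarray, targets: np.ndarray,
                  reduction: str = "mean") -> float:
    """Categorical cross-entropy of integer ``targets`` under ``logits``.

    ``logits`` has shape ``(..., p)``; ``targets`` the matching leading shape.
    ``reduction`` is ``"mean"`` or ``"sum"`` over all target positions.
    """
    lp = log_softmax(logits, axis=-1)
    picked = np.take_along_axis(lp, targets[..., None], axis=-1)[..., 0]
    if reduction == "mean":
        return float(-np.mean(picked))
    if reduction == "sum":
        return float(-np.sum(picked))
    raise ValueError(f"unknown reduction {reduction!r}")


def cross_entropy_grad(logits: np.ndarray, targets: np.ndarray,
                       reduction: str = "mean") -> np.ndarray:
    """Gradient of :func:`cross_entropy` with respect to ``logits``."""
    g = softmax(logits, axis=-1)
    idx = np.indices(targets.shape)
    g[(*idx, targets)] -= 1.0
    if reduction == "mean":
        g /= targets.size
    return g
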