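"""Softmax and soft-label (mix-up compatible) cross-entropy."""

from __future__ import annotations

import numpy as np

_EPS = 1e-12


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise stable softmax."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_loss(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Batch-mean categorical cross-entropy -mean_i sum_c y_ic log p_ic.

    Accepts soft labels (probability vectors, e.g. from mix-up). Always
    non-negative; zero only for a perfect one-hot match.
    """
    probabilities = np.asarray(probabilities, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if probabilities.shape != labels.shape:
        raise ValueError("probabilities and labels must have identical shapes")
    if not np.all(np.isfinite(probabilities)):
        raise ValueError("probabilities contain non-finite values")
    return float(-(labels * np.log(probabilities + _EPS)).sum(axis=-1).mean())


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Loss and the gradient of the batch-mean cross-entropy w.r.t. logits.

    Returns (loss, probabilities, grad) with grad = (p - y) / batch.
    """
    probs = softmax(np.asarray(logits, dtype=np.float64))
    loss = cross_entropy_loss(probs, labels)
    grad = ((probs - labels) / logits.shape[0]).astype(np.float32)
    return loss, probs, grad
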