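"""Softmax and cross-entropy with analytic gradients."""

from __future__ import annotations

import numpy as np


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over a batch.

    Parameters
    ----------
    logits : (N, C) array
    labels : (N,) integer class indices

    Returns
    -------
    loss : float
    dlogits : (N, C) gradient of the mean loss w.r.t. the logits
    probs : (N, C) softmax probabilities
    """
    logits = np.asarray(logits)
    labels = np.asarray(labels)
    if logits.ndim != 2:
        raise ValueError("logits must be (N, C)")
    n = logits.shape[0]
    if labels.shape != (n,):
        raise ValueError("labels must be (N,)")
    z = logits - logits.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1))
    loss = float(np.mean(lse - z[np.arange(n), labels]))
    probs = softmax(logits)
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits /= n
    return loss, dlogits.astype(logits.dtype), probs
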