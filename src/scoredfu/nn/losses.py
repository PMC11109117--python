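"""Losses returning (scalar loss, gradient w.r.t. logits)."""

from __future__ import annotations

import numpy as np


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over all items (and pixels, for 4-D logits).

    ``logits``: (N, K) or (N, K, H, W); ``labels``: integer array (N,) or
    (N, H, W). Returns (loss, dlogits).
    """
    if logits.ndim == 4:
        n, k, h, w = logits.shape
        flat = logits.transpose(0, 2, 3, 1).reshape(-1, k)
        lab = labels.reshape(-1)
        loss, dflat = softmax_cross_entropy(flat, lab)
        dlogits = dflat.reshape(n, h, w, k).transpose(0, 3, 1, 2)
        return loss, np.ascontiguousarray(dlogits)
    m = logits.shape[0]
    p = softmax(logits, axis=1)
    eps = 1e-12
    loss = float(-np.log(p[np.arange(m), labels] + eps).mean())
    dlogits = p.copy()
    dlogits[np.arange(m), labels] -= 1.0
    dlogits /= m
    return loss, dlogits.astype(np.float32)


def soft_dice_loss(logits: np.ndarray, labels: np.ndarray, smooth: float = 1.0):
    """1 - mean soft Dice over non-background channels; pixel-wise softmax.

    ``logits``: (N, K, H, W); ``labels``: (N, H, W) integer codes < K.
    """
    n, k, h, w = logits.shape
    p = softmax(logits, axis=1)
    onehot = np.zeros_like(p)
    ii = np.arange(n)[:, None, None]
    hh = np.arange(h)[None, :, None]
    ww = np.arange(w)[None, None, :]
    onehot[ii, labels, hh, ww] = 1.0

    dims = (0, 2, 3)
    inter = (p * onehot).sum(axis=dims)
    denom = p.sum(axis=dims) + onehot.sum(axis=dims)
    dice_c = (2.0 * inter + smooth) / (denom + smooth)
    fg = slice(1, k)  # background channel excluded from the objective
    loss = float(1.0 - dice_c[fg].mean())

    # d(dice_c)/dp then through the softmax jacobian
    dp = np.zeros_like(p)
    n_fg = k - 1
    for c in range(1, k):
        num = 2.0 * onehot[:, c] * (denom[c] + smooth) - (2.0 * inter[c] + smooth)
        dp[:, c] = -num / (denom[c] + smooth) ** 2 / n_fg
    dot = (dp * p).sum(axis=1, keepdims=True)
    dlogits = p * (dp - dot)
    return loss, dlogits.astype(np.float32)
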