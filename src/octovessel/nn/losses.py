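"""Softmax cross-entropy for dense (pixel) and vector (patch) outputs."""

from __future__ import annotations

import numpy as np


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray,
    labels: np.ndarray,
    class_weights: np.ndarray | None = None,
    valid_mask: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Mean class-weighted cross-entropy and its gradient w.r.t. the logits.

    ``logits`` is (N, C) or (N, C, H, W); ``labels`` holds integer classes with
    matching non-channel shape.  Pixels where ``valid_mask`` is false are
    excluded from both the mean and the gradient.  The mean is taken over
    valid elements with the per-element class weight as weighting.
    """
    dense = logits.ndim == 4
    if dense:
        n, c, h, w = logits.shape
        flat = logits.transpose(0, 2, 3, 1).reshape(-1, c)
        lab = labels.reshape(-1)
        vm = None if valid_mask is None else valid_mask.reshape(-1).astype(bool)
    else:
        flat, lab = logits, labels
        c = flat.shape[1]
        vm = None if valid_mask is None else valid_mask.astype(bool)
    if vm is None:
        vm = np.ones(flat.shape[0], dtype=bool)
    p = softmax(flat, axis=1)
    wts = np.ones(c, dtype=np.float64) if class_weights is None else np.asarray(class_weights, dtype=np.float64)
    per = wts[lab] * vm
    denom = per.sum()
    if denom <= 0:
        raise ValueError("no valid elements in loss")
    eps = 1e-12
    ll = -np.log(p[np.arange(flat.shape[0]), lab] + eps)
    loss = float((per * ll).sum() / denom)
    onehot = np.zeros_like(flat)
    onehot[np.arange(flat.shape[0]), lab] = 1.0
    dflat = (p - onehot) * (per / denom)[:, None]
    dflat = dflat.astype(np.float32)
    if dense:
        dlogits = dflat.reshape(n, h, w, c).transpose(0, 3, 1, 2)
        return loss, np.ascontiguousarray(dlogits)
    return loss, dflat
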