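"""Generalized Dice loss for multi-label segmentation.

GDL = 1 - 2 * (sum_l w_l sum_n r_ln p_ln) / (sum_l w_l sum_n (r_ln + p_ln))
with inverse-squared class-volume weights w_l = 1 / (sum_n r_ln + eps)^2,
which balances the loss across classes of very different sizes (here the
background dwarfs myocardium and blood pool).
"""

from __future__ import annotations

import numpy as np


def generalized_dice_loss(class_probabilities: np.ndarray,
                          one_hot_reference: np.ndarray,
                          epsilon: float = 1e-5,
                          return_grad: bool = False):
    """Scalar GDL in [0, 1]; optionally also d(loss)/d(probabilities).

    Both inputs are channels-first ``(n_classes, ...)``; probabilities must
    sum to one per voxel.
    """
    p = np.asarray(class_probabilities, dtype=np.float64)
    r = np.asarray(one_hot_reference, dtype=np.float64)
    if p.shape != r.shape:
        raise ValueError(f"shape mismatch: probabilities {p.shape} vs reference {r.shape}")
    n_classes = p.shape[0]
    pf = p.reshape(n_classes, -1)
    rf = r.reshape(n_classes, -1)
    if not np.allclose(pf.sum(axis=0), 1.0, atol=1e-3):
        raise ValueError("class probabilities must sum to 1 per voxel")

    ref_vol = rf.sum(axis=1)
    # inverse-squared class-volume weights; a class absent from the
    # reference gets weight zero (1/eps^2 would otherwise dwarf every
    # present class and collapse training on patches missing a class)
    w = np.where(ref_vol > 0, 1.0 / (ref_vol + epsilon) ** 2, 0.0)  # (C,)
    inter = (rf * pf).sum(axis=1)                        # (C,)
    total = (rf + pf).sum(axis=1)
    num = float((w * inter).sum())
    den = float((w * total).sum())
    loss = 1.0 - 2.0 * num / den
    if not return_grad:
        return loss
    # d/dp_ln [1 - 2 N/D] = -2 (w_l r_ln D - N w_l) / D^2
    grad = (-2.0 * (w[:, None] * rf * den - num * w[:, None]) / den**2)
    return loss, grad.reshape(p.shape)


def softmax_gdl_grad(logits: np.ndarray, one_hot_reference: np.ndarray,
                     epsilon: float = 1e-5):
    """(loss, d loss / d logits) for softmax probabilities under GDL."""
    from .nn import softmax

    p = softmax(logits, axis=0)
    loss, gp = generalized_dice_loss(p, one_hot_reference, epsilon, return_grad=True)
    inner = (gp * p).sum(axis=0, keepdims=True)
    return loss, (p * (gp - inner)).astype(np.float32)
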