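"""Segmentation losses: Lovász-Softmax plus weighted binary cross-entropy.

The training objective is the sum ``L = L_lovasz + L_bce``.  The
Lovász-Softmax term is the Lovász extension of the per-class Jaccard loss
evaluated on the softmax probabilities and averaged over the classes present
in the labels; it directly optimises the intersection-over-union of each
region.  The weighted BCE term treats each class channel one-vs-rest and
scales every pixel's contribution by the weight of that pixel's true class,
counteracting the small share of trabecular pixels.

Each function returns ``(loss, dloss_dprobs)`` so the gradients can be
pushed back through the network's softmax.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "lovasz_grad",
    "lovasz_softmax_loss",
    "weighted_bce_loss",
    "total_loss",
    "softmax_backward",
]

_EPS = 1e-12


def lovasz_grad(gt_sorted: np.ndarray) -> np.ndarray:
    """Gradient of the Lovász extension of the Jaccard loss.

    ``gt_sorted`` is the 0/1 ground-truth vector re-ordered by decreasing
    prediction error; the output is the vector of first differences of the
    Jaccard loss of the growing error set.
    """
    gts = gt_sorted.sum()
    intersection = gts - np.cumsum(gt_sorted)
    union = gts + np.cumsum(1.0 - gt_sorted)
    jaccard = 1.0 - intersection / np.maximum(union, _EPS)
    if len(gt_sorted) > 1:
        jaccard[1:] = jaccard[1:] - jaccard[:-1]
    return jaccard


def _check_shapes(probs: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    if probs.ndim == 3:  # single image (C, H, W)
        probs = probs[None]
        labels = labels[None]
    if probs.ndim != 4 or labels.shape != (
        probs.shape[0],
        probs.shape[2],
        probs.shape[3],
    ):
        raise ValueError(
            f"shape mismatch: probs {probs.shape} vs labels {labels.shape}"
        )
    return probs, labels


def lovasz_softmax_loss(
    probs: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Lovász-Softmax loss averaged over classes present in ``labels``.

    Zero for a confident, fully correct prediction; at most 1 per class.
    """
    probs, labels = _check_shapes(probs, labels)
    n_classes = probs.shape[1]
    dprobs = np.zeros_like(probs)
    losses = []
    flat_labels = labels.reshape(-1)
    for c in range(n_classes):
        fg = (flat_labels == c).astype(float)
        if fg.sum() == 0:
            continue
        p = probs[:, c].reshape(-1)
        errors = np.abs(fg - p)
        order = np.argsort(-errors, kind="stable")
        grad = lovasz_grad(fg[order])
        losses.append(float(errors[order] @ grad))
        # d|fg - p|/dp = -1 on foreground, +1 on background
        derr = np.empty_like(errors)
        derr[order] = grad
        dprobs[:, c] += (np.where(fg > 0, -derr, derr)).reshape(labels.shape)
    if not losses:
        return 0.0, dprobs
    k = len(losses)
    return float(np.mean(losses)), dprobs / k


def weighted_bce_loss(
    probs: np.ndarray,
    labels: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """One-vs-rest binary cross-entropy, pixel-weighted by the true class.

    ``weights`` holds one positive weight per class; a pixel whose true
    label is ``c`` contributes all four of its channel terms scaled by
    ``weights[c]``.  With all weights 1 this is the plain (unweighted)
    binary cross-entropy, averaged over pixels and channels.
    """
    probs, labels = _check_shapes(probs, labels)
    n_classes = probs.shape[1]
    if weights is None:
        weights = np.ones(n_classes)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (n_classes,):
        raise ValueError("one weight per class required")
    if np.any(weights <= 0):
        raise ValueError("class weights must be positive")

    p = np.clip(probs, 1e-7, 1.0 - 1e-7)
    targets = np.stack([(labels == c) for c in range(n_classes)], axis=1).astype(float)
    wpix = weights[labels][:, None]  # (B, 1, H, W)
    terms = -(targets * np.log(p) + (1.0 - targets) * np.log(1.0 - p))
    n = terms.size
    loss = float((wpix * terms).sum() / n)
    dprobs = wpix * (p - targets) / (p * (1.0 - p)) / n
    return loss, dprobs


def total_loss(
    probs: np.ndarray,
    labels: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Training objective ``L = L_lovasz + L_bce`` and its probability gradient."""
    ll, dl = lovasz_softmax_loss(probs, labels)
    lb, db = weighted_bce_loss(probs, labels, weights)
    return ll + lb, dl + db


def softmax_backward(probs: np.ndarray, dprobs: np.ndarray) -> np.ndarray:
    """Map a gradient w.r.t. softmax outputs to one w.r.t. the logits."""
    inner = (dprobs * probs).sum(axis=1, keepdims=True)
    return probs * (dprobs - inner)
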