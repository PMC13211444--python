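"""Training objectives for pCR prediction.

* A supervised contrastive loss on the 128-dim enhanced embeddings: for each
  anchor, same-label batch peers are positives, every other non-self sample
  appears in the denominator; similarities are raw scaled dot products
  ``S_ij = z_i . z_j / tau`` (no L2 normalization by default — a flag enables
  the cosine variant).
* The intra-class similarity ``s_intra,i`` — the mean of ``S_ij`` over the
  positives of ``i`` — fed back to the enhancement module.
* A class-weighted cross-entropy on the classifier output, with weights set
  to the *opposite* class counts of the training split (w1 = #non-pCR,
  w0 = #pCR), so the rare pCR class is up-weighted.
* The dual-loss combination ``L_total = L_cls + lambda * L_CL``.

All loss functions accept either plain ndarrays (returning floats, handy for
testing and evaluation) or autodiff tensors (returning tensors, used in
training).
"""

from __future__ import annotations

import warnings

import numpy as np

from .autodiff import Tensor, relu, softmax
from .nn import Linear, Module

__all__ = [
    "intra_class_similarity",
    "supcon_loss",
    "class_weights_from_counts",
    "weighted_cross_entropy",
    "total_loss",
    "ClassificationHead",
]


def _label_masks(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels).reshape(-1)
    same = labels[:, None] == labels[None, :]
    non_self = ~np.eye(labels.size, dtype=bool)
    return (same & non_self).astype(float), non_self.astype(float)


def _similarity(z: Tensor, tau: float, normalize: bool) -> Tensor:
    if normalize:
        norms = (z * z).sum(axis=1, keepdims=True) ** 0.5
        z = z / (norms + 1e-12)
    return (z @ z.transpose(1, 0)) * (1.0 / tau)


def intra_class_similarity(z, labels, tau: float = 0.1, normalize: bool = False):
    """Mean scaled similarity of each sample to its same-label batch peers.

    Samples without a same-label peer get 0.  Returns (N, 1).
    """
    if tau <= 0:
        raise ValueError("temperature must be positive")
    is_tensor = isinstance(z, Tensor)
    zt = z if is_tensor else Tensor(np.asarray(z, dtype=np.float64))
    pos_mask, _ = _label_masks(labels)
    counts = pos_mask.sum(axis=1)
    safe = np.where(counts > 0, counts, 1.0)
    S = _similarity(zt, tau, normalize)
    sums = (S * Tensor(pos_mask)).sum(axis=1, keepdims=True)
    out = sums * Tensor((np.where(counts > 0, 1.0, 0.0) / safe)[:, None])
    return out if is_tensor else out.data


def supcon_loss(z, labels, tau: float = 0.1, normalize: bool = False):
    """Supervised contrastive loss over one batch.

    Anchors with no positive are skipped; if every anchor is skipped the loss
    is 0 (with a warning).  The denominator runs over all non-self samples;
    log-sum-exp is computed with a detached max shift for stability.
    """
    if tau <= 0:
        raise ValueError("temperature must be positive")
    labels = np.asarray(labels).reshape(-1)
    if labels.size < 2:
        raise ValueError("need at least two samples")
    is_tensor = isinstance(z, Tensor)
    zt = z if is_tensor else Tensor(np.asarray(z, dtype=np.float64))

    pos_mask, nonself_mask = _label_masks(labels)
    counts = pos_mask.sum(axis=1)
    anchors = counts > 0
    if not anchors.any():
        warnings.warn("no anchor has a same-label peer; contrastive loss is 0",
                      stacklevel=2)
        return Tensor(0.0) if is_tensor else 0.0

    S = _similarity(zt, tau, normalize)
    shift = np.where(nonself_mask > 0, S.data, -np.inf).max(axis=1, keepdims=True)
    # mask the (excluded) self-similarities *before* exponentiating: the
    # diagonal can exceed the non-self max and overflow otherwise
    masked = (S - Tensor(shift)) * Tensor(nonself_mask)
    exp_terms = masked.exp() * Tensor(nonself_mask)
    log_denom = exp_terms.sum(axis=1, keepdims=True).log() + Tensor(shift)
    log_prob = S - log_denom  # (N, N); column j = log p(j | anchor i)

    safe_counts = np.where(anchors, counts, 1.0)
    per_anchor = (log_prob * Tensor(pos_mask)).sum(axis=1) * Tensor(1.0 / safe_counts)
    loss = -(per_anchor * Tensor(anchors.astype(float))).sum() * (
        1.0 / float(anchors.sum())
    )
    return loss if is_tensor else float(loss.data)


def class_weights_from_counts(labels, normalize: bool = False) -> tuple[float, float]:
    """(w0, w1) = (#pCR, #non-pCR): each class is weighted by the size of the
    *other* class, so the minority class is up-weighted.  ``normalize`` divides
    both weights by their mean, keeping loss magnitudes comparable across
    cohort sizes."""
    labels = np.asarray(labels).reshape(-1)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present in the training labels")
    w0, w1 = float(n_pos), float(n_neg)
    if normalize:
        mean = 0.5 * (w0 + w1)
        w0, w1 = w0 / mean, w1 / mean
    return w0, w1


def weighted_cross_entropy(probs, labels, w0: float = 1.0, w1: float = 1.0,
                           eps: float = 1e-12):
    """Class-weighted CE over two-class probability rows.

    ``eps`` stabilizes the logarithm when a true-class probability underflows
    to zero.
    """
    labels = np.asarray(labels).reshape(-1).astype(float)
    is_tensor = isinstance(probs, Tensor)
    pt = probs if is_tensor else Tensor(np.asarray(probs, dtype=np.float64))
    p0 = pt[:, 0]
    p1 = pt[:, 1]
    terms = Tensor(w1 * labels) * (p1 + eps).log() + Tensor(
        w0 * (1.0 - labels)
    ) * (p0 + eps).log()
    loss = -terms.mean()
    return loss if is_tensor else float(loss.data)


def total_loss(lcls, lcl, lam: float = 0.9):
    """Dual-loss combination L_total = L_cls + lambda * L_CL."""
    return lcls + lam * lcl


class ClassificationHead(Module):
    """Two-layer MLP (d_in -> hidden -> 2) with softmax-normalized output."""

    def __init__(self, d_in: int = 512, hidden: int = 128,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.fc1 = Linear(d_in, hidden, rng)
        self.fc2 = Linear(hidden, 2, rng)

    def forward(self, ffused: Tensor) -> Tensor:
        return softmax(self.fc2(relu(self.fc1(ffused))), axis=-1)
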