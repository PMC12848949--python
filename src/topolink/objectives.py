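"""Training objectives: contrastive, classification and regularization.

The contrastive term is a multi-positive extension of the temperature-scaled
cross-entropy (NT-Xent / InfoNCE) loss. For a batch of representations and
per-anchor positive sets P(i),

    L = -(1/|A|) * sum_{i in A} log( sum_{j in P(i)} exp(sim(i,j)/tau)
                                     / sum_{k != i} exp(sim(i,k)/tau) )

with ``sim`` the cosine similarity. With a single positive per anchor this
reduces exactly to standard NT-Xent. The denominator runs over every batch
entry except the anchor itself (including the positives), so the loss is
always non-negative. Positives here are the two encoder views of the same
node plus any within-batch entries sharing that node identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, take_per_row, maximum
from .encoders import l2_normalize_rows

__all__ = [
    "PositivePairIndex",
    "LossWeights",
    "multipos_ntxent",
    "l2_regularization",
    "cross_entropy",
    "total_loss",
]


@dataclass
class PositivePairIndex:
    """Anchors and their per-anchor positive sets over a batch.

    ``anchors[t]`` is a batch index; ``positives[t]`` the batch indices
    positive for it. An anchor must not be its own positive.
    """

    anchors: np.ndarray
    positives: list

    def __post_init__(self):
        self.anchors = np.asarray(self.anchors, dtype=np.int64)
        if len(self.anchors) != len(self.positives):
            raise ValueError("anchors and positives must align")
        for a, pos in zip(self.anchors, self.positives):
            if a in np.asarray(pos):
                raise ValueError(f"anchor {a} listed as its own positive")

    @classmethod
    def from_node_ids(cls, node_ids: np.ndarray) -> "PositivePairIndex":
        """Positives = all other batch entries with the same node identity.

        Typical use: the batch stacks the attention-view and the gated-view
        vectors of the same nodes, so each entry's counterpart(s) share its
        node id.
        """
        node_ids = np.asarray(node_ids)
        anchors, positives = [], []
        for i, nid in enumerate(node_ids):
            pos = np.flatnonzero(node_ids == nid)
            pos = pos[pos != i]
            anchors.append(i)
            positives.append(pos)
        return cls(np.array(anchors), positives)


@dataclass
class LossWeights:
    """Weights of the composite objective and the contrastive temperature."""

    alpha: float = 1e-4   # L2 regularization
    beta: float = 0.05    # contrastive
    gamma: float = 1.0    # cross-entropy
    temperature: float = 1.0

    def __post_init__(self):
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("loss weights must be non-negative")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def multipos_ntxent(reps: Tensor, pp: PositivePairIndex, tau: float) -> Tensor:
    """Multi-positive NT-Xent loss over a batch of representations.

    Representations are L2-normalized internally, so similarities are
    cosine. Anchors with an empty positive set are excluded with a warning.
    """
    if tau <= 0:
        raise ValueError("temperature must be positive")
    n = reps.data.shape[0]
    if n < 2:
        raise ValueError("need at least 2 batch entries")

    keep = [t for t in range(len(pp.anchors)) if len(pp.positives[t]) > 0]
    if len(keep) < len(pp.anchors):
        warnings.warn("anchors with empty positive sets excluded from the "
                      "contrastive loss", stacklevel=2)
    if not keep:
        raise ValueError("no anchor has a non-empty positive set")
    anchors = pp.anchors[keep]

    pos_mask = np.zeros((len(anchors), n), dtype=np.float64)
    for r, t in enumerate(keep):
        pos_mask[r, np.asarray(pp.positives[t], dtype=np.int64)] = 1.0
    denom_mask = np.ones((len(anchors), n), dtype=np.float64)
    denom_mask[np.arange(len(anchors)), anchors] = 0.0

    rn = l2_normalize_rows(reps)
    sims = rn @ rn.T
    from .autodiff import rows as _rows
    logits = _rows(sims, anchors) * (1.0 / tau)
    shift = logits.data.max(axis=1, keepdims=True)   # constant under softmax grad
    ex = (logits - shift).exp()
    numer = (ex * pos_mask).sum(axis=1)
    denom = (ex * denom_mask).sum(axis=1)
    return -((numer / denom).log()).mean()


def l2_regularization(params) -> Tensor:
    """Sum of squared entries over the given weight matrices.

    By convention the embedding table and bias vectors are excluded by the
    caller: in a featureless model the embedding norms carry topology
    signal and should not be shrunk.
    """
    total = None
    for w in params:
        term = (w * w).sum()
        total = term if total is None else total + term
    if total is None:
        return Tensor(0.0)
    return total


def cross_entropy(probs: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-probability of the true class.

    ``probs`` rows must be probability distributions (validated to 1e-6);
    a zero probability at the true class is clamped at 1e-12 with a warning.
    """
    labels = np.asarray(labels, dtype=np.int64)
    if probs.data.ndim != 2 or len(labels) != probs.data.shape[0]:
        raise ValueError("probs must be (batch, C) aligned with labels")
    c = probs.data.shape[1]
    if labels.size and (labels.min() < 0 or labels.max() >= c):
        raise ValueError("label out of range")
    row_sums = probs.data.sum(axis=1)
    if np.any(np.abs(row_sums - 1.0) > 1e-6):
        raise ValueError("probability rows must sum to 1")
    p_true = take_per_row(probs, labels)
    if np.any(p_true.data < 1e-12):
        warnings.warn("zero probability at true class clamped to 1e-12",
                      stacklevel=2)
        p_true = maximum(p_true, 1e-12)
    return -(p_true.log()).mean()


def total_loss(reg, cl, ce, w: LossWeights):
    """alpha * L_reg + beta * L_cl + gamma * L_ce."""
    return reg * w.alpha + cl * w.beta + ce * w.gamma
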