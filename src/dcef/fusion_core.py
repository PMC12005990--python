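"""Fused cross-entropy objective with simplex-constrained network weights.

The per-network loss is the standard multinomial softmax cross-entropy on a
linear head: sample ``i`` with deep feature ``x_i`` (row of a feature batch)
is scored by ``x_i @ w`` for a weight matrix ``w`` of shape ``(d, C)``. The
fused objective of a K-network ensemble is

    L_fused = sum_k pi_k * L_k,     sum_k pi_k = 1,  pi_k > 0,

i.e. a convex combination of the per-network cross-entropies with weights
``pi`` on the open probability simplex. Everything here is pure NumPy and
stateless; training lives in :mod:`dcef.fusion_optimizer`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

SIMPLEX_ATOL = 1e-9
#: Floor used when re-projecting weights onto the *open* simplex.
PI_EPS = 1e-6


def _as_float_matrix(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")
    return arr


@dataclass(frozen=True)
class FeatureBatch:
    """Deep features for ``n`` samples from one sub-network.

    ``features`` has shape ``(n, d_k)`` where ``d_k`` is the feature
    dimension of sub-network ``k`` (fixed per network across a run).
    """

    features: np.ndarray
    network_index: int = 0

    def __post_init__(self):
        object.__setattr__(
            self, "features", _as_float_matrix(self.features, "features")
        )
        if self.features.shape[0] < 1:
            raise ValueError("feature batch needs at least one sample")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def dim(self) -> int:
        return self.features.shape[1]


@dataclass(frozen=True)
class ClassifierWeights:
    """Linear softmax head for one sub-network: shape ``(d_k, C)``."""

    weights: np.ndarray

    def __post_init__(self):
        w = _as_float_matrix(self.weights, "weights")
        if w.shape[1] < 2:
            raise ValueError("need at least C=2 classes")
        object.__setattr__(self, "weights", w)

    @property
    def n_classes(self) -> int:
        return self.weights.shape[1]

    @property
    def dim(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class LabelBatch:
    """Integer class indices in ``[0, C-1]``, one per sample.

    The same ground-truth label is shared by every sub-network: the ensemble
    disagrees about features, never about what the sample is.
    """

    labels: np.ndarray

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.ndim != 1:
            raise ValueError("labels must be a 1-D vector")
        if not np.issubdtype(lab.dtype, np.integer):
            as_int = lab.astype(int)
            if not np.array_equal(as_int, lab):
                raise ValueError("labels must be integers")
            lab = as_int
        if lab.size and lab.min() < 0:
            raise ValueError("labels must be nonnegative class indices")
        object.__setattr__(self, "labels", lab)

    @property
    def n(self) -> int:
        return self.labels.shape[0]

    def validate_against(self, n_classes: int) -> None:
        if self.labels.size and self.labels.max() >= n_classes:
            raise ValueError(
                f"label {self.labels.max()} out of range for C={n_classes}"
            )


@dataclass(frozen=True)
class FusionWeights:
    """Ensemble weights ``pi`` on the open probability simplex."""

    pi: np.ndarray

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=float)
        if pi.ndim != 1 or pi.size < 1:
            raise ValueError("pi must be a nonempty 1-D vector")
        if not np.all(np.isfinite(pi)):
            raise ValueError("pi contains non-finite entries")
        if abs(pi.sum() - 1.0) > SIMPLEX_ATOL:
            raise ValueError(f"pi must sum to 1 (got {pi.sum():.12g})")
        if np.any(pi <= 0):
            raise ValueError("every pi_k must be strictly positive")
        object.__setattr__(self, "pi", pi)

    @property
    def k(self) -> int:
        return self.pi.shape[0]

    @staticmethod
    def uniform(k: int) -> "FusionWeights":
        return FusionWeights(np.full(k, 1.0 / k))


def softmax_probs(
    features: FeatureBatch, weights: ClassifierWeights
) -> np.ndarray:
    """Class probabilities ``(n, C)`` from a linear head, via stable softmax.

    Logits are shifted by their row-max before exponentiation so the result
    is exact up to floating point even for large scores.
    """
    if features.dim != weights.dim:
        raise ValueError(
            f"feature dim {features.dim} != weight rows {weights.dim}"
        )
    logits = features.features @ weights.weights
    logits = logits - logits.max(axis=1, keepdims=True)
    expd = np.exp(logits)
    return expd / expd.sum(axis=1, keepdims=True)


def _log_softmax(features: FeatureBatch, weights: ClassifierWeights) -> np.ndarray:
    if features.dim != weights.dim:
        raise ValueError(
            f"feature dim {features.dim} != weight rows {weights.dim}"
        )
    logits = features.features @ weights.weights
    shifted = logits - logits.max(axis=1, keepdims=True)
    return shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))


def cross_entropy(
    features: FeatureBatch,
    weights: ClassifierWeights,
    labels: LabelBatch,
    sample_weights: np.ndarray | None = None,
    reduction: str = "sum",
) -> float:
    """Softmax cross-entropy ``-sum_i s_i log p_{i, y_i}``.

    ``reduction`` is ``"sum"`` (the literal summed form) or ``"mean"``
    (per-sample average, the optimizer default). ``sample_weights`` lets the
    caller inject per-sample class weights for imbalance handling; it
    multiplies the log term and defaults to all ones.
    """
    if labels.n != features.n:
        raise ValueError("labels and features disagree on n")
    labels.validate_against(weights.n_classes)
    if reduction not in ("sum", "mean"):
        raise ValueError(f"unknown reduction {reduction!r}")
    logp = _log_softmax(features, weights)
    picked = logp[np.arange(features.n), labels.labels]
    if sample_weights is not None:
        sw = np.asarray(sample_weights, dtype=float)
        if sw.shape != (features.n,):
            raise ValueError("sample_weights must be length n")
        picked = picked * sw
    total = -float(picked.sum())
    return total / features.n if reduction == "mean" else total


def fused_loss(
    per_network: Sequence[tuple[FeatureBatch, ClassifierWeights]],
    labels: LabelBatch,
    fusion: FusionWeights,
    sample_weights: np.ndarray | None = None,
    reduction: str = "sum",
) -> float:
    """Convex combination ``sum_k pi_k * CE_k`` of per-network losses.

    Exactly linear in ``pi`` for fixed heads, hence always within
    ``[min_k CE_k, max_k CE_k]``.
    """
    if len(per_network) != fusion.k:
        raise ValueError(
            f"got {len(per_network)} networks but {fusion.k} fusion weights"
        )
    ns = {fb.n for fb, _ in per_network}
    if len(ns) > 1:
        raise ValueError("all feature batches must cover the same samples")
    losses = np.array(
        [
            cross_entropy(fb, cw, labels, sample_weights, reduction)
            for fb, cw in per_network
        ]
    )
    return float(fusion.pi @ losses)
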