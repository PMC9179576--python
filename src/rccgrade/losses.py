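"""Objective functions for grading under one-directional label noise and class imbalance.

The training criterion is built from cross-entropy pieces. Writing p_ij for
the predicted probability that sample i belongs to class j, and l_ij for the
one-hot encoding of the observed label y_i:

* plain CE:            L_CE      = -(1/N) sum_i sum_j l_ij log p_ij
* low-grade-only CE:   L_CE0     = -(1/N) sum_i 1[y_i = 0] log p_i0
* mixed loss:          L_mix     = alpha * L_CE + (1 - alpha) * L_CE0
* class-weighted CE:   L_w       = -(1/N) sum_i sum_j lambda_j l_ij log p_ij
* combined objective:  L_total   = alpha * L_w + (1 - alpha) * lambda_0 * L_CE0

The (1 - alpha) term treats observed high-grade labels as unreliable at rate
alpha: it rewards low-grade probability mass but only ever *on samples
labeled low-grade*, never penalizing a high-labeled sample for hedging toward
low. Noise is one-directional (some high-labeled images are truly low-grade;
low-labeled images are trusted), which is why there is no symmetric term.

All losses are defined on probabilities and have closed-form gradients with
respect to logits (see :func:`total_weighted_grad_logits`), which is what the
numpy trainer consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BatchPrediction",
    "LossConfig",
    "ce_loss",
    "ce_class0_loss",
    "mixed_loss",
    "weighted_ce_loss",
    "total_weighted_loss",
    "class_weights_from_counts",
    "total_weighted_grad_logits",
]


@dataclass
class BatchPrediction:
    """A batch of two-class probability rows with their observed labels."""

    probs: np.ndarray  # (N, 2), rows sum to 1
    labels: np.ndarray  # (N,), values in {0, 1}

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.probs.ndim != 2 or self.probs.shape[1] != 2:
            raise ValueError(f"probs must be (N, 2), got {self.probs.shape}")
        if self.probs.shape[0] == 0:
            raise ValueError("empty batch")
        if self.labels.shape != (self.probs.shape[0],):
            raise ValueError("labels length must match probs rows")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0 or 1")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1 (within 1e-6)")

    def __len__(self) -> int:
        return self.probs.shape[0]


@dataclass(frozen=True)
class LossConfig:
    """Noise rate and class weights governing the combined objective.

    ``alpha`` is the assumed label-noise rate among high-labeled samples
    (default 0.4). ``mixing='as_printed'`` weights plain CE by alpha and the
    low-grade term by (1 - alpha); ``'complement'`` swaps the two, for the
    reading under which a noisier dataset should trust the observed labels
    *less*. ``noise_term='class0'`` restricts the auxiliary term to samples
    labeled low-grade; ``'flip_to_low'`` applies -log p_i0 to every sample,
    i.e. learning from a copy of the data with all labels set to low.
    """

    alpha: float = 0.4
    lambda0: float = 1.0
    lambda1: float = 1.0
    epsilon: float = 1e-12
    mixing: str = "as_printed"
    noise_term: str = "class0"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.lambda0 <= 0 or self.lambda1 <= 0:
            raise ValueError("class weights must be positive")
        if self.mixing not in ("as_printed", "complement"):
            raise ValueError(f"unknown mixing {self.mixing!r}")
        if self.noise_term not in ("class0", "flip_to_low"):
            raise ValueError(f"unknown noise_term {self.noise_term!r}")

    @property
    def ce_weight(self) -> float:
        return self.alpha if self.mixing == "as_printed" else 1.0 - self.alpha

    @property
    def aux_weight(self) -> float:
        return 1.0 - self.alpha if self.mixing == "as_printed" else self.alpha


def _logp(batch: BatchPrediction, epsilon: float) -> np.ndarray:
    return np.log(np.clip(batch.probs, epsilon, 1.0))


def ce_loss(batch: BatchPrediction, epsilon: float = 1e-12) -> float:
    """Ordinary mean cross-entropy over the batch."""
    lp = _logp(batch, epsilon)
    n = len(batch)
    return float(-lp[np.arange(n), batch.labels].mean())


def ce_class0_loss(batch: BatchPrediction, epsilon: float = 1e-12, noise_term: str = "class0") -> float:
    """Low-grade cross-entropy term, divided by the full batch size N.

    With ``noise_term='class0'`` only samples labeled low-grade contribute
    (-(1/N) sum_i 1[y_i=0] log p_i0); with ``'flip_to_low'`` every sample
    contributes -log p_i0.
    """
    lp0 = _logp(batch, epsilon)[:, 0]
    n = len(batch)
    if noise_term == "class0":
        return float(-(lp0 * (batch.labels == 0)).sum() / n)
    return float(-lp0.mean())


def mixed_loss(batch: BatchPrediction, config: LossConfig) -> float:
    """Noise-countering mixture of plain CE and the low-grade term."""
    return config.ce_weight * ce_loss(batch, config.epsilon) + config.aux_weight * ce_class0_loss(
        batch, config.epsilon, config.noise_term
    )


def weighted_ce_loss(batch: BatchPrediction, config: LossConfig) -> float:
    """Class-frequency-weighted cross-entropy (weight lambda_j on class-j samples)."""
    lp = _logp(batch, config.epsilon)
    n = len(batch)
    lam = np.where(batch.labels == 0, config.lambda0, config.lambda1)
    return float(-(lam * lp[np.arange(n), batch.labels]).sum() / n)


def total_weighted_loss(batch: BatchPrediction, config: LossConfig) -> float:
    """The combined training objective: weighted CE plus the lambda_0-scaled noise term."""
    aux = config.lambda0 * ce_class0_loss(batch, config.epsilon, config.noise_term)
    return config.ce_weight * weighted_ce_loss(batch, config) + config.aux_weight * aux


def total_weighted_grad_logits(probs: np.ndarray, labels: np.ndarray, config: LossConfig) -> np.ndarray:
    """Gradient of :func:`total_weighted_loss` with respect to the softmax logits.

    For sample i with label y and softmax output p: the weighted-CE piece
    contributes ce_weight * lambda_y * (p - e_y); the noise term contributes
    aux_weight * lambda_0 * (p - e_0) on the samples it covers. Averaged
    over the batch.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels)
    n, k = probs.shape
    onehot = np.zeros((n, k))
    onehot[np.arange(n), labels] = 1.0
    lam = np.where(labels == 0, config.lambda0, config.lambda1)[:, None]
    grad = config.ce_weight * lam * (probs - onehot)
    e0 = np.zeros((n, k))
    e0[:, 0] = 1.0
    if config.noise_term == "class0":
        mask = (labels == 0).astype(np.float64)[:, None]
    else:
        mask = 1.0
    grad = grad + config.aux_weight * config.lambda0 * mask * (probs - e0)
    return grad / n


def class_weights_from_counts(
    n_low: int, n_high: int, scheme: str = "inverse_frequency", alpha: float = 0.4
) -> tuple[float, float]:
    """Derive (lambda0, lambda1) from class counts.

    ``inverse_frequency``: lambda_j = N / (2 n_j), the usual balanced
    weighting. ``noise_adjusted``: accounts for the extra low-grade term in
    the combined objective by equalizing the *expected* per-class
    contribution, solving lambda0 * n_low = alpha * lambda1 * n_high with the
    normalization lambda0 + lambda1 = 2.
    """
    if n_low <= 0 or n_high <= 0:
        raise ValueError("both class counts must be positive")
    if scheme == "inverse_frequency":
        total = n_low + n_high
        return total / (2.0 * n_low), total / (2.0 * n_high)
    if scheme == "noise_adjusted":
        if not 0.0 < alpha <= 1.0:
            raise ValueError("noise_adjusted scheme needs alpha in (0, 1]")
        lam1 = 2.0 * n_low / (n_low + alpha * n_high)
        lam0 = 2.0 * alpha * n_high / (n_low + alpha * n_high)
        return lam0, lam1
    raise ValueError(f"unknown scheme {scheme!r}")
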