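"""Patient-level aggregation, thresholded metrics, and ROC/AUC.

Each patient's per-image high-grade probabilities g_1..g_M are collapsed to a
single score G = max(g_1, ..., g_M): grading follows the most severe-looking
image in the stack. Sensitivity is the true-positive rate on high-grade
patients (the positive class throughout), specificity the true-negative rate
on low-grade patients. The ROC curve and AUC are computed over patient
scores; with ties the AUC equals the Mann-Whitney probability with half
credit for ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .cohort import Cohort, percentage
from .nnet import Model

__all__ = [
    "PatientPrediction",
    "EvalResult",
    "aggregate_patient",
    "score_cohort",
    "classification_metrics",
    "roc_auc",
    "youden_threshold",
]


@dataclass
class PatientPrediction:
    patient_id: str
    image_scores: list[float]
    aggregated_score: float
    true_binary_label: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.image_scores) < 1:
            raise ValueError("a patient prediction needs at least one image score")
        if abs(self.aggregated_score - max(self.image_scores)) > 1e-9:
            raise ValueError("aggregated_score must be the maximum image score")


@dataclass
class EvalResult:
    threshold: Optional[float] = None
    acc: Optional[float] = None
    sen: Optional[float] = None
    spc: Optional[float] = None
    auc: Optional[float] = None
    roc_points: list[tuple[float, float]] = field(default_factory=list)


def aggregate_patient(image_scores: Sequence[float]) -> float:
    """Max-aggregate per-image high-grade probabilities into one patient score."""
    scores = list(image_scores)
    if not scores:
        raise ValueError("cannot aggregate an empty score list")
    if min(scores) < 0.0 or max(scores) > 1.0:
        raise ValueError("image scores must be probabilities in [0, 1]")
    return float(max(scores))


def score_cohort(model: Model, cohort: Cohort, transform=None, batch_size: int = 256) -> list[PatientPrediction]:
    """One PatientPrediction per patient, image scores in the patient's image order.

    ``transform`` (e.g. a resize_or_pad closure) is applied per image before
    inference; without it, images must already be uniformly sized.
    """
    preds = []
    for patient in cohort:
        if patient.n_images == 0:
            raise ValueError(f"patient {patient.patient_id!r} has no images")
        imgs = [img.pixels for img in patient.images]
        if transform is not None:
            imgs = [transform(im) for im in imgs]
        x = np.stack(imgs).astype(np.float32)
        g = model.predict_proba(x, batch_size=batch_size)[:, 1]
        preds.append(
            PatientPrediction(
                patient_id=patient.patient_id,
                image_scores=[float(v) for v in g],
                aggregated_score=aggregate_patient(g),
                true_binary_label=patient.binary_label,
            )
        )
    return preds


def _labels_scores(predictions: Sequence[PatientPrediction]) -> tuple[np.ndarray, np.ndarray]:
    if any(p.true_binary_label is None for p in predictions):
        raise ValueError("all predictions must carry true labels")
    y = np.array([p.true_binary_label for p in predictions])
    s = np.array([p.aggregated_score for p in predictions])
    return y, s


def classification_metrics(predictions: Sequence[PatientPrediction], threshold: float = 0.5) -> EvalResult:
    """ACC / SEN / SPC (one-decimal percentages) at a score threshold.

    A patient is called high-grade when G >= threshold. Requires both classes
    to be present, otherwise sensitivity or specificity is undefined.
    """
    y, s = _labels_scores(predictions)
    if len(set(y.tolist())) < 2:
        raise ValueError("metrics need both classes present (sen/spc undefined otherwise)")
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    return EvalResult(
        threshold=threshold,
        acc=percentage(tp + tn, len(y)),
        sen=percentage(tp, tp + fn),
        spc=percentage(tn, tn + fp),
    )


def roc_auc(predictions: Sequence[PatientPrediction]) -> EvalResult:
    """ROC points over all distinct thresholds and the trapezoidal AUC."""
    y, s = _labels_scores(predictions)
    if len(set(y.tolist())) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = _sk_roc_curve(y, s)
    return EvalResult(auc=float(_sk_auc(fpr, tpr)), roc_points=list(zip(fpr.tolist(), tpr.tolist())))


def youden_threshold(predictions: Sequence[PatientPrediction]) -> float:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Meant to be computed on development-side predictions and then applied to
    the validation cohort; choosing it on validation data would tune the
    operating point on the evaluation set. Ties break toward the smallest
    qualifying threshold.
    """
    y, s = _labels_scores(predictions)
    if len(set(y.tolist())) < 2:
        raise ValueError("Youden threshold needs both classes present")
    fpr, tpr, thr = _sk_roc_curve(y, s)
    j = tpr - fpr
    best = float(j.max())
    # sklearn's thresholds are descending; pick the smallest score achieving best J
    candidates = [float(t) for t, v in zip(thr, j) if v >= best - 1e-12]
    return min(min(candidates), 1.0)
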