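"""AUC-weighted combination of per-patient scores from several trained models.

The weight rule exploits that well-trained models tend to land in the same
AUC decile: stripping the shared decile digit (0.864 -> 0.064) stretches the
small differences between models into large relative weight differences,
so the stronger models dominate the weighted average. When the deciles
differ, the smallest decile is subtracted from every AUC instead, which
extends the rule continuously while preserving the ordering. The combined
patient score is the weight-normalized convex combination of the models'
aggregated scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .evaluation import PatientPrediction, aggregate_patient

__all__ = ["EnsembleSpec", "decile_stripped_weights", "ensemble_patient", "ensemble_cohort"]


@dataclass
class EnsembleSpec:
    model_ids: list[str]
    aucs: list[float]
    weights: list[float]

    def __post_init__(self) -> None:
        if not (len(self.model_ids) == len(self.aucs) == len(self.weights)):
            raise ValueError("model_ids, aucs and weights must have equal length")
        if any(w <= 0 for w in self.weights):
            raise ValueError("ensemble weights must all be positive")

    @classmethod
    def from_aucs(cls, model_ids: list[str], aucs: list[float], rule: str = "decile_stripped") -> "EnsembleSpec":
        if rule == "decile_stripped":
            weights = decile_stripped_weights(aucs)
        elif rule == "raw_auc":
            weights = [float(a) for a in aucs]
        else:
            raise ValueError(f"unknown weight rule {rule!r}")
        return cls(model_ids=list(model_ids), aucs=[float(a) for a in aucs], weights=weights)


def _decile(auc: float) -> float:
    # tiny nudge so values sitting exactly on a decile boundary floor cleanly
    return math.floor(10.0 * auc + 1e-9) / 10.0


def decile_stripped_weights(aucs: Sequence[float]) -> list[float]:
    """Weights gamma_k = AUC_k minus the shared decile (or the minimum decile).

    (0.864, 0.822, 0.830, 0.859) -> (0.064, 0.022, 0.030, 0.059). Raises if
    any AUC lies outside (0, 1) or a weight comes out non-positive (an AUC
    exactly on the minimum decile boundary).
    """
    aucs = [float(a) for a in aucs]
    if not aucs:
        raise ValueError("need at least one AUC")
    if any(not 0.0 < a < 1.0 for a in aucs):
        raise ValueError(f"AUCs must lie strictly in (0, 1), got {aucs}")
    d_min = min(_decile(a) for a in aucs)
    weights = [a - d_min for a in aucs]
    if any(w <= 0 for w in weights):
        raise ValueError(
            f"decile-stripped weights must be positive, got {weights}; use the raw_auc rule"
        )
    return weights


def ensemble_patient(scores: Sequence[float], weights: Sequence[float]) -> float:
    """Weight-normalized convex combination of one patient's per-model scores."""
    if len(scores) != len(weights):
        raise ValueError(f"got {len(scores)} scores but {len(weights)} weights")
    if any(w <= 0 for w in weights):
        raise ValueError("weights must be positive")
    return float(np.average(np.asarray(scores, dtype=float), weights=np.asarray(weights, dtype=float)))


def ensemble_cohort(
    per_model_predictions: Sequence[Sequence[PatientPrediction]], spec: EnsembleSpec
) -> list[PatientPrediction]:
    """Combine K aligned prediction lists into one, matching patients by id."""
    if len(per_model_predictions) != len(spec.weights):
        raise ValueError("number of prediction lists must match the ensemble spec")
    by_id = []
    for preds in per_model_predictions:
        d = {p.patient_id: p for p in preds}
        if len(d) != len(preds):
            raise ValueError("duplicate patient_id within one model's predictions")
        by_id.append(d)
    ref_ids = [p.patient_id for p in per_model_predictions[0]]
    for k, d in enumerate(by_id[1:], start=1):
        missing = set(ref_ids) ^ set(d)
        if missing:
            raise ValueError(f"patient id(s) {sorted(missing)} not shared with model {k}")
    out = []
    for pid in ref_ids:
        combined = ensemble_patient([d[pid].aggregated_score for d in by_id], spec.weights)
        ref = by_id[0][pid]
        out.append(
            PatientPrediction(
                patient_id=pid,
                image_scores=[combined],
                aggregated_score=combined,
                true_binary_label=ref.true_binary_label,
            )
        )
    return out
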