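"""Out-of-distribution scoring, distribution-shift control and OOD-guarded
conformal inference.

Slides or patients unlike anything in training (other tissue types, other
scanners, other cohorts) silently break both plain classification and the
conformal coverage guarantee, because exchangeability with the calibration
data fails.  Two unit-level scores flag them:

* probability-based: 1 − (1/N) Σᵢ max_k p̂(ŷ_k|xᵢ) over the unit's tiles —
  high when the classifier is indifferent everywhere;
* uncertainty-based: the mean of the δ lowest tile-level uncertainties
  (default δ=200) — even the *most* confident tiles of an OOD unit carry
  high GP variance.

A decision threshold is set on in-distribution reference scores at a target
FPR (or on mixed scores at a target TPR/precision).  ``dsc_filter`` applies
it before transfer to an external cohort; ``guarded_inference`` combines it
with conformal risk control so that coverage over surviving units stays at
1−α even when some OOD units escape detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import precision_recall_curve, roc_auc_score, roc_curve

from trustwsi.conformal import NEVER_COVERED, RiskController, crc_predict, evaluate

__all__ = [
    "OODScorer",
    "dsc_filter",
    "evaluate_detection",
    "guarded_inference",
    "probability_ood_score",
    "threshold_at_fpr",
    "threshold_at_tpr",
    "uncertainty_ood_score",
    "unit_scores",
]


def probability_ood_score(tile_probs: np.ndarray) -> float:
    """1 − mean over the unit's tiles of the max-class probability.

    Lies in [0, 1 − 1/K]; 0 when every tile is classified with certainty.
    """
    tile_probs = np.atleast_2d(np.asarray(tile_probs, dtype=float))
    if tile_probs.shape[0] == 0:
        raise ValueError("unit has no tiles")
    return float(1.0 - tile_probs.max(axis=1).mean())


def uncertainty_ood_score(tile_uncertainties: np.ndarray, delta: int = 200) -> float:
    """Mean uncertainty of the unit's ``min(δ, N)`` lowest-uncertainty tiles.

    Default δ=200; δ is clipped to the number of tiles.
    """
    u = np.asarray(tile_uncertainties, dtype=float).ravel()
    if u.size == 0:
        raise ValueError("unit has no tiles")
    d = min(int(delta), u.size)
    return float(np.sort(u)[:d].mean())


@dataclass
class OODScorer:
    """Unit-level OOD scorer with a fitted decision threshold.

    ``mode`` selects the score; ``threshold_basis`` records how the
    threshold was chosen (target fpr on in-distribution scores, or target
    tpr on OOD scores).  Units with score > threshold are treated as OOD.
    """

    mode: str = "uncertainty"
    delta: int = 200
    threshold: float = np.inf
    threshold_basis: str = "fpr"

    def score_unit(self, tile_probs=None, tile_uncertainties=None) -> float:
        if self.mode == "probability":
            return probability_ood_score(tile_probs)
        if self.mode == "uncertainty":
            return uncertainty_ood_score(tile_uncertainties, self.delta)
        raise ValueError(f"unknown OOD score mode {self.mode!r}")

    def fit_threshold_fpr(self, scores_in: np.ndarray, fpr: float) -> float:
        self.threshold = threshold_at_fpr(scores_in, fpr)
        self.threshold_basis = "fpr"
        return self.threshold

    def fit_threshold_tpr(self, scores_out: np.ndarray, tpr: float) -> float:
        self.threshold = threshold_at_tpr(scores_out, tpr)
        self.threshold_basis = "tpr"
        return self.threshold

    def is_ood(self, scores: np.ndarray) -> np.ndarray:
        return np.asarray(scores, dtype=float) > self.threshold


def unit_scores(
    manifest,
    tile_probs: np.ndarray,
    tile_uncertainties: np.ndarray,
    level: str = "patient",
    mode: str = "uncertainty",
    delta: int = 200,
):
    """Pooled per-unit OOD scores: all of a unit's tiles together.

    Returns ``(unit_ids, scores)`` with units in first-appearance order.
    """
    key = "patient_id" if level == "patient" else "slide_id"
    ids, scores = [], []
    for uid, idx in manifest.groupby(key, sort=False).indices.items():
        ids.append(uid)
        if mode == "probability":
            scores.append(probability_ood_score(tile_probs[idx]))
        else:
            scores.append(uncertainty_ood_score(tile_uncertainties[idx], delta))
    return np.asarray(ids, dtype=object), np.asarray(scores)


def threshold_at_fpr(scores_in: np.ndarray, fpr: float) -> float:
    """Threshold on in-distribution reference scores such that ~``fpr`` of
    them exceed it (the empirical (1−fpr)-quantile)."""
    scores_in = np.asarray(scores_in, dtype=float)
    if not (0.0 <= fpr <= 1.0):
        raise ValueError("fpr must lie in [0, 1]")
    if fpr == 0.0:
        return float(np.inf)
    return float(np.quantile(scores_in, 1.0 - fpr))


def threshold_at_tpr(scores_out: np.ndarray, tpr: float) -> float:
    """Threshold such that ~``tpr`` of OOD reference scores exceed it."""
    scores_out = np.asarray(scores_out, dtype=float)
    if not (0.0 <= tpr <= 1.0):
        raise ValueError("tpr must lie in [0, 1]")
    if tpr >= 1.0:
        return float(np.nextafter(scores_out.min(), -np.inf))
    return float(np.quantile(scores_out, 1.0 - tpr))


def evaluate_detection(
    scores_in: np.ndarray,
    scores_out: np.ndarray,
    target_precision: float = 0.95,
    target_fpr: float = 0.2,
) -> dict:
    """Standard OOD-detection metrics with OOD as the positive class.

    Returns AUROC, the precision-recall curve, TPR at the target precision,
    and the score threshold at the target FPR (computed on in-distribution
    scores only).
    """
    scores_in = np.asarray(scores_in, dtype=float)
    scores_out = np.asarray(scores_out, dtype=float)
    if scores_in.size == 0 or scores_out.size == 0:
        raise ValueError("both score groups must be nonempty")
    y = np.concatenate([np.zeros(scores_in.size), np.ones(scores_out.size)])
    s = np.concatenate([scores_in, scores_out])
    if np.all(s == s[0]):
        warnings.warn("constant scores: AUROC is 0.5 by convention", stacklevel=2)
        auroc = 0.5
        prec, rec, _ = (np.array([1.0]), np.array([0.0]), None)
        tpr_at_prec = 0.0
    else:
        auroc = float(roc_auc_score(y, s))
        prec, rec, _ = precision_recall_curve(y, s)
        ok = prec[:-1] >= target_precision
        tpr_at_prec = float(rec[:-1][ok].max()) if ok.any() else 0.0
    return {
        "auroc": auroc,
        "pr_curve": {"precision": prec.tolist(), "recall": rec.tolist()},
        "tpr_at_precision": tpr_at_prec,
        "target_precision": target_precision,
        "threshold_at_fpr": threshold_at_fpr(scores_in, target_fpr),
        "target_fpr": target_fpr,
    }


def dsc_filter(unit_ids: np.ndarray, unit_scores_: np.ndarray, threshold: float) -> dict:
    """Distribution-shift control: exclude external units whose OOD score
    exceeds the reference threshold before inference/CP."""
    unit_ids = np.asarray(unit_ids, dtype=object)
    s = np.asarray(unit_scores_, dtype=float)
    keep = s <= threshold
    return {
        "retained_ids": unit_ids[keep],
        "excluded_ids": unit_ids[~keep],
        "n_retained": int(keep.sum()),
        "n_excluded": int((~keep).sum()),
        "threshold": float(threshold),
    }


def guarded_inference(
    unit_probs: np.ndarray,
    unit_labels: np.ndarray,
    unit_ood_scores: np.ndarray,
    scorer: OODScorer,
    controller: RiskController,
) -> dict:
    """OOD-guarded conformal inference over a mixed In-D/OOD stream.

    Units whose OOD score exceeds the scorer's threshold are rejected;
    survivors receive CRC prediction sets from ``controller``.  Labels equal
    to ``NEVER_COVERED`` mark true-OOD units.  Reports empirical coverage
    over surviving in-distribution units (the quantity the CRC calibration
    is meant to protect) as well as over all survivors.
    """
    unit_probs = np.atleast_2d(np.asarray(unit_probs, dtype=float))
    unit_labels = np.asarray(unit_labels, dtype=int)
    rejected = scorer.is_ood(unit_ood_scores)
    survivors = ~rejected
    result = {
        "n_units": int(len(unit_labels)),
        "n_rejected": int(rejected.sum()),
        "rejected": rejected,
    }
    if not survivors.any():
        result.update({"survivor_eval": None, "coverage_ind_survivors": None, "sets": None})
        return result
    sets = crc_predict(unit_probs[survivors], controller)
    labels_s = unit_labels[survivors]
    ev = evaluate(sets, labels_s)
    ind = labels_s != NEVER_COVERED
    cov_ind = (
        float(sets[np.flatnonzero(ind), labels_s[ind]].mean()) if ind.any() else None
    )
    result.update(
        {
            "sets": sets,
            "survivor_eval": ev,
            "coverage_ind_survivors": cov_ind,
            "n_ind_survivors": int(ind.sum()),
            "n_ood_survivors": int((~ind).sum()),
        }
    )
    return result
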