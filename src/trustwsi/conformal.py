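"""Split conformal prediction and conformal risk control.

Split (inductive) conformal prediction turns any classifier's probabilities
into prediction *sets* with a finite-sample marginal coverage guarantee: with
nonconformity score s(x, y) = 1 - p̂(y|x) computed on R held-out calibration
points, the threshold q̂ is the ⌈(R+1)(1-α)⌉-th smallest calibration score,
and the set Γ(x) = {k : s(x, k) ≤ q̂} contains the true label with
probability in [1-α, 1-α + 1/(R+1)] under exchangeability.

Conformal risk control (CRC) generalizes this to a monotone loss — here,
miscoverage in the presence of out-of-distribution units that can never be
covered.  The prediction set Γ_ρ(x) = {k : p̂(x)_k ≥ 1-ρ} grows with ρ, and
the smallest ρ̂ achieving empirical coverage ≥ 1-α on a (possibly
contaminated) calibration stream is found by bisection.

For binary problems the set size has a direct clinical reading: size 1 is a
definitive call, size 2 is an abstention deferring to a human, and size 0
flags a unit unlike anything in calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConformalCalibrator",
    "PredictionSetResult",
    "RiskController",
    "calibrate",
    "categorize",
    "crc_calibrate",
    "crc_predict",
    "evaluate",
    "nonconformity",
    "predict_set",
]

SINGLE_CORRECT = "single_correct"
SINGLE_INCORRECT = "single_incorrect"
ABSTENTION = "abstention"
EMPTY = "empty"

#: label value marking units (e.g. OOD) that no prediction set can cover
NEVER_COVERED = -1


def nonconformity(probs: np.ndarray, labels) -> np.ndarray:
    """Nonconformity score s(x, y) = 1 - p̂(x)_y.

    ``probs`` is (n, K) rows on the simplex (a single row is accepted);
    ``labels`` integer class indices.
    """
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    labels = np.atleast_1d(np.asarray(labels, dtype=int))
    if labels.min() < 0 or labels.max() >= probs.shape[1]:
        raise ValueError("label out of range")
    return 1.0 - probs[np.arange(len(labels)), labels]


@dataclass(frozen=True)
class ConformalCalibrator:
    """Calibrated split-CP threshold at error level ``alpha``.

    ``q_hat`` is the ⌈(R+1)(1-α)⌉-th smallest calibration score, or +inf when
    that index exceeds the calibration size R (small R / small α), in which
    case every prediction set contains all labels.
    """

    alpha: float
    scores: np.ndarray
    q_hat: float

    @property
    def R(self) -> int:
        return len(self.scores)


def calibrate(scores: np.ndarray, alpha: float) -> ConformalCalibrator:
    """Compute q̂ from calibration nonconformity scores."""
    scores = np.asarray(scores, dtype=float).ravel()
    if scores.size == 0:
        raise ValueError("calibration scores must be nonempty")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    R = scores.size
    k = math.ceil((R + 1) * (1.0 - alpha))
    if k > R:
        q_hat = float("inf")
    else:
        q_hat = float(np.sort(scores)[k - 1])
    return ConformalCalibrator(alpha=alpha, scores=np.sort(scores), q_hat=q_hat)


def predict_set(probs: np.ndarray, calibrator: ConformalCalibrator) -> np.ndarray:
    """Prediction sets Γ(x) = {k : 1 - p̂(x)_k ≤ q̂} as a boolean (n, K) mask.

    Ties at q̂ are included; empty sets are representable (all-False rows).
    """
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    return (1.0 - probs) <= calibrator.q_hat


@dataclass(frozen=True)
class PredictionSetResult:
    """Per-unit prediction sets with sizes and outcome categories."""

    sets: np.ndarray  # (n, K) boolean
    set_size: np.ndarray  # (n,)
    category: np.ndarray  # (n,) of strings, only when labels were supplied


def categorize(sets: np.ndarray, labels: np.ndarray) -> PredictionSetResult:
    """Assign each unit its outcome category given the true label.

    ``single_correct`` / ``single_incorrect`` for size-1 sets, ``abstention``
    for all-label sets (size K), ``empty`` for size 0.  Units labelled
    ``NEVER_COVERED`` (e.g. OOD) can only be abstention/empty/single_incorrect.
    """
    sets = np.atleast_2d(np.asarray(sets, dtype=bool))
    labels = np.asarray(labels, dtype=int)
    n, K = sets.shape
    size = sets.sum(axis=1)
    covered = np.zeros(n, dtype=bool)
    valid = labels >= 0
    covered[valid] = sets[np.flatnonzero(valid), labels[valid]]
    cat = np.empty(n, dtype=object)
    cat[size == 0] = EMPTY
    cat[size == K] = ABSTENTION
    singleton = (size >= 1) & (size < K)
    # for K=2 "singleton" is exactly size 1; for K>2 partial sets count as
    # abstention-free multi-label calls and are categorized by coverage
    cat[singleton & (size == 1) & covered] = SINGLE_CORRECT
    cat[singleton & (size == 1) & ~covered] = SINGLE_INCORRECT
    multi = singleton & (size > 1)
    cat[multi] = ABSTENTION
    return PredictionSetResult(sets=sets, set_size=size, category=cat)


def evaluate(sets: np.ndarray, labels: np.ndarray) -> dict:
    """Coverage, efficiency and the diagnosis-attempt breakdown.

    Returns coverage (fraction of sets containing the truth), mean set size,
    counts per category, and the definitive-answer (DA) error rate: among
    singleton predictions, the fraction that are incorrect — ``None`` when
    there is no singleton.
    """
    sets = np.atleast_2d(np.asarray(sets, dtype=bool))
    labels = np.asarray(labels, dtype=int)
    if len(sets) != len(labels):
        raise ValueError("sets and labels must be aligned")
    res = categorize(sets, labels)
    valid = labels >= 0
    covered = np.zeros(len(labels), dtype=bool)
    covered[valid] = sets[np.flatnonzero(valid), labels[valid]]
    counts = {
        c: int((res.category == c).sum())
        for c in (SINGLE_CORRECT, SINGLE_INCORRECT, ABSTENTION, EMPTY)
    }
    n_single = counts[SINGLE_CORRECT] + counts[SINGLE_INCORRECT]
    da_error = counts[SINGLE_INCORRECT] / n_single if n_single else None
    return {
        "n": len(labels),
        "coverage": float(covered.mean()) if len(labels) else None,
        "mean_set_size": float(res.set_size.mean()) if len(labels) else None,
        "breakdown": counts,
        "da_error": da_error,
    }


@dataclass(frozen=True)
class RiskController:
    """Calibrated CRC threshold ρ̂ for sets Γ_ρ(x) = {k : p̂(x)_k ≥ 1-ρ}.

    ``target_coverage`` is the finite-sample-corrected empirical coverage
    the calibration stream must reach so that the *expected* miscoverage of
    new units is bounded by α (for a monotone loss bounded by 1 on R
    calibration units: R·miscoverage + 1 ≤ (R+1)·α).  ``infeasible`` is set
    when even ρ=1 (all-label sets) cannot reach it — e.g. when the
    contaminating OOD fraction exceeds α.
    """

    rho_hat: float
    alpha: float
    tolerance: float
    target_coverage: float = 1.0
    infeasible: bool = False


def _crc_coverage(probs: np.ndarray, labels: np.ndarray, rho: float) -> float:
    """Empirical coverage of Γ_ρ; NEVER_COVERED labels count as misses."""
    valid = labels >= 0
    hit = np.zeros(len(labels), dtype=float)
    idx = np.flatnonzero(valid)
    hit[idx] = probs[idx, labels[idx]] >= 1.0 - rho
    return float(hit.mean())


def crc_calibrate(
    probs_cal: np.ndarray,
    labels_cal: np.ndarray,
    alpha: float,
    tolerance: float = 1e-4,
    max_iter: int = 64,
) -> RiskController:
    """Find the smallest ρ̂ whose calibration coverage meets the corrected
    target by bisection.

    The finite-sample target is coverage ≥ 1 − ((R+1)·α − 1)/R on the R
    calibration units (the upper-confidence form of the risk bound with a
    loss bounded by 1), which guarantees expected miscoverage ≤ α on
    exchangeable new units; for large R it approaches 1 − α.  The
    calibration stream may contain undetected OOD units, marked with label
    ``NEVER_COVERED``; their miscoverage is charged at every ρ, which is
    what forces ρ̂ (and hence set sizes) up under contamination.
    """
    probs_cal = np.atleast_2d(np.asarray(probs_cal, dtype=float))
    labels_cal = np.asarray(labels_cal, dtype=int)
    if len(probs_cal) != len(labels_cal):
        raise ValueError("probs and labels must be aligned")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    R = len(labels_cal)
    if R == 0:
        raise ValueError("calibration stream must be nonempty")
    max_miscoverage = ((R + 1) * alpha - 1.0) / R
    target = 1.0 - max_miscoverage  # may exceed 1 for tiny R: then infeasible
    if _crc_coverage(probs_cal, labels_cal, 1.0) < target:
        return RiskController(
            rho_hat=1.0, alpha=alpha, tolerance=tolerance,
            target_coverage=target, infeasible=True,
        )
    lo, hi = 0.0, 1.0
    if _crc_coverage(probs_cal, labels_cal, lo) >= target:
        return RiskController(
            rho_hat=0.0, alpha=alpha, tolerance=tolerance, target_coverage=target
        )
    for _ in range(max_iter):
        if hi - lo <= tolerance:
            break
        mid = 0.5 * (lo + hi)
        if _crc_coverage(probs_cal, labels_cal, mid) >= target:
            hi = mid
        else:
            lo = mid
    return RiskController(
        rho_hat=float(hi), alpha=alpha, tolerance=tolerance, target_coverage=target
    )


def crc_predict(probs: np.ndarray, controller: RiskController) -> np.ndarray:
    """CRC prediction sets Γ_ρ̂(x) = {k : p̂(x)_k ≥ 1-ρ̂} as boolean mask."""
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    return probs >= 1.0 - controller.rho_hat
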