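"""Hierarchical aggregation and evaluation metrics.

Tile-level class probabilities are averaged (unweighted) within each slide,
and slide-level probabilities averaged within each patient — the two-stage
mean, never a direct tile pool, so that slides contribute equally to a
patient regardless of tile count.  On top sit the evaluation metrics:
accuracy/AUROC, demographic fairness gaps (max − min of a metric over
subgroups, small groups merged into "Others"), and attention efficiency
(the precision of a model's top-attention tiles against reference-relevant
regions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

__all__ = [
    "FairnessReport",
    "HierarchyResult",
    "aggregate",
    "attention_efficiency",
    "classification_metrics",
    "fairness_gaps",
]


@dataclass
class HierarchyResult:
    """Per-unit probabilities and labels at one level of the hierarchy."""

    level: str
    unit_ids: np.ndarray
    probs: np.ndarray
    labels: np.ndarray
    subgroup: pd.DataFrame | None = None


def aggregate(tile_probs: np.ndarray, manifest: pd.DataFrame) -> dict[str, HierarchyResult]:
    """Two-stage unweighted aggregation: tiles → slides → patients.

    ``manifest`` rows must align with ``tile_probs``; tiles already
    eliminated must be absent from both.  Slides with zero remaining tiles
    simply do not appear; patients whose every slide vanished are excluded
    with a warning.
    """
    tile_probs = np.atleast_2d(np.asarray(tile_probs, dtype=float))
    if len(tile_probs) != len(manifest):
        raise ValueError("tile_probs and manifest must be aligned")
    K = tile_probs.shape[1]
    df = manifest[["slide_id", "patient_id", "weak_label", "sex", "race"]].copy()
    for k in range(K):
        df[f"p{k}"] = tile_probs[:, k]
    pcols = [f"p{k}" for k in range(K)]

    slide = df.groupby("slide_id", sort=False).agg(
        {**{c: "mean" for c in pcols}, "patient_id": "first", "weak_label": "first",
         "sex": "first", "race": "first"}
    )
    patient = slide.groupby("patient_id", sort=False).agg(
        {**{c: "mean" for c in pcols}, "weak_label": "first", "sex": "first", "race": "first"}
    )

    all_patients = manifest["patient_id"].nunique()
    if len(patient) < all_patients:
        warnings.warn(
            f"{all_patients - len(patient)} patient(s) lost all slides during "
            "aggregation",
            stacklevel=2,
        )

    out = {}
    out["tile"] = HierarchyResult(
        "tile",
        manifest["tile_id"].to_numpy(),
        tile_probs,
        manifest["weak_label"].to_numpy(),
        manifest[["sex", "race"]],
    )
    out["slide"] = HierarchyResult(
        "slide",
        slide.index.to_numpy(),
        slide[pcols].to_numpy(),
        slide["weak_label"].to_numpy(),
        slide[["sex", "race"]].reset_index(drop=True),
    )
    out["patient"] = HierarchyResult(
        "patient",
        patient.index.to_numpy(),
        patient[pcols].to_numpy(),
        patient["weak_label"].to_numpy(),
        patient[["sex", "race"]].reset_index(drop=True),
    )
    return out


@dataclass
class FairnessReport:
    """Per-subgroup metric values and the max−min fairness gap."""

    attribute: str
    metric: str
    per_group: dict[str, float]
    group_sizes: dict[str, int]
    gap: float | None


def fairness_gaps(
    values: np.ndarray,
    subgroup_labels: np.ndarray,
    attribute: str = "race",
    metric: str = "accuracy",
    min_group_size: int = 20,
) -> FairnessReport:
    """Fairness gap: max − min of the mean per-unit ``values`` (0/1 correct
    flags for accuracy, set sizes for CP efficiency) across subgroups.

    Groups with fewer than ``min_group_size`` units are merged into
    "Others"; with a single group after merging the gap is undefined
    (``None``).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(subgroup_labels, dtype=object).copy()
    counts = pd.Series(groups).value_counts()
    small = set(counts[counts < min_group_size].index)
    if small:
        groups = np.array(["Others" if g in small else g for g in groups], dtype=object)
    per_group, sizes = {}, {}
    for g in pd.unique(groups):
        sel = groups == g
        per_group[str(g)] = float(values[sel].mean())
        sizes[str(g)] = int(sel.sum())
    gap = max(per_group.values()) - min(per_group.values()) if len(per_group) > 1 else None
    return FairnessReport(
        attribute=attribute, metric=metric, per_group=per_group, group_sizes=sizes, gap=gap
    )


def attention_efficiency(
    attention_scores: np.ndarray,
    relevance: np.ndarray,
    removal_fraction: float = 0.0,
) -> float:
    """Fraction of the model's top-attention tiles that are also in the
    reference-relevant set.

    Keeps the top ``1 - removal_fraction`` of tiles by attention (ties broken
    by stable tile order) and returns |kept ∩ relevant| / |kept|.
    """
    a = np.asarray(attention_scores, dtype=float).ravel()
    r = np.asarray(relevance).ravel().astype(bool)
    if a.shape != r.shape:
        raise ValueError("attention and relevance must be aligned")
    if not (0.0 <= removal_fraction < 1.0):
        raise ValueError("removal_fraction must lie in [0, 1)")
    if np.all(a == 0):
        raise ValueError("all-zero attention scores")
    n_keep = max(1, int(round((1.0 - removal_fraction) * a.size)))
    order = np.argsort(-a, kind="stable")
    kept = order[:n_keep]
    return float(r[kept].mean())


def classification_metrics(probs: np.ndarray, labels: np.ndarray) -> dict:
    """Threshold-0.5 accuracy and rank AUROC for binary class probabilities.

    AUROC is ``None`` when only one class is present.
    """
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    labels = np.asarray(labels, dtype=int)
    p1 = probs[:, 1] if probs.shape[1] > 1 else probs[:, 0]
    acc = float(((p1 > 0.5).astype(int) == labels).mean())
    if len(np.unique(labels)) < 2:
        auroc = None
    else:
        auroc = float(roc_auc_score(labels, p1))
    return {"accuracy": acc, "auroc": auroc, "n": int(len(labels))}
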