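"""Elimination of ambiguous tiles (EAT).

Weak slide-level supervision attaches the slide's diagnosis to every tile,
including tiles (stroma, necrosis, normal tissue) that carry no subtype
signal.  The ambiguity score of a tile under a binary classifier M,

    s(x, M) = 1 - |p(y=0|x,M) - p(y=1|x,M)|,

is near 0 for tiles the model can call confidently and near 1 for
uninformative ones.  EAT removes ambiguous tiles before training and/or
aggregation, in one of three modes:

* ``cluster`` — k-means on latent tile representations (k chosen by the
  silhouette coefficient); clusters whose slide-label mix lacks a dominant
  class are flagged ambiguous and all their tiles dropped (new tiles are
  assigned to the nearest center).  Typical use: retrain the tile classifier
  on the surviving tiles.
* ``threshold`` — keep the ``retain_rate`` fraction of tiles with the lowest
  ambiguity score (per cohort), using any proxy tile classifier's
  probabilities; the bag-level model is reused without retraining.
* ``random`` — drop the same number of tiles uniformly at random; the
  control baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from trustwsi.synthetic import TileTable

__all__ = [
    "AmbiguityIndex",
    "ambiguity_score",
    "eliminate",
    "fit_clusters",
    "identify_ambiguous",
    "select_k",
    "train_proxy_classifier",
]


def ambiguity_score(probs: np.ndarray) -> np.ndarray:
    """s(x, M) = 1 - |p₀ - p₁| for binary class probabilities (n, 2)."""
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    if probs.shape[1] != 2:
        raise ValueError("ambiguity score is defined for binary classifiers only")
    return 1.0 - np.abs(probs[:, 0] - probs[:, 1])


def select_k(
    embeddings: np.ndarray,
    k_range=range(2, 7),
    seed: int = 0,
    subsample: int = 20_000,
) -> int:
    """Pick the cluster count maximizing the mean silhouette coefficient of
    k-means assignments (subsampled above ``subsample`` points)."""
    X = np.asarray(embeddings, dtype=float)
    ks = sorted(k_range)
    if len(ks) < 2:
        raise ValueError("k_range must contain at least two candidate values")
    if len(X) <= max(ks):
        raise ValueError("need more points than the largest candidate k")
    if np.allclose(X, X[0]):
        raise ValueError("degenerate data: all points identical")
    rng = np.random.default_rng(seed)
    if len(X) > subsample:
        X = X[rng.choice(len(X), subsample, replace=False)]
    best_k, best_s = ks[0], -np.inf
    for k in ks:
        km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(X)
        s = silhouette_score(X, km.labels_)
        if s > best_s:
            best_k, best_s = k, s
    return best_k


@dataclass
class AmbiguityIndex:
    """Fitted elimination rule.

    ``mode`` selects the elimination strategy; cluster mode carries k-means
    ``centers`` and the set of ``ambiguous_ids``; threshold and random modes
    carry ``retain_rate``.
    """

    mode: str = "cluster"
    k: int = 3
    centers: np.ndarray | None = None
    assignments: np.ndarray | None = None
    inertia: float | None = None
    ambiguous_ids: frozenset = frozenset()
    dominance_threshold: float = 0.7
    retain_rate: float = 1.0
    seed: int = 0
    cluster_stats: pd.DataFrame | None = None

    def assign(self, embeddings: np.ndarray) -> np.ndarray:
        """Nearest-Euclidean-center cluster assignment for new tiles."""
        if self.centers is None:
            raise ValueError("index has no fitted centers")
        X = np.asarray(embeddings, dtype=float)
        d2 = ((X[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)


def fit_clusters(embeddings: np.ndarray, k: int, seed: int = 0) -> AmbiguityIndex:
    """k-means over latent tile representations with a fixed seed."""
    X = np.asarray(embeddings, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(X):
        raise ValueError("k exceeds the number of points")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(X)
    return AmbiguityIndex(
        mode="cluster",
        k=k,
        centers=km.cluster_centers_,
        assignments=km.labels_.copy(),
        inertia=float(km.inertia_),
        seed=seed,
    )


def identify_ambiguous(
    assignments: np.ndarray,
    slide_labels: np.ndarray,
    dominance_threshold: float = 0.7,
    scores: np.ndarray | None = None,
) -> tuple[frozenset, pd.DataFrame]:
    """Flag clusters not dominated by either slide label.

    A cluster is ambiguous iff its largest weak-label fraction is below
    ``dominance_threshold``.  Returns the flagged cluster ids and a
    per-cluster table (size, label fractions, mean ambiguity score when
    scores are given — expected higher in flagged clusters).
    """
    assignments = np.asarray(assignments)
    slide_labels = np.asarray(slide_labels)
    rows = []
    flagged = set()
    for cid in np.unique(assignments):
        sel = assignments == cid
        if not sel.any():
            continue
        labels = slide_labels[sel]
        frac1 = float((labels == 1).mean())
        dominance = max(frac1, 1.0 - frac1)
        is_amb = dominance < dominance_threshold
        if is_amb:
            flagged.add(int(cid))
        rows.append(
            {
                "cluster": int(cid),
                "n_tiles": int(sel.sum()),
                "frac_label1": frac1,
                "dominance": dominance,
                "ambiguous": is_amb,
                "mean_ambiguity": float(scores[sel].mean()) if scores is not None else np.nan,
            }
        )
    return frozenset(flagged), pd.DataFrame(rows)


def build_cluster_index(
    embeddings: np.ndarray,
    slide_labels: np.ndarray,
    k: int | None = None,
    k_range=range(2, 7),
    dominance_threshold: float = 0.7,
    scores: np.ndarray | None = None,
    seed: int = 0,
) -> AmbiguityIndex:
    """Convenience: select k (unless given), fit clusters and flag the
    ambiguous ones in one call."""
    if k is None:
        k = select_k(embeddings, k_range=k_range, seed=seed)
    index = fit_clusters(embeddings, k, seed=seed)
    flagged, stats = identify_ambiguous(
        index.assignments, slide_labels, dominance_threshold, scores=scores
    )
    index.ambiguous_ids = flagged
    index.dominance_threshold = dominance_threshold
    index.cluster_stats = stats
    return index


def eliminate(
    tiles: TileTable,
    index: AmbiguityIndex,
    scores: np.ndarray | None = None,
    latents: np.ndarray | None = None,
) -> tuple[TileTable, pd.DataFrame]:
    """Apply the elimination rule; returns the filtered cohort and a
    per-tile report (tile_id, score, cluster, kept).

    Cluster mode assigns each tile to its nearest center (``latents``
    defaults to the raw embeddings) and drops tiles in ambiguous clusters.
    Threshold mode keeps the ``retain_rate`` fraction with lowest ambiguity
    ``scores`` cohort-wide.  Random mode drops ``1 - retain_rate`` of tiles
    uniformly at random (seeded).  Slides losing all their tiles are
    reported with a warning; they must be excluded from aggregation.
    """
    n = len(tiles)
    clusters = np.full(n, -1)
    if index.mode == "cluster":
        X = latents if latents is not None else tiles.embeddings
        clusters = index.assign(X)
        kept = ~np.isin(clusters, list(index.ambiguous_ids))
    elif index.mode == "threshold":
        if scores is None:
            raise ValueError("threshold mode requires ambiguity scores")
        scores = np.asarray(scores, dtype=float)
        n_keep = max(1, int(round(index.retain_rate * n)))
        order = np.argsort(scores, kind="stable")
        kept = np.zeros(n, dtype=bool)
        kept[order[:n_keep]] = True
    elif index.mode == "random":
        rng = np.random.default_rng(index.seed)
        n_keep = max(1, int(round(index.retain_rate * n)))
        kept = np.zeros(n, dtype=bool)
        kept[rng.choice(n, n_keep, replace=False)] = True
    else:
        raise ValueError(f"unknown elimination mode {index.mode!r}")

    report = pd.DataFrame(
        {
            "tile_id": tiles.manifest["tile_id"],
            "score": scores if scores is not None else np.nan,
            "cluster": clusters,
            "kept": kept,
        }
    )
    filtered = tiles.subset(kept)
    lost = set(tiles.manifest["slide_id"].unique()) - set(filtered.manifest["slide_id"].unique())
    if lost:
        warnings.warn(
            f"{len(lost)} slide(s) lost all tiles during elimination and must "
            "be excluded from aggregation",
            stacklevel=2,
        )
    return filtered, report


def train_proxy_classifier(tiles: TileTable, seed: int = 0):
    """Logistic-regression proxy tile classifier for the foundation-model
    path: consumes raw embeddings, emits per-tile binary probabilities for
    ambiguity scoring (the interface any tabular learner could fill)."""
    from sklearn.linear_model import LogisticRegression

    clf = LogisticRegression(max_iter=1000, random_state=seed)
    clf.fit(tiles.embeddings, tiles.labels.astype(int))
    return clf
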