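"""End-to-end experiment protocols on synthetic cohorts.

The simulation protocol mirrors a standard weakly supervised WSI study:
patients are split 65/15/20 into training / validation / calibration+testing,
the tile classifier is trained per replicate, and conformal prediction is
established and evaluated over many random calibration/test splits of the
held-out 20% (100 calibration patients by default).  Results are reported as
means over ``n_replicates`` models x ``n_cp_splits`` splits.

Also here: the OOD-guarded coverage experiments (detector + conformal risk
control on mixed In-D/OOD streams), the split-CP validity experiment, and
the tile-elimination comparison (EAT vs random elimination vs none).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from trustwsi import conformal
from trustwsi.conformal import NEVER_COVERED
from trustwsi.eat import (
    AmbiguityIndex,
    ambiguity_score,
    build_cluster_index,
    eliminate,
    train_proxy_classifier,
)
from trustwsi.metrics import aggregate, classification_metrics, fairness_gaps
from trustwsi.ood import OODScorer, guarded_inference, threshold_at_fpr, threshold_at_tpr, unit_scores
from trustwsi.sngp import SNGPConfig, SNGPModel, train_tile_classifier
from trustwsi.synthetic import CohortConfig, TileTable, default_cluster_means, generate_cohort, generate_ood_cohort

__all__ = [
    "ExperimentConfig",
    "cp_validity_experiment",
    "eat_comparison",
    "guarded_coverage_experiment",
    "run_protocol",
    "split_patients",
    "threshold_retention_sweep",
    "tpr_sweep_experiment",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Top-level protocol settings (defaults mirror the full study design:
    20 model replicates, 500 CP splits, 100 calibration patients)."""

    alphas: tuple[float, ...] = (0.1, 0.05, 0.01)
    level: str = "patient"
    n_replicates: int = 20
    n_cp_splits: int = 500
    n_cal_patients: int = 100
    split_fractions: tuple[float, float, float] = (0.65, 0.15, 0.20)
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    sngp: SNGPConfig = field(default_factory=SNGPConfig)


def split_patients(
    tiles: TileTable, fractions: tuple[float, float, float], rng: np.random.Generator
):
    """Patient-level split into (train, validation, calibration+test) id sets."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    patients = tiles.patients()
    order = rng.permutation(len(patients))
    n = len(patients)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    train = patients[order[:n_train]]
    val = patients[order[n_train : n_train + n_val]]
    caltest = patients[order[n_train + n_val :]]
    return train, val, caltest


def _patient_table(tiles: TileTable, probs: np.ndarray) -> pd.DataFrame:
    """Patient-level probabilities/labels/subgroups from tile probabilities."""
    res = aggregate(probs, tiles.manifest)["patient"]
    df = pd.DataFrame(
        {
            "patient_id": res.unit_ids,
            "p0": res.probs[:, 0],
            "p1": res.probs[:, 1],
            "label": res.labels,
        }
    )
    df[["sex", "race"]] = res.subgroup.to_numpy()
    return df


def _cp_over_splits(
    patient_df: pd.DataFrame,
    alphas,
    n_splits: int,
    n_cal: int,
    rng: np.random.Generator,
) -> dict:
    """Split-CP metrics averaged over random calibration/test splits."""
    probs = patient_df[["p0", "p1"]].to_numpy()
    labels = patient_df["label"].to_numpy().astype(int)
    n = len(patient_df)
    # keep at least a fifth (and at least 10) of the units for testing
    n_cal = min(n_cal, n - max(10, n // 5))
    acc = {
        a: {"coverage": [], "mean_set_size": [], "da_error": [], "breakdown": []}
        for a in alphas
    }
    set_sizes_by_group = {a: [] for a in alphas}
    groups = patient_df["race"].to_numpy()
    for _ in range(n_splits):
        order = rng.permutation(n)
        cal, test = order[:n_cal], order[n_cal:]
        scores = conformal.nonconformity(probs[cal], labels[cal])
        for a in alphas:
            calib = conformal.calibrate(scores, a)
            sets = conformal.predict_set(probs[test], calib)
            ev = conformal.evaluate(sets, labels[test])
            acc[a]["coverage"].append(ev["coverage"])
            acc[a]["mean_set_size"].append(ev["mean_set_size"])
            acc[a]["da_error"].append(ev["da_error"])
            acc[a]["breakdown"].append(ev["breakdown"])
            rep = fairness_gaps(
                sets.sum(axis=1), groups[test], attribute="race", metric="mean_set_size"
            )
            set_sizes_by_group[a].append(rep.gap if rep.gap is not None else np.nan)
    out = {}
    for a in alphas:
        da = [d for d in acc[a]["da_error"] if d is not None]
        breakdown = {
            k: float(np.mean([b[k] for b in acc[a]["breakdown"]]))
            for k in acc[a]["breakdown"][0]
        }
        gaps = [g for g in set_sizes_by_group[a] if not np.isnan(g)]
        out[str(a)] = {
            "coverage": float(np.mean(acc[a]["coverage"])),
            "coverage_se": float(np.std(acc[a]["coverage"]) / np.sqrt(n_splits)),
            "mean_set_size": float(np.mean(acc[a]["mean_set_size"])),
            "da_error": float(np.mean(da)) if da else None,
            "breakdown": breakdown,
            "set_size_race_gap": float(np.mean(gaps)) if gaps else None,
        }
    return out


def run_protocol(config: ExperimentConfig) -> dict:
    """Run the full replicated protocol and return the summary dictionary.

    Per replicate: fresh cohort seed, 65/15/20 patient split, SNGP training
    on train+validation, tile probabilities on the held-out 20%, patient
    aggregation, then ``n_cp_splits`` random calibration/test splits per
    error level.  Fairness gaps (accuracy by sex and race) and plain
    classification metrics are computed on the held-out patients.
    """
    master = np.random.SeedSequence(config.seed)
    rep_seeds = master.spawn(config.n_replicates)
    per_alpha = {str(a): [] for a in config.alphas}
    cls_rows, fair_rows = [], []
    for r, ss in enumerate(rep_seeds):
        rng = np.random.default_rng(ss)
        cseed = int(rng.integers(0, 2**31 - 1))
        cohort = generate_cohort(replace(config.cohort, seed=cseed))
        train_p, val_p, caltest_p = split_patients(cohort, config.split_fractions, rng)
        trainval = cohort.subset_patients(np.concatenate([train_p, val_p]))
        vf = config.split_fractions[1] / (config.split_fractions[0] + config.split_fractions[1])
        scfg = replace(config.sngp, seed=int(rng.integers(0, 2**31 - 1)), val_fraction=vf)
        model = train_tile_classifier(trainval, scfg)
        held = cohort.subset_patients(caltest_p)
        out = model.predict(held.embeddings)
        pdf = _patient_table(held, out.probs)
        cp = _cp_over_splits(
            pdf, config.alphas, config.n_cp_splits, config.n_cal_patients, rng
        )
        for a in config.alphas:
            per_alpha[str(a)].append(cp[str(a)])
        cls_rows.append(
            classification_metrics(pdf[["p0", "p1"]].to_numpy(), pdf["label"].to_numpy())
        )
        correct = (
            (pdf["p1"].to_numpy() > 0.5).astype(int) == pdf["label"].to_numpy()
        ).astype(float)
        for attr in ("sex", "race"):
            rep_f = fairness_gaps(correct, pdf[attr].to_numpy(), attribute=attr)
            fair_rows.append({"attribute": attr, "gap": rep_f.gap, "per_group": rep_f.per_group})

    def _mean(key, rows):
        vals = [r[key] for r in rows if r[key] is not None]
        return float(np.mean(vals)) if vals else None

    summary = {
        "protocol": {
            "n_replicates": config.n_replicates,
            "n_cp_splits": config.n_cp_splits,
            "n_cal_patients": config.n_cal_patients,
            "split_fractions": list(config.split_fractions),
            "seed": config.seed,
            "level": config.level,
        },
        "classification": {
            "accuracy": _mean("accuracy", cls_rows),
            "auroc": _mean("auroc", cls_rows),
        },
        "conformal": {},
        "fairness": {},
    }
    for a in config.alphas:
        rows = per_alpha[str(a)]
        summary["conformal"][str(a)] = {
            "coverage": _mean("coverage", rows),
            "mean_set_size": _mean("mean_set_size", rows),
            "da_error": _mean("da_error", rows),
            "set_size_race_gap": _mean("set_size_race_gap", rows),
            "breakdown": {
                k: float(np.mean([r["breakdown"][k] for r in rows]))
                for k in rows[0]["breakdown"]
            },
        }
    for attr in ("sex", "race"):
        gaps = [r["gap"] for r in fair_rows if r["attribute"] == attr and r["gap"] is not None]
        summary["fairness"][attr] = {
            "accuracy_gap": float(np.mean(gaps)) if gaps else None
        }
    return summary


# ---------------------------------------------------------------------------
# split-CP validity


def cp_validity_experiment(
    seeds=(0, 1, 2, 3, 4),
    alphas=(0.1, 0.05, 0.01),
    n_splits: int = 500,
    n_cal: int = 100,
    cohort_cfg: CohortConfig | None = None,
    sngp_cfg: SNGPConfig | None = None,
) -> dict:
    """Marginal-coverage check of split CP on full pipeline outputs.

    Per generator seed: train the tile classifier, aggregate to patients,
    then average empirical coverage over ``n_splits`` random splits with
    ``n_cal`` calibration patients.  Returns per-alpha mean coverage (to be
    compared with the [1-a, 1-a+1/(R+1)] sandwich).
    """
    cohort_cfg = cohort_cfg or CohortConfig(
        n_patients_per_class=130, tiles_per_slide=(15, 25)
    )
    sngp_cfg = sngp_cfg or SNGPConfig(hidden_sizes=(32, 32), D_L=128, epochs=10)
    cov = {a: [] for a in alphas}
    for seed in seeds:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
        cohort = generate_cohort(replace(cohort_cfg, seed=seed))
        train_p, val_p, held_p = split_patients(cohort, (0.3, 0.1, 0.6), rng)
        model = train_tile_classifier(
            cohort.subset_patients(np.concatenate([train_p, val_p])),
            replace(sngp_cfg, seed=seed, val_fraction=0.25),
        )
        held = cohort.subset_patients(held_p)
        probs = model.predict(held.embeddings).probs
        pdf = _patient_table(held, probs)
        P = pdf[["p0", "p1"]].to_numpy()
        y = pdf["label"].to_numpy().astype(int)
        n = len(pdf)
        for _ in range(n_splits):
            order = rng.permutation(n)
            cal, test = order[:n_cal], order[n_cal:]
            scores = conformal.nonconformity(P[cal], y[cal])
            for a in alphas:
                calib = conformal.calibrate(scores, a)
                sets = conformal.predict_set(P[test], calib)
                cov[a].append(float(sets[np.arange(len(test)), y[test]].mean()))
    return {
        a: {
            "mean_coverage": float(np.mean(cov[a])),
            "se": float(np.std(cov[a]) / np.sqrt(len(cov[a]))),
            "R": n_cal,
        }
        for a in alphas
    }


# ---------------------------------------------------------------------------
# OOD-guarded coverage


def _fit_and_score(seed: int, cohort_cfg: CohortConfig, sngp_cfg: SNGPConfig, n_ood: int):
    """Train one model and return per-patient probabilities / OOD scores for
    held-out In-D patients and an OOD cohort."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 29]))
    cfg = replace(cohort_cfg, seed=seed)
    cohort = generate_cohort(cfg)
    train_p, val_p, held_p = split_patients(cohort, (0.5, 0.15, 0.35), rng)
    model = train_tile_classifier(
        cohort.subset_patients(np.concatenate([train_p, val_p])),
        replace(sngp_cfg, seed=seed, val_fraction=0.23),
    )
    held = cohort.subset_patients(held_p)
    ood = generate_ood_cohort(cfg, n_ood)

    def patient_probs_scores(table):
        out = model.predict(table.embeddings)
        pdf = _patient_table(table, out.probs)
        ids, sc = unit_scores(
            table.manifest, out.probs, out.uncertainty, level="patient", mode="uncertainty"
        )
        sdf = pd.Series(sc, index=ids)
        pdf["ood_score"] = sdf.loc[pdf["patient_id"]].to_numpy()
        return pdf

    pdf_in = patient_probs_scores(held)
    pdf_ood = patient_probs_scores(ood)
    pdf_ood["label"] = NEVER_COVERED
    return pdf_in, pdf_ood


def guarded_coverage_experiment(
    seeds=(0, 1, 2, 3, 4),
    ratios=(0.25, 0.5, 1.0, 2.0),
    alpha: float = 0.05,
    n_splits: int = 500,
    detector_fpr: float = 0.05,
    cohort_cfg: CohortConfig | None = None,
    sngp_cfg: SNGPConfig | None = None,
    n_ood_patients: int = 120,
    disable_safeguards: bool = False,
) -> dict:
    """Coverage of OOD-detector + CRC pipelines on mixed streams.

    Per seed and OOD-to-In-D ratio, over ``n_splits`` resampled splits: a
    contaminated calibration stream (held-out In-D calibration patients plus
    OOD patients at the same ratio) fixes the uncertainty-score threshold
    (at ``detector_fpr`` on its In-D part) and calibrates CRC on the
    post-filter survivors; guarded inference then runs on an independent
    contaminated test stream.  With ``disable_safeguards`` both the detector
    and CRC are switched off (plain split CP on everything), the deployment
    failure mode whose coverage dilutes toward (1-alpha)/(1+ratio).

    Returns per-ratio mean coverage over In-D survivors with its Monte-Carlo
    standard error, plus the pooled mean.
    """
    cohort_cfg = cohort_cfg or CohortConfig(n_patients_per_class=80, tiles_per_slide=(15, 25))
    sngp_cfg = sngp_cfg or SNGPConfig(hidden_sizes=(32, 32), D_L=128, epochs=10)
    by_ratio = {r: [] for r in ratios}
    set_sizes = {r: [] for r in ratios}
    for seed in seeds:
        pdf_in, pdf_ood = _fit_and_score(seed, cohort_cfg, sngp_cfg, n_ood_patients)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))
        P_in = pdf_in[["p0", "p1"]].to_numpy()
        y_in = pdf_in["label"].to_numpy().astype(int)
        s_in = pdf_in["ood_score"].to_numpy()
        P_ood = pdf_ood[["p0", "p1"]].to_numpy()
        s_ood = pdf_ood["ood_score"].to_numpy()
        n_in = len(pdf_in)
        n_half = n_in // 2
        for ratio in ratios:
            for _ in range(n_splits):
                order = rng.permutation(n_in)
                cal, test = order[:n_half], order[n_half:]
                n_ood_cal = min(int(round(ratio * n_half)), len(P_ood))
                n_ood_test = min(int(round(ratio * (n_in - n_half))), len(P_ood))
                ood_idx = rng.permutation(len(P_ood))
                oc = ood_idx[:n_ood_cal]
                ot = ood_idx[n_ood_cal : n_ood_cal + n_ood_test]
                probs_c = np.vstack([P_in[cal], P_ood[oc]])
                labels_c = np.concatenate([y_in[cal], np.full(len(oc), NEVER_COVERED)])
                scores_c = np.concatenate([s_in[cal], s_ood[oc]])
                probs_t = np.vstack([P_in[test], P_ood[ot]])
                labels_t = np.concatenate([y_in[test], np.full(len(ot), NEVER_COVERED)])
                scores_t = np.concatenate([s_in[test], s_ood[ot]])
                if disable_safeguards:
                    scores_cal = conformal.nonconformity(P_in[cal], y_in[cal])
                    calib = conformal.calibrate(scores_cal, alpha)
                    sets = conformal.predict_set(probs_t, calib)
                    ev = conformal.evaluate(sets, labels_t)
                    by_ratio[ratio].append(ev["coverage"])
                    set_sizes[ratio].append(ev["mean_set_size"])
                else:
                    scorer = OODScorer(mode="uncertainty")
                    scorer.fit_threshold_fpr(s_in[cal], detector_fpr)
                    keep_c = ~scorer.is_ood(scores_c)
                    ctl = conformal.crc_calibrate(probs_c[keep_c], labels_c[keep_c], alpha)
                    res = guarded_inference(probs_t, labels_t, scores_t, scorer, ctl)
                    if res["coverage_ind_survivors"] is not None:
                        by_ratio[ratio].append(res["coverage_ind_survivors"])
                        set_sizes[ratio].append(res["survivor_eval"]["mean_set_size"])
    out = {"alpha": alpha, "ratios": {}}
    pooled = []
    for r in ratios:
        v = np.asarray(by_ratio[r], dtype=float)
        pooled.extend(v)
        out["ratios"][str(r)] = {
            "coverage": float(v.mean()),
            "se": float(v.std() / np.sqrt(len(v))),
            "mean_set_size": float(np.mean(set_sizes[r])),
            "n": int(len(v)),
        }
    pooled = np.asarray(pooled)
    out["mean_coverage"] = float(pooled.mean())
    out["se"] = float(pooled.std() / np.sqrt(len(pooled)))
    return out


def tpr_sweep_experiment(
    seeds=(0, 1, 2, 3, 4),
    tprs=(0.5, 0.8, 0.95, 1.0),
    alpha: float = 0.05,
    n_splits: int = 500,
    cohort_cfg: CohortConfig | None = None,
    sngp_cfg: SNGPConfig | None = None,
    n_ood_patients: int = 120,
) -> dict:
    """Split-CP coverage on a 1:1 In-D/OOD mixture as detector TPR -> 1.

    The OOD-score threshold is swept to hit each target TPR on an OOD
    reference pool; retained units (detector negatives) receive standard
    split-CP sets calibrated on clean In-D calibration patients.  As TPR
    approaches 1 the retained stream is again exchangeable with calibration
    and coverage returns to 1-alpha.
    """
    cohort_cfg = cohort_cfg or CohortConfig(n_patients_per_class=80, tiles_per_slide=(15, 25))
    sngp_cfg = sngp_cfg or SNGPConfig(hidden_sizes=(32, 32), D_L=128, epochs=10)
    cov = {t: [] for t in tprs}
    for seed in seeds:
        pdf_in, pdf_ood = _fit_and_score(seed, cohort_cfg, sngp_cfg, n_ood_patients)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 37]))
        P_in = pdf_in[["p0", "p1"]].to_numpy()
        y_in = pdf_in["label"].to_numpy().astype(int)
        s_in = pdf_in["ood_score"].to_numpy()
        P_ood = pdf_ood[["p0", "p1"]].to_numpy()
        s_ood = pdf_ood["ood_score"].to_numpy()
        n_in = len(pdf_in)
        n_half = n_in // 2
        for _ in range(n_splits):
            order = rng.permutation(n_in)
            cal, test = order[:n_half], order[n_half:]
            n_test = n_in - n_half
            ot = rng.permutation(len(P_ood))[: min(n_test, len(P_ood))]  # 1:1 mixture
            probs_t = np.vstack([P_in[test], P_ood[ot]])
            labels_t = np.concatenate([y_in[test], np.full(len(ot), NEVER_COVERED)])
            scores_t = np.concatenate([s_in[test], s_ood[ot]])
            cal_scores = conformal.nonconformity(P_in[cal], y_in[cal])
            calib = conformal.calibrate(cal_scores, alpha)
            for t in tprs:
                thr = threshold_at_tpr(s_ood, t)
                retained = scores_t <= thr
                if not retained.any():
                    continue
                sets = conformal.predict_set(probs_t[retained], calib)
                ev = conformal.evaluate(sets, labels_t[retained])
                cov[t].append(ev["coverage"])
    out = {"alpha": alpha, "tpr": {}}
    for t in tprs:
        v = np.asarray(cov[t], dtype=float)
        out["tpr"][str(t)] = {
            "coverage": float(v.mean()),
            "se": float(v.std() / np.sqrt(len(v))),
            "n": int(len(v)),
        }
    return out


# ---------------------------------------------------------------------------
# tile-elimination comparison


def eat_study_config(seed: int = 0) -> CohortConfig:
    """Study conditions for the elimination experiments: two-thirds of tiles
    ambiguous, partially overlapping class clusters (separation 2.5 scales)
    and few tiles per slide, so tile-level noise genuinely propagates to
    patient calls."""
    return CohortConfig(
        n_patients_per_class=50,
        tiles_per_slide=(12, 12),
        cluster_means=default_cluster_means(8, separation=3.0),
        ambiguous_fraction=2.0 / 3.0,
        seed=seed,
    )


def _patient_accuracy(table: TileTable, probs: np.ndarray, keep: np.ndarray | None = None):
    """Patient accuracy after optionally dropping tiles; patients whose every
    tile was dropped fall back to their unfiltered probabilities."""
    if keep is None:
        pdf = _patient_table(table, probs)
    else:
        kept = table.subset(keep)
        pdf = _patient_table(kept, probs[keep])
        missing = set(table.patients()) - set(pdf["patient_id"])
        if missing:
            fallback = _patient_table(table, probs)
            pdf = pd.concat(
                [pdf, fallback[fallback["patient_id"].isin(missing)]], ignore_index=True
            )
    y = pdf["label"].to_numpy().astype(int)
    return float(((pdf["p1"].to_numpy() > 0.5).astype(int) == y).mean())


def eat_comparison(
    seed: int,
    cohort_cfg: CohortConfig | None = None,
    sngp_cfg: SNGPConfig | None = None,
) -> dict:
    """Patient accuracy of SNGP vs SNGP after cluster-mode EAT (retrained)
    vs SNGP after random elimination at the matched rate (retrained).

    Clustering runs on the tile embeddings of the training split (k=3);
    because the spectral-normalized extractor preserves distances, input
    and latent cluster structure coincide on this generator, and clustering
    the inputs keeps the elimination rule independent of any single trained
    representation.  Test tiles are assigned to the nearest center and
    ambiguous ones excluded before aggregation.
    """
    cohort_cfg = cohort_cfg or eat_study_config(seed)
    sngp_cfg = sngp_cfg or SNGPConfig(hidden_sizes=(32, 32), D_L=128, epochs=10)
    cohort = generate_cohort(replace(cohort_cfg, seed=seed))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 41]))
    train_p, _, test_p = split_patients(cohort, (0.8, 0.0, 0.2), rng)
    train, test = cohort.subset_patients(train_p), cohort.subset_patients(test_p)
    scfg = replace(sngp_cfg, seed=seed)

    base = train_tile_classifier(train, scfg)
    acc_base = _patient_accuracy(test, base.predict(test.embeddings).probs)

    # cluster-mode EAT, then retrain; the ambiguous cluster is the (single)
    # least label-dominated one
    index = build_cluster_index(train.embeddings, train.labels, k=3, seed=seed)
    stats = index.cluster_stats
    index.ambiguous_ids = frozenset({int(stats.loc[stats["dominance"].idxmin(), "cluster"])})
    train_eat, _ = eliminate(train, index)
    removed_frac = 1.0 - len(train_eat) / len(train)
    eat_model = train_tile_classifier(train_eat, scfg)
    keep_test = ~np.isin(index.assign(test.embeddings), list(index.ambiguous_ids))
    acc_eat = _patient_accuracy(test, eat_model.predict(test.embeddings).probs, keep_test)

    # random elimination at the matched rate, then retrain
    re_index = AmbiguityIndex(mode="random", retain_rate=1.0 - removed_frac, seed=seed)
    train_re, _ = eliminate(train, re_index)
    re_model = train_tile_classifier(train_re, scfg)
    keep_re = np.zeros(len(test), dtype=bool)
    keep_re[
        rng.choice(len(test), max(1, int(round((1 - removed_frac) * len(test)))), replace=False)
    ] = True
    acc_re = _patient_accuracy(test, re_model.predict(test.embeddings).probs, keep_re)

    return {
        "accuracy_sngp": acc_base,
        "accuracy_eat": acc_eat,
        "accuracy_random": acc_re,
        "removed_fraction": removed_frac,
    }


def threshold_retention_sweep(
    seed: int,
    retain_rates=(1.0, 0.4, 0.1, 0.01),
    cohort_cfg: CohortConfig | None = None,
) -> dict:
    """Patient accuracy vs per-slide tile retention rate for score-threshold
    EAT and for random elimination, using a proxy tile classifier (no
    retraining).

    Each slide keeps its ``max(1, round(rate * n_tiles))`` least ambiguous
    tiles (threshold) or a random subset of the same size (random), so every
    slide always contributes at least one tile.  Threshold elimination keeps
    the most informative tiles and stays flat down to tiny retention rates
    on separable data; random elimination throws away signal and degrades.

    Defaults to a separable cohort (default cluster geometry) with
    two-thirds ambiguous tiles: the property that the *least ambiguous*
    tiles suffice requires the proxy's confident tiles to actually be
    informative, which holds when the class clusters are separated.
    """
    cohort_cfg = cohort_cfg or CohortConfig(
        n_patients_per_class=50, tiles_per_slide=(12, 12),
        ambiguous_fraction=2.0 / 3.0, seed=seed,
    )
    cohort = generate_cohort(replace(cohort_cfg, seed=seed))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 43]))
    train_p, _, test_p = split_patients(cohort, (0.8, 0.0, 0.2), rng)
    train, test = cohort.subset_patients(train_p), cohort.subset_patients(test_p)
    proxy = train_proxy_classifier(train, seed=seed)
    probs = proxy.predict_proba(test.embeddings)
    scores = ambiguity_score(probs)
    slide_groups = list(test.manifest.groupby("slide_id", sort=False).indices.values())
    out = {"retain_rates": list(retain_rates), "threshold": [], "random": []}
    for rate in retain_rates:
        keep_t = np.zeros(len(test), dtype=bool)
        keep_r = np.zeros(len(test), dtype=bool)
        for idx in slide_groups:
            idx = np.asarray(idx)
            n_keep = max(1, int(round(rate * len(idx))))
            best = idx[np.argsort(scores[idx], kind="stable")[:n_keep]]
            keep_t[best] = True
            keep_r[rng.choice(idx, n_keep, replace=False)] = True
        out["threshold"].append(_patient_accuracy(test, probs, keep_t))
        out["random"].append(_patient_accuracy(test, probs, keep_r))
    return out
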