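"""Hierarchical aggregation identities, fairness gaps with the small-group
merge rule, attention efficiency against a permutation null, and
classification metrics vs a brute-force AUROC oracle."""

import numpy as np
import pandas as pd
import pytest

from trustwsi.metrics import (
    aggregate,
    attention_efficiency,
    classification_metrics,
    fairness_gaps,
)
from trustwsi.synthetic import CohortConfig, cptac_like, generate_cohort


def _manifest(rows):
    return pd.DataFrame(
        rows, columns=["tile_id", "slide_id", "patient_id", "weak_label", "sex", "race"]
    )


class TestAggregate:
    def test_slide_mean_of_tiles(self):
        m = _manifest(
            [("t0", "s0", "p0", 1, "m", "w"), ("t1", "s0", "p0", 1, "m", "w")]
        )
        probs = np.array([[0.8, 0.2], [0.6, 0.4]])
        res = aggregate(probs, m)
        np.testing.assert_allclose(res["slide"].probs, [[0.7, 0.3]])

    def test_patient_mean_of_slides(self):
        m = _manifest(
            [
                ("t0", "s0", "p0", 0, "f", "w"),
                ("t1", "s1", "p0", 0, "f", "w"),
                ("t2", "s1", "p0", 0, "f", "w"),
                ("t3", "s1", "p0", 0, "f", "w"),
            ]
        )
        probs = np.array([[0.7, 0.3], [0.5, 0.5], [0.5, 0.5], [0.5, 0.5]])
        res = aggregate(probs, m)
        # slide means 0.3 and 0.5 -> patient 0.4, regardless of tile counts
        np.testing.assert_allclose(res["patient"].probs, [[0.6, 0.4]])

    def test_equals_grand_mean_for_balanced_hierarchy(self):
        # algebraic identity: equal tiles per slide, one slide per patient
        cfg = CohortConfig(n_patients_per_class=10, tiles_per_slide=(20, 20), seed=3)
        t = generate_cohort(cfg)
        rng = np.random.default_rng(0)
        p1 = rng.random(len(t))
        probs = np.column_stack([1 - p1, p1])
        res = aggregate(probs, t.manifest)
        grand = pd.DataFrame({"pid": t.patient_ids, "p1": p1}).groupby("pid", sort=False)[
            "p1"
        ].mean()
        np.testing.assert_allclose(res["patient"].probs[:, 1], grand.to_numpy())

    def test_permutation_invariant_within_slides(self):
        t = generate_cohort(cptac_like(seed=4, n_patients_per_class=8))
        rng = np.random.default_rng(1)
        p1 = rng.random(len(t))
        probs = np.column_stack([1 - p1, p1])
        perm = rng.permutation(len(t))
        a = aggregate(probs, t.manifest)["patient"]
        b = aggregate(probs[perm], t.manifest.iloc[perm].reset_index(drop=True))["patient"]
        pa = dict(zip(a.unit_ids, a.probs[:, 1]))
        pb = dict(zip(b.unit_ids, b.probs[:, 1]))
        assert pa.keys() == pb.keys()
        for k in pa:
            assert pa[k] == pytest.approx(pb[k])

    def test_misaligned_inputs_rejected(self):
        m = _manifest([("t0", "s0", "p0", 0, "m", "w")])
        with pytest.raises(ValueError):
            aggregate(np.zeros((2, 2)), m)


class TestFairness:
    def test_identical_groups_gap_zero(self):
        values = np.ones(60)
        groups = np.array(["a"] * 30 + ["b"] * 30)
        rep = fairness_gaps(values, groups)
        assert rep.gap == 0.0

    def test_gap_is_max_minus_min(self):
        values = np.concatenate([np.full(30, 0.9), np.full(30, 0.8), np.full(30, 0.85)])
        groups = np.array(["a"] * 30 + ["b"] * 30 + ["c"] * 30)
        rep = fairness_gaps(values, groups)
        assert rep.gap == pytest.approx(0.1)

    def test_small_group_merged_into_others(self):
        values = np.concatenate([np.ones(25), np.zeros(19)])
        groups = np.array(["big"] * 25 + ["tiny"] * 19)
        rep = fairness_gaps(values, groups, min_group_size=20)
        assert "Others" in rep.per_group
        assert "tiny" not in rep.per_group
        assert rep.group_sizes["Others"] == 19

    def test_single_group_gap_undefined(self):
        rep = fairness_gaps(np.ones(30), np.array(["a"] * 30))
        assert rep.gap is None

    def test_gap_invariant_to_relabeling(self):
        rng = np.random.default_rng(2)
        values = rng.random(100)
        groups = rng.choice(["x", "y", "z"], 100)
        rep1 = fairness_gaps(values, groups, min_group_size=1)
        relabel = {"x": "1", "y": "2", "z": "3"}
        rep2 = fairness_gaps(values, np.array([relabel[g] for g in groups]), min_group_size=1)
        assert rep1.gap == pytest.approx(rep2.gap)

    def test_gap_near_zero_when_subgroups_independent_of_difficulty(self):
        rng = np.random.default_rng(3)
        n = 4000
        correct = (rng.random(n) < 0.9).astype(float)
        groups = rng.choice(["a", "b"], n)  # assigned independently
        rep = fairness_gaps(correct, groups)
        assert rep.gap < 3 * np.sqrt(0.9 * 0.1 * (1 / (groups == "a").sum() + 1 / (groups == "b").sum()))


class TestAttentionEfficiency:
    def test_attention_equal_to_relevance_is_perfect(self):
        r = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
        a = r.astype(float)
        assert attention_efficiency(a, r, removal_fraction=0.5) == 1.0

    def test_anticorrelated_attention_with_large_removal(self):
        r = np.array([1] * 5 + [0] * 5, dtype=bool)
        a = np.concatenate([np.full(5, 0.1), np.full(5, 1.0)])
        assert attention_efficiency(a, r, removal_fraction=0.5) == 0.0

    def test_random_attention_matches_prevalence(self):
        rng = np.random.default_rng(4)
        n = 20000
        r = rng.random(n) < 0.3
        a = rng.random(n)  # permutation-null attention
        eff = attention_efficiency(a, r, removal_fraction=0.8)
        assert abs(eff - 0.3) < 4 * np.sqrt(0.3 * 0.7 / (0.2 * n))

    def test_all_zero_attention_rejected(self):
        with pytest.raises(ValueError):
            attention_efficiency(np.zeros(5), np.ones(5, dtype=bool))

    def test_invalid_removal_fraction(self):
        with pytest.raises(ValueError):
            attention_efficiency(np.ones(5), np.ones(5, dtype=bool), removal_fraction=1.0)


def test_attention_efficiency_improves_after_tile_elimination():
    """Removing high-ambiguity tiles before attention pooling concentrates
    the bag model's attention on reference-relevant tiles, so attention
    efficiency does not decrease."""
    from trustwsi.eat import AmbiguityIndex, ambiguity_score, eliminate, train_proxy_classifier
    from trustwsi.mil import train_abmil_classifier
    from trustwsi.sngp import SNGPConfig
    from trustwsi.synthetic import relevance_mask

    cohort = generate_cohort(
        CohortConfig(n_patients_per_class=30, tiles_per_slide=(20, 30), seed=17)
    )
    model = train_abmil_classifier(
        cohort,
        SNGPConfig(seed=17, D_L=64, abmil_hidden=(32, 32), attn_dim=16,
                   abmil_epochs=8, abmil_lr=1e-3),
    )

    def efficiency(table):
        ids, _, attn = model.predict_tiles(table)
        rel = relevance_mask(table)
        slides = table.manifest.groupby("slide_id", sort=False).indices
        a = np.zeros(len(table))
        for sid, idx in slides.items():
            a[idx] = attn[sid]
        return attention_efficiency(a, rel, removal_fraction=0.5)

    before = efficiency(cohort)
    proxy = train_proxy_classifier(cohort, seed=17)
    scores = ambiguity_score(proxy.predict_proba(cohort.embeddings))
    filtered, _ = eliminate(
        cohort, AmbiguityIndex(mode="threshold", retain_rate=2 / 3), scores=scores
    )
    after = efficiency(filtered)
    assert after >= before


class TestClassificationMetrics:
    def test_perfect_ranking(self):
        probs = np.column_stack([1 - np.linspace(0, 1, 10), np.linspace(0, 1, 10)])
        labels = (np.linspace(0, 1, 10) > 0.5).astype(int)
        res = classification_metrics(probs, labels)
        assert res["auroc"] == 1.0
        assert res["accuracy"] == 1.0

    def test_single_class_auroc_missing(self):
        res = classification_metrics(np.array([[0.4, 0.6]]), np.array([1]))
        assert res["auroc"] is None

    def test_matches_brute_force_pairwise_auroc(self):
        rng = np.random.default_rng(5)
        p1 = rng.random(30)
        labels = rng.integers(0, 2, 30)
        if len(np.unique(labels)) < 2:
            labels[0] = 1 - labels[0]
        res = classification_metrics(np.column_stack([1 - p1, p1]), labels)
        pos, neg = p1[labels == 1], p1[labels == 0]
        wins = sum(1.0 if a > b else (0.5 if a == b else 0.0) for a in pos for b in neg)
        assert res["auroc"] == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)
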