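"""Split-CP and CRC contracts: the order-statistic threshold, prediction-set
rules, outcome breakdown, marginal-coverage sandwich, nestedness, and the
bisection-based risk controller against a grid-scan oracle."""

import numpy as np
import pytest

from trustwsi.conformal import (
    NEVER_COVERED,
    RiskController,
    calibrate,
    categorize,
    crc_calibrate,
    crc_predict,
    evaluate,
    nonconformity,
    predict_set,
)


class TestNonconformity:
    def test_direct_values(self):
        assert nonconformity([[1.0, 0.0]], [0])[0] == 0.0
        assert nonconformity([[0.5, 0.5]], [0])[0] == 0.5
        assert nonconformity([[0.5, 0.5]], [1])[0] == 0.5
        assert nonconformity([[0.2, 0.8]], [1])[0] == pytest.approx(0.2)

    def test_always_in_unit_interval(self):
        rng = np.random.default_rng(0)
        p = rng.dirichlet(np.ones(3), size=100)
        y = rng.integers(0, 3, 100)
        s = nonconformity(p, y)
        assert np.all((s >= 0) & (s <= 1))

    def test_label_out_of_range(self):
        with pytest.raises(ValueError):
            nonconformity([[0.5, 0.5]], [2])


class TestCalibrate:
    def test_order_statistic_example(self):
        # exhaustive enumeration: R=4, alpha=0.5 -> k = ceil(2.5) = 3 -> 3rd smallest
        cal = calibrate([0.1, 0.2, 0.3, 0.9], alpha=0.5)
        assert cal.q_hat == pytest.approx(0.3)

    def test_index_overflow_yields_infinite_threshold(self):
        cal = calibrate([0.1, 0.2, 0.3, 0.9], alpha=0.05)  # k = ceil(4.75) = 5 > 4
        assert cal.q_hat == np.inf

    def test_alpha_near_one_gives_smallest_score(self):
        cal = calibrate([0.4, 0.1, 0.7], alpha=0.999)
        assert cal.q_hat == pytest.approx(0.1)

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError):
            calibrate([], alpha=0.1)

    def test_q_hat_monotone_in_alpha(self):
        rng = np.random.default_rng(1)
        scores = rng.random(101)
        alphas = np.linspace(0.01, 0.6, 20)
        qs = [calibrate(scores, a).q_hat for a in alphas]
        assert np.all(np.diff(qs) <= 1e-12)


class TestPredictSet:
    def test_direct_rule(self):
        cal = calibrate([0.3] * 9, alpha=0.1)  # q_hat = 0.3
        sets = predict_set([[0.9, 0.1]], cal)
        np.testing.assert_array_equal(sets, [[True, False]])

    def test_infinite_threshold_includes_all_labels(self):
        cal = calibrate([0.1], alpha=0.05)
        sets = predict_set([[0.99, 0.01]], cal)
        assert sets.all()

    def test_empty_set_is_representable(self):
        cal = calibrate([0.05] * 9, alpha=0.1)  # q_hat = 0.05
        sets = predict_set([[0.5, 0.5]], cal)  # both scores 0.5 > 0.05
        assert sets.sum() == 0
        res = evaluate(sets, [0])
        assert res["breakdown"]["empty"] == 1
        assert res["coverage"] == 0.0

    def test_nestedness_across_alpha(self):
        rng = np.random.default_rng(2)
        scores = rng.random(100)
        p = rng.dirichlet(np.ones(2), size=50)
        s1 = predict_set(p, calibrate(scores, 0.2))
        s2 = predict_set(p, calibrate(scores, 0.05))
        # smaller alpha -> larger (or equal) sets containing the former
        assert np.all(s2 | ~s1)


class TestEvaluate:
    def test_all_label_sets(self):
        sets = np.ones((4, 2), dtype=bool)
        res = evaluate(sets, [0, 1, 0, 1])
        assert res["coverage"] == 1.0
        assert res["mean_set_size"] == 2.0
        assert res["da_error"] is None
        assert res["breakdown"]["abstention"] == 4

    def test_singleton_enumeration(self):
        sets = np.array([[True, False], [False, True]])
        res = evaluate(sets, [0, 0])
        assert res["coverage"] == 0.5
        assert res["da_error"] == 0.5
        assert res["breakdown"]["single_correct"] == 1
        assert res["breakdown"]["single_incorrect"] == 1

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            evaluate(np.ones((2, 2), dtype=bool), [0])

    def test_never_covered_label_counts_as_miss(self):
        sets = np.array([[True, False]])
        res = evaluate(sets, [NEVER_COVERED])
        assert res["coverage"] == 0.0
        assert res["breakdown"]["single_incorrect"] == 1

    @pytest.mark.parametrize("alpha", [0.1, 0.05])
    def test_marginal_coverage_sandwich(self, alpha):
        # Monte-Carlo check of the finite-sample guarantee:
        # mean coverage over exchangeable splits lies in [1-a, 1-a+1/(R+1)]
        rng = np.random.default_rng(3)
        R, n_test, n_splits = 100, 100, 400
        covs = []
        for _ in range(n_splits):
            scores = rng.random(R + n_test)  # exchangeable continuous scores
            cal = calibrate(scores[:R], alpha)
            covs.append((scores[R:] <= cal.q_hat).mean())
        m = np.mean(covs)
        mc_tol = 3 * np.std(covs) / np.sqrt(n_splits)
        assert 1 - alpha - mc_tol <= m <= 1 - alpha + 1 / (R + 1) + mc_tol


class TestCRC:
    def test_perfect_confidence_gives_zero_threshold(self):
        probs = np.tile([1.0, 0.0], (20, 1))
        ctl = crc_calibrate(probs, np.zeros(20, dtype=int), alpha=0.1)
        assert ctl.rho_hat == 0.0
        assert not ctl.infeasible

    def test_bisection_matches_grid_scan_oracle(self):
        rng = np.random.default_rng(4)
        p1 = rng.random(200)
        probs = np.column_stack([1 - p1, p1])
        labels = (rng.random(200) < p1).astype(int)
        alpha = 0.1
        ctl = crc_calibrate(probs, labels, alpha, tolerance=1e-4)

        def cov(rho):
            return (probs[np.arange(200), labels] >= 1 - rho).mean()

        target = ctl.target_coverage
        # finite-sample-corrected target: 1 - ((R+1)a - 1)/R
        assert target == pytest.approx(1 - (201 * alpha - 1) / 200)
        grid = np.linspace(0, 1, 20001)
        oracle = grid[np.argmax([cov(r) >= target for r in grid])]
        assert cov(ctl.rho_hat) >= target
        assert abs(ctl.rho_hat - oracle) <= ctl.tolerance + 1e-9
        # just below the threshold the target is not met
        assert cov(ctl.rho_hat - ctl.tolerance - 1e-6) < target

    def test_contamination_never_decreases_threshold(self):
        rng = np.random.default_rng(5)
        n = 300
        p1 = np.clip(rng.beta(6, 2, n), 0, 1)
        probs_in = np.column_stack([1 - p1, p1])
        labels_in = (rng.random(n) < p1).astype(int)
        rhos = []
        for frac in (0.0, 0.02, 0.04, 0.06):
            n_ood = int(frac * n)
            probs = np.vstack([probs_in, np.tile([0.5, 0.5], (n_ood, 1))])
            labels = np.concatenate([labels_in, np.full(n_ood, NEVER_COVERED)])
            rhos.append(crc_calibrate(probs, labels, alpha=0.1).rho_hat)
        assert np.all(np.diff(rhos) >= -1e-9)

    def test_infeasible_when_ood_fraction_exceeds_alpha(self):
        probs = np.tile([0.5, 0.5], (100, 1))
        labels = np.full(100, NEVER_COVERED)
        labels[:80] = 0
        ctl = crc_calibrate(probs, labels, alpha=0.05)  # 20% never covered > alpha
        assert ctl.infeasible and ctl.rho_hat == 1.0

    def test_predict_limits(self):
        probs = np.array([[0.7, 0.3], [1.0, 0.0]])
        all_in = crc_predict(probs, RiskController(rho_hat=1.0, alpha=0.1, tolerance=1e-4))
        assert all_in.all()
        only_certain = crc_predict(probs, RiskController(rho_hat=0.0, alpha=0.1, tolerance=1e-4))
        np.testing.assert_array_equal(only_certain, [[False, False], [True, False]])

    def test_binary_halfway_threshold_is_argmax(self):
        rng = np.random.default_rng(6)
        p1 = rng.random(50)
        probs = np.column_stack([1 - p1, p1])
        sets = crc_predict(probs, RiskController(rho_hat=0.5, alpha=0.1, tolerance=1e-4))
        strict = np.abs(p1 - 0.5) > 1e-9
        np.testing.assert_array_equal(
            sets[strict].argmax(axis=1), probs[strict].argmax(axis=1)
        )
        assert np.all(sets[strict].sum(axis=1) == 1)

    def test_ood_free_crc_matches_split_cp_coverage(self):
        # with no contamination, CRC is a plain threshold predictor whose
        # coverage agrees with split CP within simulation error
        rng = np.random.default_rng(7)
        covs_crc, covs_cp = [], []
        for _ in range(100):
            p1 = np.clip(rng.beta(8, 2, 300), 0, 1)
            probs = np.column_stack([1 - p1, p1])
            labels = (rng.random(300) < p1).astype(int)
            cal, test = slice(0, 150), slice(150, 300)
            ctl = crc_calibrate(probs[cal], labels[cal], alpha=0.1)
            sets = crc_predict(probs[test], ctl)
            covs_crc.append(sets[np.arange(150), labels[test]].mean())
            c = calibrate(nonconformity(probs[cal], labels[cal]), alpha=0.1)
            s = predict_set(probs[test], c)
            covs_cp.append(s[np.arange(150), labels[test]].mean())
        assert abs(np.mean(covs_crc) - np.mean(covs_cp)) < 0.02


class TestCategorize:
    def test_categories_for_binary(self):
        sets = np.array([[True, False], [False, True], [True, True], [False, False]])
        res = categorize(sets, np.array([0, 0, 0, 0]))
        assert list(res.category) == [
            "single_correct",
            "single_incorrect",
            "abstention",
            "empty",
        ]
        assert list(res.set_size) == [1, 1, 2, 0]
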