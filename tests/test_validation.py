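"""Cross-validation harnesses, q², permutation nulls, consistency."""

import numpy as np
import pytest

from transcpm import (
    PermutationResult,
    consistency_degree,
    edge_node_indices,
    external_validate,
    group_permutation_test,
    kfold_cv,
    leave_group_out,
    permutation_null_behavior,
    r2_cv,
)
from transcpm.validation import _measures_frame

FAST = dict(lambda_grid=np.logspace(-2, 3, 6))


class TestR2CV:
    def test_perfect_prediction(self):
        q2, root = r2_cv([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert q2 == 1.0 and root == 1.0

    def test_mean_prediction_scores_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        q2, _ = r2_cv(y, np.full(4, y.mean()))
        assert q2 == pytest.approx(0.0)

    def test_hand_computed_sums_of_squares(self):
        # SS_res = 1, SS_tot = 2 -> q2 = 0.5
        q2, root = r2_cv([1.0, 2.0, 3.0], [1.0, 2.0, 4.0])
        assert q2 == pytest.approx(0.5)
        assert root == pytest.approx(np.sqrt(0.5), abs=1e-4)

    def test_negative_q2_root_flagged_nan(self):
        q2, root = r2_cv([1.0, 2.0, 3.0], [3.0, 1.0, 5.0])
        assert q2 < 0 and np.isnan(root)

    def test_constant_actual_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            r2_cv([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestKFold:
    def test_each_subject_predicted_exactly_once(self, small_cohort):
        cfg, conn, pheno, truth = small_cohort
        cv = kfold_cv(conn, pheno.measures, iterations=2, seed=0, **FAST)
        for it in range(2):
            assert len(np.unique(cv.fold_assignments[it])) == 10
            counts = np.bincount(cv.fold_assignments[it], minlength=10)
            assert counts.max() - counts.min() <= 1
        assert np.isfinite(cv.predicted).all()

    def test_deterministic_under_seed(self, small_cohort):
        cfg, conn, pheno, truth = small_cohort
        a = kfold_cv(conn, pheno.measures, iterations=2, seed=5, **FAST)
        b = kfold_cv(conn, pheno.measures, iterations=2, seed=5, **FAST)
        np.testing.assert_array_equal(a.q2, b.q2)
        np.testing.assert_array_equal(a.fold_assignments, b.fold_assignments)
        np.testing.assert_array_equal(a.mask_history, b.mask_history)

    def test_planted_signal_predicts_heldout(self, small_cohort):
        cfg, conn, pheno, truth = small_cohort
        cv = kfold_cv(conn, pheno.measures,
                      motion=pheno.motion_grand_mean.to_numpy(),
                      iterations=5, seed=1, **FAST)
        assert cv.median_q2 > 0.1
        assert cv.median_q2 <= 1.0

    def test_null_cohort_gives_nonpositive_median_q2(self, null_cohort):
        cfg, conn, pheno, truth = null_cohort
        cv = kfold_cv(conn, pheno.measures, iterations=10, seed=2, **FAST)
        assert cv.median_q2 <= 0

    def test_k_larger_than_n_rejected(self, small_cohort):
        cfg, conn, pheno, truth = small_cohort
        with pytest.raises(ValueError):
            kfold_cv(conn, pheno.measures, k=100)


class TestPermutationFormula:
    def test_p_floor_when_no_null_exceeds(self):
        # directly exercise the formula semantics on synthetic null arrays
        obs, null = 0.5, np.full(1000, -1.0)
        p = (np.sum(null > obs) + 1) / (len(null) + 1)
        assert p == pytest.approx(1 / 1001)

    def test_p_one_when_all_exceed(self):
        obs, null = -0.5, np.full(1000, 1.0)
        p = (np.sum(null > obs) + 1) / (len(null) + 1)
        assert p == 1.0

    def test_49_exceed_gives_50_over_1001(self):
        null = np.concatenate([np.full(49, 2.0), np.full(951, -2.0)])
        p = (np.sum(null > 0.0) + 1) / (len(null) + 1)
        assert p == pytest.approx(50 / 1001)

    def test_planted_signal_detected(self, small_cohort):
        cfg, conn, pheno, truth = small_cohort
        res = permutation_null_behavior(conn, pheno.measures, n_perm=19,
                                        iterations=1, seed=0, **FAST)
        assert isinstance(res, PermutationResult)
        assert res.p_value == pytest.approx(1 / 20)
        assert 1 / (res.n_perm + 1) <= res.p_value <= 1

    def test_invalid_n_perm_rejected(self, small_cohort):
        cfg, conn, pheno, truth = small_cohort
        with pytest.raises(ValueError):
            permutation_null_behavior(conn, pheno.measures, n_perm=0)


class TestLeaveGroupOut:
    def test_groupwise_r_positive_with_group_independent_signal(self, small_cohort):
        cfg, conn, pheno, truth = small_cohort
        res = leave_group_out(conn, pheno.measures, pheno.groups, **FAST)
        assert set(res.group_r) == {"HC", "SCZ", "BPAD", "ADHD"}
        assert all(r > 0 for r in res.group_r.values())

    def test_deterministic(self, small_cohort):
        cfg, conn, pheno, truth = small_cohort
        a = leave_group_out(conn, pheno.measures, pheno.groups, **FAST)
        b = leave_group_out(conn, pheno.measures, pheno.groups, **FAST)
        assert a.group_r == b.group_r

    def test_small_group_rejected(self, small_cohort):
        cfg, conn, pheno, truth = small_cohort
        groups = np.asarray(pheno.groups).copy()
        groups[:2] = "TINY"
        groups[2:] = "REST"
        with pytest.raises(ValueError, match="fewer than 3"):
            leave_group_out(conn, pheno.measures, groups, **FAST)


class TestGroupPermutation:
    def test_observed_inside_band_is_uninformative(self, small_cohort):
        cfg, conn, pheno, truth = small_cohort
        res = group_permutation_test(conn, pheno.measures, pheno.groups,
                                     n_perm=49, seed=0, **FAST)
        # trait signal is group-independent: every diagnostic label
        # permutation predicts about equally well
        for g, cls in res.classification.items():
            assert cls == "uninformative", (g, res.observed[g], res.band[g])
        for g in res.p_two_sided:
            assert 0 < res.p_two_sided[g] <= 1

    def test_null_distribution_deterministic_under_seed(self, small_cohort):
        cfg, conn, pheno, truth = small_cohort
        a = group_permutation_test(conn, pheno.measures, pheno.groups,
                                   n_perm=40, seed=3, **FAST)
        b = group_permutation_test(conn, pheno.measures, pheno.groups,
                                   n_perm=40, seed=3, **FAST)
        for g in a.null:
            np.testing.assert_array_equal(a.null[g], b.null[g])

    def test_low_n_perm_warns(self, small_cohort):
        cfg, conn, pheno, truth = small_cohort
        with pytest.warns(UserWarning, match="unstable"):
            group_permutation_test(conn, pheno.measures, pheno.groups,
                                   n_perm=5, seed=0, **FAST)


class TestConsistencyDegree:
    def test_always_selected_edge_is_consistent(self):
        hist = np.zeros((10, 3), dtype=bool)
        hist[:, 0] = True
        res = consistency_degree(hist, n_nodes=3)
        assert res.consistent_mask.tolist() == [True, False, False]

    def test_94_percent_of_100_is_not_consistent(self):
        hist = np.zeros((100, 3), dtype=bool)
        hist[:94, 1] = True
        hist[:95, 2] = True
        res = consistency_degree(hist, n_nodes=3, threshold=0.95)
        assert not res.consistent_mask[1]
        assert res.consistent_mask[2]  # exactly 95% meets the threshold

    def test_degrees_match_brute_force_recount(self, rng):
        n_nodes, iters = 8, 40
        n_e = n_nodes * (n_nodes - 1) // 2
        hist = rng.random((iters, n_e)) < 0.9
        res = consistency_degree(hist, n_nodes=n_nodes, threshold=0.85)
        iu, ju = edge_node_indices(n_nodes)
        expected = np.zeros(n_nodes, dtype=int)
        for k in range(n_e):
            if hist[:, k].sum() >= 0.85 * iters:
                expected[iu[k]] += 1
                expected[ju[k]] += 1
        np.testing.assert_array_equal(res.node_degree, expected)
        assert res.node_degree.sum() == 2 * res.n_consistent_edges

    def test_union_over_tasks_and_threshold_validation(self, rng):
        hist3 = rng.random((20, 2, 6)) < 0.5
        res = consistency_degree(hist3, n_nodes=4, threshold=0.2)
        np.testing.assert_array_equal(
            res.selection_fraction, hist3.any(axis=1).mean(axis=0))
        with pytest.raises(ValueError):
            consistency_degree(hist3, n_nodes=4, threshold=1.5)


class TestExternalValidation:
    def _general(self, conn):
        return conn.edges.mean(axis=1)

    def test_cross_cohort_transfer_of_planted_signal(self, small_cohort):
        from transcpm import CohortConfig, generate_cohort

        cfg, conn, pheno, truth = small_cohort
        # independent cohort sharing the planted predictive network
        cfg2 = CohortConfig(**{
            **cfg.__dict__, "seed": cfg.seed + 1,
            "signal_edge_indices": tuple(int(i) for i in truth.signal_edges[0]),
            "group_edge_indices": tuple(int(i) for i in truth.group_edges),
        })
        conn2, pheno2, _ = generate_cohort(cfg2)
        fwd = external_validate((self._general(conn), pheno.measures),
                                (self._general(conn2), pheno2.measures), **FAST)
        rev = external_validate((self._general(conn2), pheno2.measures),
                                (self._general(conn), pheno.measures), **FAST)
        assert fwd.r > 0.3 and rev.r > 0.3
        assert np.isfinite(fwd.p_value) and np.isfinite(rev.p_value)

    def test_edge_dimension_mismatch_rejected(self, small_cohort, rng):
        cfg, conn, pheno, truth = small_cohort
        bad = rng.standard_normal((10, conn.n_edges + 5))
        with pytest.raises(ValueError, match="mismatch"):
            external_validate((self._general(conn), pheno.measures),
                              (bad, pheno.measures.iloc[:10]))


def test_measures_frame_accepts_arrays_and_frames(rng):
    x = rng.standard_normal((5, 2))
    assert _measures_frame(x).shape == (5, 2)
    assert _measures_frame(x[:, 0]).shape == (5, 1)
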