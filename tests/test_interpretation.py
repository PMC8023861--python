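"""Node/task/network contributions and hypergeometric overlap."""

import itertools
from math import comb

import numpy as np
import pytest

from transcpm import (
    OverlapQuery,
    edge_node_indices,
    edge_set_network_profile,
    fit_rcpm,
    hypergeometric_overlap,
    network_average,
    node_contribution,
    select_edges,
    similarity,
    task_contribution,
)
from transcpm.rcpm import PredictiveModel
from transcpm.synthetic import default_network_map


def _model(n_nodes, mask, weights, stds, task_names=("t0", "t1")):
    mask = np.asarray(mask, dtype=bool)
    ft, fe = np.nonzero(mask)
    return PredictiveModel(
        task_names=list(task_names), n_edges=n_nodes * (n_nodes - 1) // 2,
        mask=mask, feat_task=ft, feat_edge=fe,
        weights=np.asarray(weights, dtype=float),
        feature_means=np.zeros(len(ft)),
        feature_stds=np.asarray(stds, dtype=float),
        lam=1.0, intercept=0.0, alpha=0.01, n_train=50,
    )


class TestNodeContribution:
    def test_single_edge_contributes_to_both_endpoints(self):
        # edge 0 of a 4-node graph connects nodes 0 and 1
        mask = np.zeros((2, 6), dtype=bool)
        mask[0, 0] = True
        model = _model(4, mask, weights=[0.4], stds=[2.0])
        w = node_contribution(model)
        np.testing.assert_allclose(w, [0.8, 0.8, 0, 0])

    def test_empty_model_all_zero(self):
        model = _model(4, np.zeros((2, 6), dtype=bool), weights=[], stds=[])
        np.testing.assert_array_equal(node_contribution(model), np.zeros(4))

    def test_matches_brute_force_recomputation(self, rng):
        n_nodes = 12
        n_e = n_nodes * (n_nodes - 1) // 2
        mask = rng.random((3, n_e)) < 0.25
        nf = mask.sum()
        model = _model(n_nodes, mask, weights=rng.standard_normal(nf),
                       stds=rng.uniform(0.5, 2, nf), task_names=["a", "b", "c"])
        w = node_contribution(model)
        iu, ju = edge_node_indices(n_nodes)
        expected = np.zeros(n_nodes)
        for f in range(nf):
            c = model.weights[f] * model.feature_stds[f]
            expected[iu[model.feat_edge[f]]] += c
            expected[ju[model.feat_edge[f]]] += c
        np.testing.assert_allclose(w, expected)
        # signed sum identity: each feature counted at both endpoints
        assert w.sum() == pytest.approx(
            2 * (model.weights * model.feature_stds).sum())


class TestTaskContribution:
    def test_single_task_model_gets_all_weight(self, rng):
        mask = np.zeros((2, 6), dtype=bool)
        mask[1, [0, 3]] = True
        model = _model(4, mask, weights=[0.5, -0.2], stds=[1.0, 1.0])
        w = task_contribution(model)
        assert w["t0"] == 0.0 and w["t1"] == pytest.approx(1.0)

    def test_symmetric_tasks_split_evenly(self):
        mask = np.zeros((2, 6), dtype=bool)
        mask[0, 0] = mask[1, 1] = True
        model = _model(4, mask, weights=[0.3, -0.3], stds=[2.0, 2.0])
        w = task_contribution(model)
        assert w["t0"] == pytest.approx(0.5) and w["t1"] == pytest.approx(0.5)

    def test_matches_brute_force_and_sums_to_one(self, rng):
        n_nodes = 10
        n_e = n_nodes * (n_nodes - 1) // 2
        mask = rng.random((4, n_e)) < 0.3
        nf = mask.sum()
        model = _model(n_nodes, mask, weights=rng.standard_normal(nf),
                       stds=rng.uniform(0.5, 2, nf),
                       task_names=[f"t{i}" for i in range(4)])
        w = task_contribution(model)
        expected = np.zeros(4)
        for f in range(nf):
            expected[model.feat_task[f]] += abs(model.weights[f]) * model.feature_stds[f]
        np.testing.assert_allclose(w.to_numpy(), expected / expected.sum(), atol=1e-12)
        assert w.sum() == pytest.approx(1.0, abs=1e-10)
        assert (w >= 0).all()

    def test_empty_model_rejected(self):
        model = _model(4, np.zeros((2, 6), dtype=bool), weights=[], stds=[])
        with pytest.raises(ValueError):
            task_contribution(model)


class TestNetworkAverage:
    def test_constant_contributions_give_constant_means(self):
        nm = default_network_map(20)
        means = network_average(np.full(20, 3.5), nm)
        assert (means == 3.5).all()

    def test_single_nonzero_node_arithmetic(self):
        nm = default_network_map(20)  # 10 networks x 2 nodes
        w = np.zeros(20)
        w[0] = 12.0
        means = network_average(w, nm)
        assert means[nm.labels[0]] == pytest.approx(6.0)

    def test_matches_groupby_recomputation(self, rng):
        nm = default_network_map(23)
        w = rng.standard_normal(23)
        means = network_average(w, nm)
        for net in nm.networks:
            assert means[net] == pytest.approx(w[nm.members(net)].mean())


class TestSimilarity:
    def test_self_and_negated_self(self, rng):
        v = rng.standard_normal(30)
        assert similarity(v, v)[0] == pytest.approx(1.0)
        assert similarity(v, -v)[0] == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            similarity(np.ones(10), np.arange(10.0))

    def test_models_sharing_planted_edges_have_correlated_nodes(self):
        # two independent cohorts whose generators share the planted
        # predictive edges: their fitted models should agree at node level
        from transcpm import CohortConfig, generate_cohort

        base = dict(group_sizes={"HC": 30, "SCZ": 10, "BPAD": 10, "ADHD": 10},
                    n_nodes=30, n_tasks=2, n_signal_edges=25, n_group_edges=0,
                    signal_corr=0.6)
        cfg1 = CohortConfig(**base, seed=21)
        conn1, _, truth1 = generate_cohort(cfg1)
        cfg2 = CohortConfig(
            **base, seed=22,
            signal_edge_indices=tuple(int(i) for i in truth1.signal_edges[0]))
        conn2, _, truth2 = generate_cohort(cfg2)
        models = []
        for c, t in ((conn1, truth1), (conn2, truth2)):
            mask = select_edges(c.edges, t.latent_trait, alpha=0.01)
            models.append(fit_rcpm(c.edges, mask, t.latent_trait, lambda_grid=[10.0]))
        r, p = similarity(node_contribution(models[0]), node_contribution(models[1]))
        assert r > 0.3 and p < 0.01


class TestHypergeometricOverlap:
    def test_empty_second_set_gives_zero(self):
        assert hypergeometric_overlap(OverlapQuery(x=0, n=5, K=0, M=20)) == 0.0

    def test_maximal_overlap_gives_zero(self):
        assert hypergeometric_overlap(OverlapQuery(x=3, n=3, K=4, M=10)) == 0.0

    def test_enumerated_small_case(self):
        # P(X > 2) = P(X = 3) = C(4,3) C(6,0) / C(10,3) = 4/120
        p = hypergeometric_overlap(OverlapQuery(x=2, n=3, K=4, M=10))
        assert p == pytest.approx(4 / 120, abs=1e-12)

    def test_against_exhaustive_pmf_enumeration(self):
        for m_pop in (6, 11, 17):
            for k_set in range(m_pop + 1):
                for n_draw in range(m_pop + 1):
                    hi = min(n_draw, k_set)
                    for x in range(hi + 1):
                        p_ref = sum(
                            comb(k_set, j) * comb(m_pop - k_set, n_draw - j)
                            for j in range(x + 1, hi + 1)
                        ) / comb(m_pop, n_draw)
                        p = hypergeometric_overlap(
                            OverlapQuery(x=x, n=n_draw, K=k_set, M=m_pop))
                        assert p == pytest.approx(p_ref, abs=1e-12)

    def test_monotone_nonincreasing_in_x(self):
        ps = [hypergeometric_overlap(OverlapQuery(x=x, n=40, K=60, M=500))
              for x in range(41)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_invalid_query_rejected(self):
        with pytest.raises(ValueError):
            OverlapQuery(x=5, n=3, K=4, M=10)


class TestNetworkProfile:
    def test_pure_cell_mask_has_zero_p(self):
        nm = default_network_map(12)
        iu, ju = edge_node_indices(12)
        lab = nm.label_indices()
        cell = (lab[iu] == 0) & (lab[ju] == 0)
        profile = edge_set_network_profile(cell, nm).table
        row = profile[(profile.net_a == nm.networks[0]) &
                      (profile.net_b == nm.networks[0])].iloc[0]
        assert row.x == row.K == row.n == cell.sum()
        assert row.p == 0.0

    def test_counts_match_brute_force(self, rng):
        nm = default_network_map(15)
        n_e = 15 * 14 // 2
        mask = rng.random(n_e) < 0.3
        profile = edge_set_network_profile(mask, nm).table
        iu, ju = edge_node_indices(15)
        lab = nm.label_indices()
        for _, row in profile.iterrows():
            ai = nm.networks.index(row.net_a)
            bi = nm.networks.index(row.net_b)
            cell = [k for k in range(n_e)
                    if {lab[iu[k]], lab[ju[k]]} == ({ai, bi} if ai != bi else {ai})]
            assert row.K == len(cell)
            assert row.x == sum(mask[k] for k in cell)
            assert row.n == mask.sum()
            assert row.M == n_e
        # cells partition the population
        assert profile.K.sum() == n_e
        assert profile.x.sum() == mask.sum()

    def test_random_mask_pvalue_calibration(self, rng):
        # under uniformly random masks the per-cell overlap is exactly
        # hypergeometric; the exclusive right tail P(X > x) is discrete, so
        # calibration is checked against the exact null rate of p < 0.05
        # rather than against uniformity
        from scipy import stats as sps

        nm = default_network_map(30)
        n_e = 30 * 29 // 2
        n_draw = 60
        profile0 = edge_set_network_profile(np.zeros(n_e, dtype=bool), nm).table
        exact_rates = []
        for k_cell in profile0.K:
            xs = np.arange(k_cell + 1)
            pmf = sps.hypergeom.pmf(xs, n_e, k_cell, n_draw)
            tail = sps.hypergeom.sf(xs, n_e, k_cell, n_draw)
            exact_rates.append(pmf[tail < 0.05].sum())
        exact_rates = np.array(exact_rates)
        reps = 30
        low = 0
        for _ in range(reps):
            mask = np.zeros(n_e, dtype=bool)
            mask[rng.choice(n_e, n_draw, replace=False)] = True
            profile = edge_set_network_profile(mask, nm).table
            low += (profile.p < 0.05).sum()
        expected = reps * exact_rates.sum()
        sigma = np.sqrt(reps * (exact_rates * (1 - exact_rates)).sum())
        assert abs(low - expected) < 4 * sigma
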