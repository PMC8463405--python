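import dataclasses

import numpy as np
import pytest

from coexnet import (
    NullModelConfig,
    ValidationError,
    chung_lu_graph,
    consensus,
    er_graph,
    run_pipeline,
    spearman_matrix,
)
from coexnet.nullmodel import _chung_lu_probs

from oracles import spearman_naive


class TestSpearman:
    def test_perfect_inversion_and_identity(self):
        m = np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        r = spearman_matrix(m)
        assert r[0, 1] == pytest.approx(-1.0)
        r2 = spearman_matrix(np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]]))
        assert r2[0, 1] == pytest.approx(1.0)

    def test_ties_match_midrank_oracle(self):
        x = [1.0, 1.0, 2.0, 3.0]
        y = [2.0, 1.0, 1.0, 3.0]
        r = spearman_matrix(np.array([x, y]))
        assert r[0, 1] == pytest.approx(spearman_naive(x, y), abs=1e-12)

    def test_random_rows_match_oracle(self, rng):
        m = rng.integers(0, 5, size=(6, 10)).astype(float)
        m[0] += rng.random(10)
        r = spearman_matrix(m)
        for i in range(6):
            for j in range(i + 1, 6):
                expect = spearman_naive(list(m[i]), list(m[j]))
                if np.isnan(expect):
                    assert np.isnan(r[i, j])
                else:
                    assert r[i, j] == pytest.approx(expect, abs=1e-12)

    def test_constant_row_is_nan_and_diag_one(self):
        m = np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        r = spearman_matrix(m)
        assert np.isnan(r[0, 1]) and r[0, 0] == 1.0 and r[1, 1] == 1.0

    def test_needs_three_samples(self):
        with pytest.raises(ValidationError):
            spearman_matrix(np.ones((2, 2)))


class TestGraphNulls:
    def test_er_expected_edge_count(self, rng):
        # n=10, avg_degree=3 -> p=1/3, expectation 15 edges
        counts = [er_graph(10, 3.0, rng).number_of_edges() for _ in range(200)]
        se = np.sqrt(45 * (1 / 3) * (2 / 3) / 200)
        assert abs(np.mean(counts) - 15.0) <= 3 * se

    def test_er_zero_degree_empty(self, rng):
        assert er_graph(10, 0.0, rng).number_of_edges() == 0

    def test_chung_lu_pair_probability_formula(self):
        _, probs = _chung_lu_probs(np.array([2, 2, 2]))
        assert np.allclose(probs, 2 / 3)  # d_i d_j / sum(d) = 4/6 each pair

    def test_chung_lu_zero_degree_never_connected(self, rng):
        for _ in range(50):
            g = chung_lu_graph([0, 3, 3, 3], rng)
            assert g.degree[0] == 0

    def test_chung_lu_mean_degree_recovery(self, rng):
        target = np.array([1, 2, 3, 2, 1, 4, 2, 1], dtype=float)
        degs = np.array([
            [chung_lu_graph(target, rng).degree[i] for i in range(len(target))]
            for _ in range(500)
        ])
        n, probs = _chung_lu_probs(target)
        iu, ju = np.triu_indices(n, k=1)
        expect = np.zeros(n)
        var = np.zeros(n)
        for i, j, p in zip(iu, ju, probs):
            expect[i] += p
            expect[j] += p
            var[i] += p * (1 - p)
            var[j] += p * (1 - p)
        se = np.sqrt(var / 500)
        assert np.all(np.abs(degs.mean(axis=0) - expect) <= 3 * se + 1e-9)


class TestConsensus:
    def edge_sets(self, present, total, key=("a", "b", "pos"), rho=0.5):
        sets = [{key: rho} for _ in range(present)]
        sets += [{} for _ in range(total - present)]
        return sets

    def test_nine_of_ten_kept_with_support(self):
        out = consensus(self.edge_sets(9, 10), 0.9)
        assert len(out) == 1 and out[0].support == 0.9

    def test_eight_of_ten_dropped(self):
        assert consensus(self.edge_sets(8, 10), 0.9) == []

    def test_fraction_one_is_intersection(self):
        sets = self.edge_sets(10, 10)
        sets[3] = {}
        assert consensus(sets, 1.0) == []
        assert len(consensus(self.edge_sets(10, 10), 1.0)) == 1

    def test_conflicting_signs_counted_separately(self):
        sets = [{("a", "b", "pos"): 0.5} for _ in range(5)]
        sets += [{("a", "b", "neg"): -0.5} for _ in range(5)]
        assert consensus(sets, 0.9) == []
        assert len(consensus(sets, 0.5)) == 2

    def test_weight_is_mean_rho_over_containing(self):
        sets = [{("a", "b", "pos"): 0.4}, {("a", "b", "pos"): 0.6}]
        out = consensus(sets, 0.9)
        assert out[0].weight == pytest.approx(0.5)


class TestInference:
    def test_single_iteration_consensus_is_that_edge_set(self, planted_small):
        data, cfg = planted_small
        cfg1 = dataclasses.replace(cfg, n_monte_carlo=1)
        net = run_pipeline(data.tables, data.frame, cfg1, env_vars=[])
        mc_edges = {e.key for e in net.edges}
        assert all(e.support == 1.0 for e in net.edges)
        assert len(mc_edges) == len(net.edges)

    def test_identical_seed_identical_network(self, planted_small):
        data, cfg = planted_small
        a = run_pipeline(data.tables, data.frame, cfg, env_vars=[])
        b = run_pipeline(data.tables, data.frame, cfg, env_vars=[])
        assert [e.key for e in a.edges] == [e.key for e in b.edges]
        assert [e.weight for e in a.edges] == [e.weight for e in b.edges]

    def test_sample_order_invariance(self, planted_small):
        data, cfg = planted_small
        a = run_pipeline(data.tables, data.frame, cfg, env_vars=[])
        rev_tables = [t.select_samples(t.sample_ids[::-1]) for t in data.tables]
        rev_frame = data.frame.subset(data.frame.sample_ids)
        rev_frame.data = rev_frame.data.iloc[::-1].reset_index(drop=True)
        b = run_pipeline(rev_tables, rev_frame, cfg, env_vars=[])
        assert {e.key for e in a.edges} == {e.key for e in b.edges}

    def test_raising_consensus_fraction_never_adds_edges(self, planted_small):
        data, cfg = planted_small
        nets = {}
        for frac in (0.6, 0.9, 1.0):
            c = dataclasses.replace(cfg, consensus_fraction=frac)
            nets[frac] = run_pipeline(data.tables, data.frame, c, env_vars=[])
        k06 = {e.key for e in nets[0.6].edges}
        k09 = {e.key for e in nets[0.9].edges}
        k10 = {e.key for e in nets[1.0].edges}
        assert k10 <= k09 <= k06

    def test_sign_coherence_with_thresholds(self, planted_small):
        data, cfg = planted_small
        net = run_pipeline(data.tables, data.frame, cfg, env_vars=[])
        assert net.edges, "planted data must produce edges"
        step = cfg.candidate_step
        for e in net.edges:
            if e.sign == "pos":
                assert e.weight >= net.thresholds.t_pos - step
            else:
                assert e.weight <= net.thresholds.t_neg + step

    def test_planted_modules_recovered(self, planted_small):
        data, cfg = planted_small
        net = run_pipeline(data.tables, data.frame, cfg, env_vars=[])
        pos = {(e.node_a, e.node_b) for e in net.edges if e.sign == "pos"}
        truth = data.truth.positive_pairs
        recall = len(pos & truth) / len(truth)
        assert recall >= 0.8

    def test_exclusion_pairs_recovered_negative(self, planted_small):
        data, cfg = planted_small
        net = run_pipeline(data.tables, data.frame, cfg, env_vars=[])
        neg = {(e.node_a, e.node_b) for e in net.edges if e.sign == "neg"}
        assert data.truth.negative_pairs <= neg

    def test_env_rows_can_form_edges_but_not_env_env_when_dropped(self, planted_small):
        data, cfg = planted_small
        c = dataclasses.replace(cfg, drop_env_env=True)
        net = run_pipeline(data.tables, data.frame, c,
                           env_vars=["pH", "C", "SB", "V"])
        env = {"pH", "C", "SB", "V"}
        for e in net.edges:
            assert not (e.node_a in env and e.node_b in env)

    def test_no_isolated_nodes(self, planted_small):
        data, cfg = planted_small
        net = run_pipeline(data.tables, data.frame, cfg, env_vars=[])
        endpoints = {e.node_a for e in net.edges} | {e.node_b for e in net.edges}
        assert {n.id for n in net.nodes} == endpoints
        assert all(n.degree >= 1 for n in net.nodes)

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            NullModelConfig(consensus_fraction=1.2).validate()
        with pytest.raises(ValidationError):
            NullModelConfig(perm_quantile=0.4).validate()
        with pytest.raises(ValidationError):
            NullModelConfig(mode="other").validate()
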