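"""Group statistics: sweep comparisons, gating, statistical networks,
nodal rankings and FDR differential networks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from netplast import (FCMatrix, differential_network, gate_thresholds,
                      rank_nodes, statistical_network, sweep_group_compare)


def z_matrices(z_upper: np.ndarray, n_nodes: int) -> list[FCMatrix]:
    """Build fisher_z FCMatrix objects from per-subject upper-triangle values."""
    iu, ju = np.triu_indices(n_nodes, k=1)
    out = []
    for row in z_upper:
        m = np.zeros((n_nodes, n_nodes))
        m[iu, ju] = row
        out.append(FCMatrix(m + m.T, space="fisher_z"))
    return out


class TestSweepCompare:
    def test_identical_cohorts_nothing_significant(self):
        vals = np.random.default_rng(0).normal(size=(10, 6))
        comp = sweep_group_compare(vals, vals.copy(), np.linspace(0.1, 0.6, 6))
        assert np.all(comp.t_stat == 0.0)
        assert not comp.significant.any()

    def test_huge_shift_significant_everywhere(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(12, 8))
        b = a + 10.0  # 10 SD shift at every threshold
        comp = sweep_group_compare(a, b, np.arange(8) / 10)
        assert comp.significant.all()

    def test_bonferroni_factor_is_grid_size(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(8, 5))
        b = rng.normal(size=(8, 5))
        comp = sweep_group_compare(a, b, np.arange(5) / 10)
        assert np.allclose(comp.p_corrected, np.minimum(comp.p_value * 5, 1.0))

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            sweep_group_compare(np.ones((1, 3)), np.ones((4, 3)), [0.1, 0.2, 0.3])


class TestGate:
    def test_gate_value_is_log_n(self):
        res = gate_thresholds([0.1], [np.array([10.0])], [np.array([2.0])], 1024)
        assert res.gate_value == pytest.approx(np.log(1024))
        assert res.gate_value == pytest.approx(6.931, abs=1e-3)

    def test_admissible_set_ends_where_degree_drops(self):
        thresholds = np.round(np.arange(0.1, 0.61, 0.1), 10)
        deg = np.where(thresholds <= 0.4, 10.0, 4.5)  # ln(128) ~ 4.85
        sig = np.full(thresholds.size, 2.0)
        res = gate_thresholds(thresholds, [deg, deg], [sig, sig], 128)
        assert res.max_admissible == pytest.approx(0.4)
        assert res.admissible.sum() == 4

    def test_sigma_never_above_one_gives_empty_set(self):
        thresholds = np.array([0.1, 0.2])
        res = gate_thresholds(thresholds, [np.array([10, 10.0])],
                              [np.array([0.9, 1.0])], 64)
        assert not res.admissible.any()
        assert res.max_admissible is None


class TestStatisticalNetwork:
    def test_single_strong_edge_survives(self):
        rng = np.random.default_rng(3)
        n = 6
        n_pairs = n * (n - 1) // 2
        z = 0.001 * rng.standard_normal((12, n_pairs))
        z[:, 0] = np.arctanh(0.8) + 0.01 * rng.standard_normal(12)
        stat = statistical_network(z_matrices(z, n), threshold=0.4)
        assert stat.network.n_edges == 1
        assert stat.network.values[0, 1] == 1

    def test_mean_r_condition_excludes_subthreshold_edges(self):
        rng = np.random.default_rng(4)
        z = 0.001 * rng.standard_normal((12, 15))
        z[:, 0] = np.arctanh(0.3) + 0.01 * rng.standard_normal(12)  # significant but r < T
        stat = statistical_network(z_matrices(z, 6), threshold=0.4)
        assert stat.network.n_edges == 0
        stat = statistical_network(z_matrices(z, 6), threshold=0.4,
                                   require_mean_r=False)
        assert stat.network.n_edges == 1

    def test_needs_two_subjects(self):
        with pytest.raises(ValueError, match="2 subjects"):
            statistical_network(z_matrices(np.zeros((1, 15)), 6))


class TestRankings:
    def test_three_values_map_to_normalization_endpoints(self):
        ranking = rank_nodes(np.array([2.0, 4.0, 6.0]), ["a", "b", "c"], k=3)
        assert ranking.table["raw"].tolist() == [6.0, 4.0, 2.0]
        assert ranking.table["normalized"].tolist() == [0.9, 0.5, 0.1]

    def test_constant_values_map_to_half(self):
        ranking = rank_nodes(np.full(5, 3.3), list("abcde"), k=4)
        assert np.all(ranking.table["normalized"] == 0.5)

    def test_full_k_is_permutation_and_ties_break_by_index(self):
        v = np.array([1.0, 3.0, 3.0, 0.5])
        ranking = rank_nodes(v, list("abcd"), k=4)
        assert sorted(ranking.table["node_index"]) == [0, 1, 2, 3]
        assert ranking.table["node_index"].tolist()[:2] == [1, 2]  # tie: low index first

    def test_k_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            ranking = rank_nodes(np.arange(3.0), list("abc"), k=50)
        assert ranking.k == 3


class TestDifferentialNetwork:
    def test_single_planted_enhanced_edge(self):
        rng = np.random.default_rng(5)
        za = 0.05 * rng.standard_normal((20, 15))
        zb = 0.05 * rng.standard_normal((20, 15))
        zb[:, 3] += 1.5
        diff = differential_network(z_matrices(za, 6), z_matrices(zb, 6))
        assert len(diff.edges) == 1
        row = diff.edges.iloc[0]
        assert (row.node_i, row.node_j) == (0, 4)
        assert row.direction == "enhanced"
        assert row.q >= row.p

    def test_group_swap_negates_t_and_flips_directions(self):
        rng = np.random.default_rng(6)
        za = rng.standard_normal((15, 28)) * 0.2
        zb = za + rng.standard_normal((15, 28)) * 0.05 + 0.3
        d1 = differential_network(z_matrices(za, 8), z_matrices(zb, 8))
        d2 = differential_network(z_matrices(zb, 8), z_matrices(za, 8))
        e1 = d1.edges.set_index(["node_i", "node_j"]).sort_index()
        e2 = d2.edges.set_index(["node_i", "node_j"]).sort_index()
        assert e1.index.equals(e2.index)
        assert np.allclose(e1["t_stat"], -e2["t_stat"])
        assert np.allclose(e1["p"], e2["p"])
        assert np.allclose(e1["q"], e2["q"])
        flip = {"enhanced": "weakened", "weakened": "enhanced"}
        assert [flip[d] for d in e1["direction"]] == e2["direction"].tolist()

    def test_welch_agrees_with_pooled_for_balanced_equal_variance(self):
        rng = np.random.default_rng(7)
        za = rng.standard_normal((25, 10))
        zb = rng.standard_normal((25, 10)) + 0.5
        welch = differential_network(z_matrices(za, 5), z_matrices(zb, 5))
        pooled = differential_network(z_matrices(za, 5), z_matrices(zb, 5),
                                      equal_var=True)
        # Welch df differ but with equal n the statistics coincide
        full_w = welch.edges.set_index(["node_i", "node_j"])["t_stat"]
        full_p = pooled.edges.set_index(["node_i", "node_j"])["t_stat"]
        common = full_w.index.intersection(full_p.index)
        assert np.allclose(full_w.loc[common], full_p.loc[common], atol=1e-10)


class TestBenjaminiHochberg:
    def test_matches_first_principles_step_up(self):
        """statsmodels' fdr_bh must agree with a hand-rolled step-up rule on
        random p-value vectors (rejections and adjusted q-values)."""
        rng = np.random.default_rng(8)
        for _ in range(1000):
            m = int(rng.integers(1, 40))
            p = rng.random(m) ** rng.uniform(0.5, 3)
            reject, q, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
            order = np.argsort(p, kind="stable")
            ranked = p[order] * m / np.arange(1, m + 1)
            q_manual = np.minimum.accumulate(ranked[::-1])[::-1]
            q_manual = np.minimum(q_manual, 1.0)
            back = np.empty(m)
            back[order] = q_manual
            assert np.allclose(q, back, atol=1e-12)
            # step-up rejection: largest k with p_(k) <= k/m * alpha
            thresh = np.flatnonzero(p[order] <= np.arange(1, m + 1) / m * 0.05)
            k = thresh.max() + 1 if thresh.size else 0
            manual_reject = np.zeros(m, dtype=bool)
            manual_reject[order[:k]] = True
            assert np.array_equal(reject, manual_reject)
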