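"""Knockout screens, hub statistics, effect stratification, cells."""

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.special import expit

from grnforge.exprmodel import ExpressionParams, SimConfig, SteadyState, simulate_to_steady_state
from grnforge.netgen import GraphParams, generate_network, shortest_path_distances
from grnforge.perturb import (
    CoexpressionSample,
    coexpression,
    hub_counts,
    knockout,
    knockout_screen,
    sample_cells,
    stratify_effects,
)

from conftest import chain_params, isolated_params, make_graph


def make_result(log2fc, expressed=None, ko_genes=None):
    """Wrap a raw matrix as a PerturbationResult (test helper)."""
    from grnforge.perturb import PerturbationResult

    log2fc = np.asarray(log2fc, dtype=float)
    n = log2fc.shape[1]
    expressed = np.ones(n, bool) if expressed is None else np.asarray(expressed)
    ko = np.arange(log2fc.shape[0]) if ko_genes is None else np.asarray(ko_genes)
    fc = log2fc.copy()
    fc[np.arange(len(ko)), ko] = np.nan
    fc[:, ~expressed] = np.nan
    baseline = SteadyState(
        xbar=np.where(expressed, 1.0, 0.0), converged=True,
        iterations_used=0, expressed_mask=expressed,
    )
    return PerturbationResult(
        log2fc=fc, baseline=baseline, expressed_mask=expressed,
        converged_per_ko=np.ones(len(ko), bool), ko_genes=ko,
    )


class TestKnockout:
    def test_zeroes_only_the_targeted_row(self):
        params = chain_params(beta12=2.0)
        ko = knockout(params, 0)
        assert ko.beta.nnz == 0
        assert params.beta.nnz == 1  # original untouched

    def test_gene_without_outgoing_edges_is_a_no_op(self):
        params = chain_params(beta12=2.0)
        ko = knockout(params, 1)
        assert (ko.beta != params.beta).nnz == 0

    def test_other_rows_bit_identical(self):
        g = generate_network(GraphParams(n=30, k=3, w=9, p=0.4,
                                         delta_in=10, delta_out=3, seed=2))
        from grnforge.exprmodel import sample_expression_params

        params = sample_expression_params(g, seed=3)
        ko = knockout(params, 5)
        dense_a, dense_b = params.beta.toarray(), ko.beta.toarray()
        assert np.all(dense_b[5] == 0)
        mask = np.ones(30, bool)
        mask[5] = False
        assert np.array_equal(dense_a[mask], dense_b[mask])

    def test_out_of_range_rejected(self):
        with pytest.raises(IndexError):
            knockout(chain_params(), 7)


class TestScreen:
    def test_chain_knockout_effect_matches_scalar_oracle(self):
        # KO of the regulator reverts the target to its regulator-free
        # fixed point sigma(alpha)/ell
        params = chain_params(beta12=2.0)
        base = simulate_to_steady_state(params, seed=0)
        res = knockout_screen(params, base, seed=1)
        a = params.alpha[0]
        x1 = 0.25
        x2_base = expit(a + 2.0 * x1) / 0.8
        expected = np.log2(0.25 / x2_base)  # ~= -0.546
        assert res.log2fc[0, 1] == pytest.approx(expected, abs=1e-3)
        assert np.isnan(res.log2fc[0, 0])  # self excluded

    def test_three_gene_chain_mediated_effect_matches_scalar_oracle(self):
        # chain 0 -> 1 -> 2 (activators, beta = 2): knocking out gene 0
        # propagates through gene 1 to gene 2 at distance 2
        a = np.log(0.2 / 0.8)
        beta = sp.csr_matrix(([2.0, 2.0], ([0, 1], [1, 2])), shape=(3, 3))
        params = ExpressionParams(alpha=np.full(3, a), ell=np.full(3, 0.8),
                                  beta=beta, s=0.0)
        base = simulate_to_steady_state(params, seed=0)
        res = knockout_screen(params, base, seed=1)
        # scalar fixed-point oracle for both conditions
        x1, x2, x3 = 0.25, 0.0, 0.0
        for _ in range(2000):
            x2 = expit(a + 2 * x1) / 0.8
            x3 = expit(a + 2 * x2) / 0.8
        x3_ko = expit(a + 2 * 0.25) / 0.8  # gene 2 under KO of gene 0
        expected = np.log2(x3_ko / x3)
        assert res.log2fc[0, 2] == pytest.approx(expected, abs=1e-3)
        assert expected < -0.1  # mediated effects are sizeable when unsaturated

    def test_isolated_gene_knockout_has_no_effect(self):
        params = isolated_params()
        g2 = ExpressionParams(
            alpha=np.r_[params.alpha, params.alpha],
            ell=np.r_[params.ell, params.ell],
            beta=sp.csr_matrix((2, 2)), s=1e-4,
        )
        base = simulate_to_steady_state(g2, seed=0)
        res = knockout_screen(g2, base, seed=1)
        assert np.nanmax(np.abs(res.log2fc)) < 1e-3

    def test_screen_equals_gene_by_gene_runs(self):
        from grnforge.exprmodel import sample_expression_params, simulate_batch

        g = generate_network(GraphParams(n=50, k=5, w=9, p=0.5,
                                         delta_in=10, delta_out=3, seed=4))
        params = sample_expression_params(g, seed=5)
        base = simulate_to_steady_state(params, seed=6)
        res = knockout_screen(params, base, seed=7)
        eps = np.finfo(float).eps
        for j in [0, 17, 42]:
            solo = simulate_batch(
                params, seeds=[np.random.SeedSequence((7, j))],
                init=base.xbar, ko_genes=[j],
            )[0]
            row = np.log2(np.maximum(solo.xbar, eps)) - np.log2(np.maximum(base.xbar, eps))
            mask = ~np.isnan(res.log2fc[j])
            assert np.array_equal(row[mask], res.log2fc[j][mask])


class TestHubCounts:
    def test_all_zero_effects_give_no_hubs(self):
        res = make_result(np.zeros((5, 5)))
        summ = hub_counts(res, count_thresh=2)
        assert summ.n_hub_ko == 0 and summ.n_hub_target == 0

    def test_constructed_hub_is_counted(self):
        fc = np.zeros((200, 200))
        fc[0, 1:151] = 0.2  # gene 0 changes 150 genes
        res = make_result(fc)
        summ = hub_counts(res, effect_thresh=0.1, count_thresh=100)
        assert summ.n_hub_ko == 1
        assert summ.n_hub_target == 0

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(0)
        fc = rng.normal(scale=0.1, size=(40, 40))
        expressed = rng.random(40) > 0.2
        res = make_result(fc, expressed=expressed)
        summ = hub_counts(res, effect_thresh=0.1, count_thresh=3)
        hub_ko = hub_tgt = 0
        for j in range(40):
            if not expressed[j]:
                continue
            cnt = sum(
                1 for i in range(40)
                if i != j and expressed[i] and abs(fc[j, i]) > 0.1
            )
            hub_ko += cnt >= 3
        for i in range(40):
            if not expressed[i]:
                continue
            cnt = sum(
                1 for j in range(40)
                if i != j and expressed[j] and abs(fc[j, i]) > 0.1
            )
            hub_tgt += cnt >= 3
        assert summ.n_hub_ko == hub_ko and summ.n_hub_target == hub_tgt


class TestStratify:
    def test_chain_effect_is_mediated_at_distance_two(self):
        g = make_graph([(0, 1), (1, 2)], n=3, groups=[0, 0, 1])
        fc = np.zeros((3, 3))
        fc[0, 2] = 0.5
        res = make_result(fc)
        strata = stratify_effects(res, shortest_path_distances(g), g.group_of)
        assert 2 in strata.by_distance
        assert 0.5 in strata.by_distance[2]
        assert 0.5 in strata.mediated and 0.5 not in strata.direct

    def test_distance_strata_partition_all_valid_pairs(self, small_graph):
        rng = np.random.default_rng(1)
        n = small_graph.n_nodes
        res = make_result(rng.normal(size=(n, n)), expressed=rng.random(n) > 0.1)
        strata = stratify_effects(res, shortest_path_distances(small_graph),
                                  small_graph.group_of)
        total = sum(len(v) for v in strata.by_distance.values())
        assert total == res.valid_mask().sum()
        assert len(strata.direct) + len(strata.mediated) == total
        assert len(strata.within_group) + len(strata.across_group) == total

    def test_fractions_match_per_pair_loop(self, small_graph):
        rng = np.random.default_rng(2)
        n = small_graph.n_nodes
        fc = rng.normal(scale=0.02, size=(n, n))
        res = make_result(fc)
        d = shortest_path_distances(small_graph)
        strata = stratify_effects(res, d, small_graph.group_of, threshold=0.01)
        for dv, frac in strata.fraction_above_by_distance.items():
            vals = [
                abs(fc[j, i])
                for j in range(n) for i in range(n)
                if i != j and d[j, i] == dv
            ]
            assert frac == pytest.approx(np.mean([v > 0.01 for v in vals]))


class TestCells:
    def test_no_noise_keeps_cells_at_the_fixed_point(self):
        params = isolated_params(sig_alpha=0.2, ell=0.8, s=0.0)
        base = SteadyState(xbar=np.array([0.25]), converged=True,
                           iterations_used=0, expressed_mask=np.array([True]))
        sample = sample_cells(params, base, n_steps=50, seed=0)
        assert sample.cells.shape == (50, 1)
        assert np.allclose(sample.cells, 0.25, atol=1e-12)

    def test_cell_means_near_baseline_with_noise(self):
        from grnforge.exprmodel import sample_expression_params

        g = generate_network(GraphParams(n=30, k=3, w=9, p=0.5,
                                         delta_in=10, delta_out=3, seed=8))
        params = sample_expression_params(g, seed=9, s=1e-4)
        base = simulate_to_steady_state(params, seed=10)
        sample = sample_cells(params, base, n_steps=2000, seed=11)
        assert np.max(np.abs(sample.cells.mean(axis=0) - base.xbar)) < 1e-2


class TestCoexpression:
    def test_duplicated_genes_fully_correlated(self):
        rng = np.random.default_rng(3)
        col = rng.random(20)
        cells = np.column_stack([col, col, rng.random(20)])
        corr = coexpression(CoexpressionSample(cells=cells, origin=np.zeros(20)))
        assert corr[0, 1] == pytest.approx(1.0)
        assert np.allclose(np.diag(corr), 1.0)

    def test_independent_noise_weakly_correlated(self):
        rng = np.random.default_rng(4)
        cells = rng.normal(size=(4000, 4))
        corr = coexpression(CoexpressionSample(cells=cells, origin=np.zeros(4000)))
        off = corr[~np.eye(4, dtype=bool)]
        assert np.max(np.abs(off)) < 0.08

    def test_matches_two_pass_pearson_oracle(self):
        rng = np.random.default_rng(5)
        cells = rng.random((10, 5))
        corr = coexpression(CoexpressionSample(cells=cells, origin=np.zeros(10)))
        expected = np.corrcoef(cells.T)
        assert np.allclose(corr, expected, atol=1e-12)

    def test_zero_variance_gene_flagged_undefined(self):
        cells = np.column_stack([np.ones(10), np.arange(10.0)])
        corr = coexpression(CoexpressionSample(cells=cells, origin=np.zeros(10)))
        assert np.isnan(corr[0, 1]) and np.isnan(corr[0, 0])
        assert corr[1, 1] == 1.0

    def test_single_cell_rejected(self):
        with pytest.raises(ValueError):
            coexpression(CoexpressionSample(cells=np.ones((1, 3)), origin=np.zeros(1)))
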