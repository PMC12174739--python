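"""Correlation, soft thresholding, topological overlap and connectivity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from degmeta.coexpression import (
    SoftThresholdScan,
    adjacency,
    build_connectivity_model,
    connectivity_scores,
    connectivity_weights,
    correlation_matrix,
    pick_soft_threshold,
    tom_similarity,
)
from degmeta.synthetic_data import SynthesisConfig, simulate_expression


def expr_frame(rows, genes=None):
    rows = np.asarray(rows, dtype=float)
    genes = genes or [f"g{i}" for i in range(rows.shape[0])]
    return pd.DataFrame(rows, index=genes)


class TestCorrelation:
    def test_identical_rows_correlate_perfectly(self):
        corr = correlation_matrix(expr_frame([[1, 2, 3, 4], [1, 2, 3, 4]]))
        assert corr.iloc[0, 1] == pytest.approx(1.0)

    def test_negated_row_anticorrelates(self):
        corr = correlation_matrix(expr_frame([[1, 2, 3, 4], [-1, -2, -3, -4]]))
        assert corr.iloc[0, 1] == pytest.approx(-1.0)

    def test_matches_direct_pearson_formula(self):
        rows = np.array([[0.1, 1.4, -0.3, 2.2], [1.1, 0.2, 0.4, -0.6], [0.0, 2.0, 1.0, 3.0]])
        corr = correlation_matrix(expr_frame(rows)).to_numpy()
        for i in range(3):
            for j in range(3):
                xi, xj = rows[i] - rows[i].mean(), rows[j] - rows[j].mean()
                expected = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert corr[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_gene_is_error_naming_the_gene(self):
        with pytest.raises(ValueError, match="flatgene"):
            correlation_matrix(expr_frame([[1, 2, 3], [5, 5, 5]], genes=["ok", "flatgene"]))

    def test_too_few_samples_is_error(self):
        with pytest.raises(ValueError, match="samples"):
            correlation_matrix(expr_frame([[1, 2], [2, 1]]))


class TestAdjacency:
    @pytest.mark.parametrize("beta", [1.0, 2.0, 6.0])
    def test_perfect_correlation_saturates(self, beta):
        corr = np.array([[1.0, 1.0], [1.0, 1.0]])
        assert adjacency(corr, beta)[0, 1] == pytest.approx(1.0)

    def test_unsigned_squares_magnitude(self):
        corr = np.array([[1.0, -0.5], [-0.5, 1.0]])
        assert adjacency(corr, 2.0, "unsigned")[0, 1] == pytest.approx(0.25)

    def test_signed_halves_then_powers(self):
        corr = np.array([[1.0, -0.5], [-0.5, 1.0]])
        assert adjacency(corr, 2.0, "signed")[0, 1] == pytest.approx(0.0625)

    def test_unsigned_invariant_to_sign_flip_signed_not(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((4, 10))
        flipped = x.copy()
        flipped[2] *= -1.0
        c, cf = np.corrcoef(x), np.corrcoef(flipped)
        assert np.allclose(adjacency(c, 3.0, "unsigned"), adjacency(cf, 3.0, "unsigned"))
        assert not np.allclose(adjacency(c, 3.0, "signed"), adjacency(cf, 3.0, "signed"))


def four_node_adjacency():
    a = np.zeros((4, 4))
    a[0, 1] = a[1, 0] = 0.8
    a[0, 2] = a[2, 0] = 0.4
    a[1, 2] = a[2, 1] = 0.5
    np.fill_diagonal(a, 1.0)
    return a


class TestTOM:
    def test_perfect_module_has_unit_overlap(self):
        a = np.ones((3, 3))
        assert np.allclose(tom_similarity(a), 1.0)

    def test_empty_graph_has_zero_overlap(self):
        a = np.eye(5)
        tom = tom_similarity(a)
        off = tom[~np.eye(5, dtype=bool)]
        assert np.all(off == 0.0)

    def test_hand_computed_four_node_example(self):
        # TOM_01 = (0.4*0.5 + 0.8) / (min(1.2, 1.3) + 1 - 0.8) = 1.0 / 1.4
        tom = tom_similarity(four_node_adjacency())
        assert tom[0, 1] == pytest.approx(1.0 / 1.4, abs=1e-12)

    def test_connectivity_is_row_sum_of_tom(self):
        tom = tom_similarity(four_node_adjacency())
        k = connectivity_scores(tom)
        expected = tom.sum(axis=1) - 1.0  # diagonal excluded
        assert np.allclose(k, expected, atol=1e-12)

    def test_isolated_gene_has_zero_connectivity(self):
        a = np.eye(3)
        a[0, 1] = a[1, 0] = 0.9
        assert connectivity_scores(tom_similarity(a))[2] == pytest.approx(0.0)

    def test_non_symmetric_input_is_error(self):
        a = four_node_adjacency()
        a[0, 1] = 0.1
        with pytest.raises(ValueError, match="symmetric"):
            tom_similarity(a)

    def test_blocked_computation_is_identical(self):
        rng = np.random.default_rng(3)
        c = np.corrcoef(rng.standard_normal((30, 12)))
        a = adjacency(c, 4.0)
        full = tom_similarity(a)
        for block in (1, 7, 30, 100):
            assert np.array_equal(tom_similarity(a, block_size=block), full)

    @settings(derandomize=True, max_examples=60)
    @given(st.integers(0, 10_000), st.floats(0.05, 0.9))
    def test_bounds_and_shared_neighbor_monotonicity(self, seed, bump):
        rng = np.random.default_rng(seed)
        n = 6
        a = rng.uniform(0.0, 0.9, size=(n, n))
        a = (a + a.T) / 2.0
        np.fill_diagonal(a, 1.0)
        tom = tom_similarity(a)
        off = tom[~np.eye(n, dtype=bool)]
        assert np.all(off >= -1e-12) and np.all(off <= 1.0 + 1e-12)
        # Strengthening a shared neighbour of genes 0 and 1 raises the
        # shared-neighbour term; TOM_01 cannot drop as long as gene 1 (whose
        # connectivity is untouched) supplies the min(k) in the denominator.
        # (Without that proviso the claim is false: the bump also raises k_0,
        # and a larger denominator can outweigh the numerator gain.)
        a2 = a.copy()
        a2[0, 2] = a2[2, 0] = min(1.0, a[0, 2] + bump * (1 - a[0, 2]))
        k0_new = a2[0].sum() - 1.0
        k1 = a[1].sum() - 1.0
        if k1 <= min(a[0].sum() - 1.0, k0_new):
            before, after = tom[0, 1], tom_similarity(a2)[0, 1]
            assert after >= before - 1e-12


class TestSoftThreshold:
    def test_single_candidate_is_chosen(self):
        corr = np.corrcoef(np.random.default_rng(1).standard_normal((20, 10)))
        scan = pick_soft_threshold(corr, SoftThresholdScan(candidate_powers=(6,)))
        assert scan.chosen_power == 6

    def test_identity_correlation_takes_warning_path(self):
        scan = pick_soft_threshold(np.eye(30))
        assert not scan.target_reached
        assert scan.chosen_power in scan.candidate_powers

    def test_modular_expression_reaches_scale_free_fit(self):
        cfg = SynthesisConfig(seed=11, n_universe_genes=800, n_modules=8)
        corr = correlation_matrix(simulate_expression(cfg))
        scan = pick_soft_threshold(corr)
        assert scan.target_reached
        assert scan.fit_r2[scan.chosen_power] >= 0.8
        # selection rule: no smaller candidate power reaches the target
        smaller = [p for p in scan.candidate_powers if p < scan.chosen_power]
        assert all(scan.fit_r2[p] < 0.8 for p in smaller)

    def test_empty_candidates_is_error(self):
        with pytest.raises(ValueError):
            pick_soft_threshold(np.eye(5), SoftThresholdScan(candidate_powers=()))


class TestConnectivityModel:
    def test_planted_modules_outrank_background_connectivity(self):
        # 100 genes in correlated modules stacked over 100 independent genes
        cfg = SynthesisConfig(seed=5, n_universe_genes=100, n_modules=2, n_samples=40)
        modular = simulate_expression(cfg)
        noise = pd.DataFrame(
            np.random.default_rng(6).standard_normal((100, cfg.n_samples)),
            index=range(10_001, 10_101), columns=modular.columns,
        )
        model = build_connectivity_model(pd.concat([modular, noise]), beta=6)
        assert model.connectivity.iloc[:100].mean() > model.connectivity.iloc[100:].mean()

    def test_adjacency_basis_option(self):
        cfg = SynthesisConfig(seed=5, n_universe_genes=60, n_modules=2, n_samples=30)
        expr = simulate_expression(cfg)
        m_tom = build_connectivity_model(expr, beta=4, connectivity_basis="tom")
        m_adj = build_connectivity_model(expr, beta=4, connectivity_basis="adjacency")
        adj = m_adj.adjacency.to_numpy()
        assert np.allclose(m_adj.connectivity, adj.sum(axis=1) - 1.0)
        assert not np.allclose(m_tom.connectivity, m_adj.connectivity)

    def test_missing_universe_genes_get_median_weight(self):
        k = pd.Series({1: 2.0, 2: 4.0, 3: 6.0}, name="connectivity")
        weights, missing = connectivity_weights([1, 2, 3, 99], k)
        assert missing == [99]
        assert weights[99] == pytest.approx(4.0)
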