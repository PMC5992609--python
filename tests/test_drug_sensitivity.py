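"""Expression-IC50 correlation screen and the random-gene-set null."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from oracles import mannwhitney_exact_less
from pdxresist.drug_sensitivity_null import (
    gene_set_negative_enrichment,
    mannwhitney_less,
    negative_fdr_threshold,
    per_gene_drug_pcc,
    random_set_null,
)
from pdxresist.errors import ValidationError
from pdxresist.synthetic_data import SimulationConfig, simulate_expression_drug


def _frame(rows: dict, cells=None):
    cells = cells or [f"CL{i}" for i in range(len(next(iter(rows.values()))))]
    return pd.DataFrame(rows, index=cells).T


class TestPerGenePcc:
    def test_perfect_anti_and_pro_correlation(self):
        expr = _frame({"NEG": [1, 2, 3], "POS": [1, 2, 3]})
        drug = pd.Series([3, 2, 1], index=expr.columns)
        result = per_gene_drug_pcc(expr, drug)
        assert result.loc["NEG", "pcc"] == pytest.approx(-1.0)
        drug_up = pd.Series([1, 2, 3], index=expr.columns)
        assert per_gene_drug_pcc(expr, drug_up).loc["POS", "pcc"] == pytest.approx(1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal(12)
        expr = _frame({"G": base, "G_SCALED": 5 * base + 7})
        drug = pd.Series(rng.standard_normal(12), index=expr.columns)
        result = per_gene_drug_pcc(expr, drug)
        assert result.loc["G", "pcc"] == pytest.approx(result.loc["G_SCALED", "pcc"])

    def test_matches_scipy_with_missing_values(self):
        rng = np.random.default_rng(1)
        values = rng.standard_normal(20)
        values[3] = np.nan
        expr = _frame({"G": values})
        drug = pd.Series(rng.standard_normal(20), index=expr.columns)
        result = per_gene_drug_pcc(expr, drug)
        mask = ~np.isnan(values)
        r_ref, p_ref = pearsonr(values[mask], drug.to_numpy()[mask])
        assert result.loc["G", "pcc"] == pytest.approx(r_ref, rel=1e-10)
        assert result.loc["G", "p"] == pytest.approx(p_ref, rel=1e-8)
        assert result.loc["G", "n_pairs"] == 19

    def test_gene_with_too_few_pairs_omitted(self):
        expr = _frame({"OK": [1.0, 2.0, 5.0, 3.0], "BAD": [1.0, np.nan, np.nan, 2.0]})
        drug = pd.Series([1.0, 3.0, 2.0, 4.0], index=expr.columns)
        result = per_gene_drug_pcc(expr, drug)
        assert list(result.index) == ["OK"]

    def test_duplicate_gene_names_rejected(self):
        expr = pd.DataFrame(
            np.ones((2, 4)), index=["G", "G"], columns=[f"CL{i}" for i in range(4)]
        )
        drug = pd.Series(np.ones(4), index=expr.columns)
        with pytest.raises(ValidationError):
            per_gene_drug_pcc(expr, drug)


class TestNegativeThreshold:
    def _results(self, rows):
        return pd.DataFrame(rows, columns=["pcc", "q"]).assign(n_pairs=30, p=0.0)

    def test_single_significant_negative_gene(self):
        rng = np.random.default_rng(2)
        z = rng.standard_normal(30)
        expr = _frame({"G": -0.9 * z + np.sqrt(1 - 0.81) * rng.standard_normal(30)})
        drug = pd.Series(z, index=expr.columns)
        result = per_gene_drug_pcc(expr, drug)
        threshold = negative_fdr_threshold(result)
        assert threshold == pytest.approx(result.loc["G", "pcc"])
        assert threshold < -0.5

    def test_no_negative_correlations_gives_none(self):
        assert negative_fdr_threshold(self._results([(0.3, 0.01), (0.5, 0.001)])) is None

    def test_least_extreme_significant_pcc_selected(self):
        results = self._results([(-0.5, 0.01), (-0.2, 0.04), (-0.1, 0.2)])
        assert negative_fdr_threshold(results) == pytest.approx(-0.2)


@pytest.fixture(scope="module")
def small_sim():
    config = SimulationConfig(seed=11, n_genes=120, n_cell_lines=60, planted_rho=0.0)
    expr, drug, _ = simulate_expression_drug(config)
    return expr, drug


class TestRandomSetNull:
    def test_deterministic_given_seed(self, small_sim):
        expr, drug = small_sim
        a = random_set_null(10, expr, drug, n_sets=50, seed=5)
        b = random_set_null(10, expr, drug, n_sets=50, seed=5)
        assert np.array_equal(a.pccs, b.pccs) and np.array_equal(a.gene_indices, b.gene_indices)
        c = random_set_null(10, expr, drug, n_sets=50, seed=6)
        assert not np.array_equal(a.gene_indices, c.gene_indices)

    def test_shape_contract(self, small_sim):
        expr, drug = small_sim
        null = random_set_null(10, expr, drug, n_sets=40, seed=1)
        assert null.pccs.shape == (40, 10)
        # within one set genes are drawn without replacement
        for row in null.gene_indices:
            assert len(set(row)) == 10

    def test_independent_data_centres_null_at_zero(self, small_sim):
        expr, drug = small_sim
        null = random_set_null(15, expr, drug, n_sets=300, seed=3)
        assert abs(null.set_medians().mean()) < 0.05

    def test_oversized_query_rejected(self, small_sim):
        expr, drug = small_sim
        with pytest.raises(ValidationError):
            random_set_null(10_000, expr, drug, n_sets=5, seed=0)


class TestMannWhitney:
    def test_toy_example_matches_enumeration(self):
        u, p = mannwhitney_less([1, 2], [3, 4])
        assert (u, p) == (0.0, pytest.approx(1 / 6))
        u_ref, p_ref = mannwhitney_exact_less([1, 2], [3, 4])
        assert (u, p) == (u_ref, pytest.approx(p_ref))

    @pytest.mark.parametrize("n1,n2,seed", [(3, 5, 0), (6, 6, 1), (8, 7, 2), (2, 8, 3)])
    def test_exact_branch_matches_enumeration(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        x = rng.permutation(np.arange(1.0, n1 + n2 + 1))[:n1]
        y = np.setdiff1d(np.arange(1.0, n1 + n2 + 1), x)
        u, p = mannwhitney_less(x, y)
        u_ref, p_ref = mannwhitney_exact_less(x, y)
        assert u == u_ref
        assert p == pytest.approx(p_ref, rel=1e-12)

    def test_identical_distributions_give_half(self):
        rng = np.random.default_rng(4)
        pooled = rng.standard_normal(400)
        _, p = mannwhitney_less(pooled[:200], pooled[200:])
        assert 0.2 < p < 0.8


class TestGeneSetEnrichment:
    def test_planted_negative_set_detected(self):
        config = SimulationConfig(
            seed=21, n_genes=600, n_cell_lines=200, planted_rho=-0.4, planted_set_size=20
        )
        expr, drug, truth = simulate_expression_drug(config)
        null = random_set_null(20, expr, drug, n_sets=1000, seed=22)
        _, p = gene_set_negative_enrichment(set(truth.planted_genes), expr, drug, null)
        assert p < 0.001

    def test_p_monotone_in_effect_and_sample_size(self):
        def enrichment_p(rho, n_cells):
            config = SimulationConfig(
                seed=31, n_genes=300, n_cell_lines=n_cells,
                planted_rho=rho, planted_set_size=15,
            )
            expr, drug, truth = simulate_expression_drug(config)
            null = random_set_null(15, expr, drug, n_sets=300, seed=32)
            return gene_set_negative_enrichment(set(truth.planted_genes), expr, drug, null)[1]

        assert enrichment_p(-0.4, 100) < enrichment_p(-0.2, 100)
        assert enrichment_p(-0.2, 400) < enrichment_p(-0.2, 50)

    def test_null_sets_reject_at_nominal_rate(self):
        rejections = []
        for seed in range(20):
            config = SimulationConfig(
                seed=seed, n_genes=150, n_cell_lines=50, planted_rho=0.0, planted_set_size=10
            )
            expr, drug, truth = simulate_expression_drug(config)
            null = random_set_null(10, expr, drug, n_sets=100, seed=seed + 1000)
            _, p = gene_set_negative_enrichment(set(truth.planted_genes), expr, drug, null)
            rejections.append(p < 0.05)
        # 20 Bernoulli(0.05) trials: >5 rejections has probability < 1e-3
        assert sum(rejections) <= 5

    def test_empirical_method_agrees_in_direction(self):
        config = SimulationConfig(
            seed=41, n_genes=200, n_cell_lines=150, planted_rho=-0.4, planted_set_size=15
        )
        expr, drug, truth = simulate_expression_drug(config)
        null = random_set_null(15, expr, drug, n_sets=200, seed=42)
        _, p = gene_set_negative_enrichment(
            set(truth.planted_genes), expr, drug, null, method="empirical"
        )
        assert p < 0.05
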