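"""Hypergeometric composition enrichment, pseudobulk and correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from immatlas import (correlation_matrix, gene_score_correlation,
                      hypergeometric_enrichment, pseudobulk_profiles)

from conftest import make_bundle


def enum_upper_tail(n_total, k_col, n_row, k):
    """Oracle: P(overlap >= k) by enumerating all draws of n_row from N."""
    hits = total = 0
    for subset in itertools.combinations(range(n_total), n_row):
        total += 1
        hits += sum(1 for i in subset if i < k_col) >= k
    return hits / total if total else 1.0


def meta_from_margins(row_sizes, col_of_cell):
    rows = [r for r, n in row_sizes.items() for _ in range(n)]
    return pd.DataFrame({"row_var": rows, "col_var": col_of_cell})


class TestHypergeometric:
    def test_derived_four_of_five_example(self):
        # N=10, K=4, n=5, k=4 -> 6/252
        meta = pd.DataFrame({
            "row_var": ["r1"] * 5 + ["r2"] * 5,
            "col_var": ["c1"] * 4 + ["c2"] * 6,
        })
        em = hypergeometric_enrichment(meta, "row_var", "col_var")
        p = em.table.query("row == 'r1' and col == 'c1'")["p_value"].iloc[0]
        assert p == pytest.approx(6 / 252, rel=1e-12)
        assert em.table.query("row == 'r1' and col == 'c1'")["overlap"].iloc[0] == 4

    def test_zero_overlap_gives_p_one(self):
        meta = pd.DataFrame({"row_var": ["a", "a", "b"], "col_var": ["x", "x", "y"]})
        em = hypergeometric_enrichment(meta, "row_var", "col_var")
        assert em.table.query("row == 'a' and col == 'y'")["p_value"].iloc[0] == 1.0

    def test_whole_population_row_gives_p_one(self):
        meta = pd.DataFrame({"row_var": ["a"] * 6, "col_var": ["x"] * 2 + ["y"] * 4})
        em = hypergeometric_enrichment(meta, "row_var", "col_var")
        assert (em.table["p_value"] == 1.0).all()
        assert (em.table["overlap"] == em.table["col_total"]).all()

    def test_empty_table_is_hard_error(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(pd.DataFrame(columns=["row_var", "col_var"]),
                                      "row_var", "col_var")

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(2, 9), st.data())
    def test_matches_enumeration(self, n_total, data):
        k_col = data.draw(st.integers(1, n_total - 1))
        n_row = data.draw(st.integers(1, n_total - 1))
        meta = pd.DataFrame({
            "row_var": ["r"] * n_row + ["other"] * (n_total - n_row),
            "col_var": ["c"] * k_col + ["d"] * (n_total - k_col),
        })
        em = hypergeometric_enrichment(meta, "row_var", "col_var")
        row = em.table.query("row == 'r' and col == 'c'").iloc[0]
        assert row["p_value"] == pytest.approx(
            enum_upper_tail(n_total, k_col, n_row, int(row["overlap"])), abs=1e-12)

    def test_contingency_conservation(self):
        rng = np.random.default_rng(0)
        meta = pd.DataFrame({
            "row_var": rng.choice(list("abcd"), 200),
            "col_var": rng.choice(list("xyz"), 200),
        })
        em = hypergeometric_enrichment(meta, "row_var", "col_var")
        for col, grp in em.table.groupby("col"):
            assert grp["overlap"].sum() == grp["col_total"].iloc[0]


class TestPseudobulk:
    def test_identical_cells_give_member_profile(self):
        counts = np.tile([[2, 4, 4]], (3, 1))
        bundle = make_bundle(counts, organs=["A"] * 3)
        pb = pseudobulk_profiles(bundle, "organ", normalized=False)
        np.testing.assert_allclose(pb.loc["A"], [2, 4, 4])

    def test_mean_of_two_cells(self):
        counts = np.array([[1, 9], [3, 7]])
        bundle = make_bundle(counts, organs=["A", "A"])
        pb = pseudobulk_profiles(bundle, "organ", normalized=False)
        np.testing.assert_allclose(pb.loc["A"], [2.0, 8.0])

    def test_strata_rows_match_ground_truth(self, demo_qc):
        gated, truth = demo_qc
        pb = pseudobulk_profiles(gated, ["organ", "cell_type"])
        n_strata = truth.cells.groupby(["organ", "cell_type"]).ngroups
        assert pb.shape[0] == n_strata

    def test_unknown_column_is_hard_error(self, demo_qc):
        with pytest.raises(ValueError):
            pseudobulk_profiles(demo_qc[0], "tissue")


class TestCorrelationMatrix:
    def _pb(self, rows, genes=6):
        return pd.DataFrame(rows, index=[f"o{i}" for i in range(len(rows))],
                            columns=[f"g{j}" for j in range(genes)])

    def test_duplicated_rows_correlate_perfectly(self):
        row = [1.0, 4.0, 2.0, 7.0, 3.0, 5.0]
        corr = correlation_matrix(self._pb([row, row, [2, 2, 9, 1, 4, 4]]))
        assert corr.iloc[0, 1] == pytest.approx(1.0)
        np.testing.assert_allclose(np.diag(corr), 1.0)

    def test_negation_pattern_gives_minus_one(self):
        row = np.array([1.0, 4.0, 2.0, 7.0, 3.0, 5.0])
        corr = correlation_matrix(self._pb([row, row.max() - row]))
        assert corr.iloc[0, 1] == pytest.approx(-1.0)

    def test_gene_permutation_and_constant_shift_invariance(self):
        rng = np.random.default_rng(1)
        pb = self._pb(rng.uniform(0, 5, (4, 6)))
        base = correlation_matrix(pb)
        perm = rng.permutation(pb.columns)
        np.testing.assert_allclose(correlation_matrix(pb[perm]), base, atol=1e-12)
        np.testing.assert_allclose(correlation_matrix(pb + 3.0), base, atol=1e-12)

    def test_divergent_organ_has_lowest_mean_correlation(self):
        rng = np.random.default_rng(2)
        shared = rng.uniform(1, 5, 40)
        pb = pd.DataFrame(
            [shared + rng.normal(0, 0.05, 40),
             shared + rng.normal(0, 0.05, 40),
             rng.permutation(shared)],
            index=["o1", "o2", "divergent"], columns=[f"g{j}" for j in range(40)])
        corr = correlation_matrix(pb)
        off = corr.where(~np.eye(3, dtype=bool))
        assert off.mean(axis=1).idxmin() == "divergent"

    def test_single_group_is_hard_error(self):
        with pytest.raises(ValueError):
            correlation_matrix(self._pb([[1, 2, 3, 4, 5, 6]]))


class TestGeneScoreCorrelation:
    def test_score_equal_to_expression_gives_r_one(self):
        counts = np.array([[1, 9], [5, 5], [9, 1], [3, 7]])
        bundle = make_bundle(counts, organs=["A"] * 4)
        expr = np.log1p(1e4 * counts[:, 0] / counts.sum(1))
        bundle.cell_meta["score"] = expr
        res = gene_score_correlation(bundle, "g0", "score", within="A")
        assert res.defined and res.r == pytest.approx(1.0)

    def test_independent_score_is_uncorrelated(self):
        from immatlas import PlantedGene, SimulationDesign, simulate_atlas
        design = SimulationDesign(
            organs=("kidney", "other"), cell_types=("T_NK",),
            cells_per_stratum=np.array([[2000], [100]]), n_genes=400,
            organ_specific=(PlantedGene("GPX3s", "kidney", 6.0),), seed=8)
        bundle, _ = simulate_atlas(design)
        res = gene_score_correlation(bundle, "GPX3s", "doublet_score", within="kidney")
        assert res.n == 2000
        assert res.defined and abs(res.r) < 0.1

    def test_two_cells_is_hard_error(self):
        bundle = make_bundle(np.ones((2, 2)), score=[0.1, 0.2])
        with pytest.raises(ValueError, match="insufficient cells"):
            gene_score_correlation(bundle, "g0", "score")

    def test_constant_expression_is_undefined_flag(self):
        bundle = make_bundle(np.ones((4, 2)), score=[0.1, 0.2, 0.3, 0.4])
        res = gene_score_correlation(bundle, "g0", "score")
        assert not res.defined and np.isnan(res.r)
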