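import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stemsig.core_data import ExpressionMatrix, PhenotypeTable
from stemsig.fir_signature import (
    FIRConfig,
    binomial_tail,
    fir_score,
    one_way_f,
    rank_genes,
    score_percentile,
    select_signature,
    t_percentile,
    t_statistics,
    threshold_sweep,
)
from stemsig.synthetic_data import LandscapeConfig, simulate_landscape

from conftest import brute_force_fir


class TestFirScore:
    def test_contiguous_anchors_at_bottom_score_one(self):
        values = [0.1, 0.2, 5.0, 6.0, 7.0, 8.0]
        anchors = [True, True, False, False, False, False]
        res = fir_score(values, anchors, w=2)
        assert (res.score, res.k_best, res.window_start) == (1.0, 2, 1)

    def test_split_anchors_earliest_best_window(self):
        # anchors at sorted positions 2, 3, 5 of 10; windows 1-3 hold two
        # anchors each, all later windows at most one
        values = [(i + 1) / 10 for i in range(10)]
        anchors = [i in (1, 2, 4) for i in range(10)]
        res = fir_score(values, anchors, w=3)
        assert (res.score, res.k_best, res.window_start) == (2 / 3, 2, 1)

    def test_all_anchor_samples_score_one(self):
        values = [3.0, 1.0, 2.0]
        for w in (1, 2, 3):
            assert fir_score(values, [True] * 3, w).score == 1.0

    def test_window_larger_than_samples_errors(self):
        with pytest.raises(ValueError):
            fir_score([1.0, 2.0], [True, False], w=3)

    def test_zero_anchors_errors(self):
        with pytest.raises(ValueError, match="anchor"):
            fir_score([1.0, 2.0], [False, False], w=1)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        s, w = 30, 6
        values = rng.normal(size=s)
        anchors = np.zeros(s, bool)
        anchors[rng.choice(s, size=6, replace=False)] = True
        res = fir_score(values, anchors, w)
        expected = brute_force_fir(values, anchors, w)
        assert (res.score, res.k_best, res.window_start) == expected

    @given(st.lists(st.integers(-50, 50), min_size=4, max_size=25))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_invariant_to_monotone_transform(self, raw):
        # integer-valued data keeps exp injective in floats, so the
        # transform is genuinely strictly monotone (ties stay ties)
        values = np.asarray(raw, dtype=float)
        rng = np.random.default_rng(len(values))
        anchors = np.zeros(len(values), bool)
        anchors[rng.choice(len(values), size=2, replace=False)] = True
        w = 2
        a = fir_score(values, anchors, w)
        b = fir_score(np.exp(values / 10), anchors, w)
        assert (a.score, a.k_best, a.window_start) == (b.score, b.k_best, b.window_start)

    def test_appending_extreme_non_anchor_never_lowers_score(self):
        rng = np.random.default_rng(11)
        values = rng.normal(size=20)
        anchors = np.zeros(20, bool)
        anchors[rng.choice(20, size=5, replace=False)] = True
        before = fir_score(values, anchors, w=5).score
        values2 = np.append(values, values.max() + 10.0)
        anchors2 = np.append(anchors, False)
        after = fir_score(values2, anchors2, w=5).score
        assert after >= before


class TestBinomialTail:
    @pytest.mark.parametrize(
        "k,n,p,expected",
        [
            (3, 3, 0.5, 0.125),
            (0, 7, 0.3, 1.0),
            (2, 3, 0.5, 0.5),  # 3 * 0.25 * 0.5 + 0.125
        ],
    )
    def test_closed_form_values(self, k, n, p, expected):
        assert binomial_tail(k, n, p) == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_pmf_summation(self):
        for n in (1, 5, 17, 40):
            for p in (0.05, 0.5):
                for k in range(n + 1):
                    direct = sum(
                        math.comb(n, i) * p**i * (1 - p) ** (n - i)
                        for i in range(k, n + 1)
                    )
                    assert binomial_tail(k, n, p) == pytest.approx(direct, abs=1e-12)

    def test_out_of_range_arguments_error(self):
        with pytest.raises(ValueError):
            binomial_tail(5, 3, 0.5)
        with pytest.raises(ValueError):
            binomial_tail(1, 3, 1.5)


def planted_matrix(seed=0, n_genes=40, n_samples=24, n_anchor=4):
    """One perfectly banded gene among Gaussian noise genes."""
    rng = np.random.default_rng(seed)
    values = rng.normal(size=(n_genes, n_samples))
    anchors = np.zeros(n_samples, bool)
    anchors[:n_anchor] = True
    # planted gene: anchors in a band no other sample enters
    values[0, anchors] = rng.uniform(100.0, 100.1, size=n_anchor)
    ids = [f"g{i:02d}" for i in range(n_genes)]
    matrix = ExpressionMatrix(values, ids, [f"s{j}" for j in range(n_samples)])
    pheno = PhenotypeTable.from_records(
        matrix.sample_ids, list(anchors),
        ["pluripotent" if a else "normal" for a in anchors],
    )
    return matrix, pheno


class TestRankGenes:
    def test_planted_gene_ranks_first(self):
        matrix, pheno = planted_matrix()
        table = rank_genes(matrix, pheno)
        assert table.iloc[0]["gene_id"] == "g00"
        assert table.iloc[0]["score"] == 1.0
        assert table.iloc[0]["rank"] == 1

    def test_table_matches_per_gene_scoring(self):
        rng = np.random.default_rng(7)
        matrix = ExpressionMatrix(
            rng.normal(size=(100, 40)), [f"g{i}" for i in range(100)],
            [f"s{j}" for j in range(40)],
        )
        anchors = np.zeros(40, bool)
        anchors[rng.choice(40, size=8, replace=False)] = True
        pheno = PhenotypeTable.from_records(
            matrix.sample_ids, list(anchors), ["x"] * 40
        )
        table = rank_genes(matrix, pheno).set_index("gene_id")
        for gene in matrix.feature_ids:
            expected = brute_force_fir(
                matrix.data.loc[gene].to_numpy(), anchors, 8
            )
            row = table.loc[gene]
            assert (row["score"], row["k_best"], row["window_start"]) == expected

    def test_row_order_invariance(self):
        matrix, pheno = planted_matrix(seed=3)
        shuffled = ExpressionMatrix.from_frame(
            matrix.data.sample(frac=1.0, random_state=5)
        )
        a = rank_genes(matrix, pheno)
        b = rank_genes(shuffled, pheno)
        pd.testing.assert_frame_equal(a, b)

    def test_p_value_uses_database_anchor_proportion(self):
        matrix, pheno = planted_matrix()
        table = rank_genes(matrix, pheno).set_index("gene_id")
        top = table.loc["g00"]
        assert top["p_value"] == pytest.approx(
            binomial_tail(int(top["k_best"]), 4, 4 / 24)
        )


class TestTTestContrast:
    def test_separated_gene_outranks_null_gene(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(30, 40))
        anchors = np.zeros(40, bool)
        anchors[:10] = True
        values[0, anchors] += 5.0  # strong mean shift
        matrix = ExpressionMatrix(values, [f"g{i}" for i in range(30)],
                                  [f"s{j}" for j in range(40)])
        pheno = PhenotypeTable.from_records(
            matrix.sample_ids, list(anchors), ["x"] * 40
        )
        assert t_percentile(matrix, pheno, "g0") > t_percentile(matrix, pheno, "g1")

    def test_identical_genes_share_percentile(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=(10, 20))
        values[1] = values[0]
        matrix = ExpressionMatrix(values, [f"g{i}" for i in range(10)],
                                  [f"s{j}" for j in range(20)])
        anchors = [True] * 5 + [False] * 15
        pheno = PhenotypeTable.from_records(matrix.sample_ids, anchors, ["x"] * 20)
        assert t_percentile(matrix, pheno, "g0") == t_percentile(matrix, pheno, "g1")

    def test_bimodal_band_gene_discordance(self):
        # symmetric-bimodal non-anchors straddling a tight anchor band:
        # FIR sees a top-decile gene, the t-test a sub-median one
        cfg = LandscapeConfig(
            n_genes=400,
            group_sizes={"pluripotent": 20, "normal": 180},
            group_stemness={"pluripotent": 1.0, "normal": 0.1},
            n_planted_gradient=0, n_planted_band=1, bimodal_fraction=1.0,
            seed=42,
        )
        matrix, pheno, truth = simulate_landscape(cfg)
        gene = truth.bimodal_genes[0]
        table = rank_genes(matrix, pheno)
        assert score_percentile(table, gene) > 90.0
        assert t_percentile(matrix, pheno, gene) < 50.0


class TestSelectSignature:
    def make_table(self):
        matrix, pheno = planted_matrix()
        return rank_genes(matrix, pheno)

    def test_top_n_is_rank_prefix(self):
        table = self.make_table()
        sig = select_signature(table, top_n=3)
        assert sig.gene_ids == list(table["gene_id"].head(3))

    def test_min_score_one_selects_perfect_windows(self):
        table = self.make_table()
        sig = select_signature(table, min_score=1.0)
        assert set(sig.gene_ids) == set(
            table.loc[table["score"] == 1.0, "gene_id"]
        )

    def test_top_n_equal_to_gene_count_returns_all(self):
        table = self.make_table()
        assert len(select_signature(table, top_n=len(table))) == len(table)

    def test_infeasible_rule_errors(self):
        table = self.make_table()
        with pytest.raises(ValueError):
            select_signature(table, top_n=len(table) + 1)


class TestOneWayF:
    def test_hand_computed_two_group_case(self):
        f, df_b, df_w = one_way_f([1, 2, 4, 5], ["A", "A", "B", "B"])
        assert f == pytest.approx(18.0)
        assert (df_b, df_w) == (1, 2)

    def test_equal_means_give_zero_f(self):
        f, _, _ = one_way_f([1, 3, 1, 3], ["A", "A", "B", "B"])
        assert f == 0.0

    def test_zero_total_variance_gives_zero(self):
        f, _, _ = one_way_f([2, 2, 2, 2], ["A", "A", "B", "B"])
        assert f == 0.0

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            one_way_f([1, 2, 3], ["A", "A", "A"])

    def test_permutation_within_groups_preserves_f(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=12)
        groups = np.repeat(["A", "B", "C"], 4)
        f1, _, _ = one_way_f(values, groups)
        perm = np.concatenate([rng.permutation(4), 4 + rng.permutation(4),
                               8 + rng.permutation(4)])
        f2, _, _ = one_way_f(values[perm], groups)
        assert f1 == pytest.approx(f2)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(9)
        a, b, c = rng.normal(size=5), rng.normal(1, 1, 6), rng.normal(2, 1, 7)
        values = np.concatenate([a, b, c])
        groups = ["A"] * 5 + ["B"] * 6 + ["C"] * 7
        from scipy.stats import f_oneway

        f, _, _ = one_way_f(values, groups)
        assert f == pytest.approx(f_oneway(a, b, c).statistic)


class TestThresholdSweep:
    def landscape(self, seed=0):
        cfg = LandscapeConfig(
            n_genes=300,
            group_sizes={"pluripotent": 12, "multipotent": 12,
                         "cancer": 30, "normal": 40},
            group_stemness={"pluripotent": 1.0, "multipotent": 0.7,
                            "cancer": 0.4, "normal": 0.1},
            n_planted_gradient=50, n_planted_band=0, seed=seed,
        )
        return simulate_landscape(cfg)

    def test_argmax_beats_grid_ends(self):
        matrix, pheno, _ = self.landscape()
        grid = [3, 10, 30, 50, 100]
        res = threshold_sweep(matrix, pheno, FIRConfig(), grid,
                              ["pluripotent", "multipotent", "cancer", "normal"])
        f = res.table.set_index("n_genes")["f_stat"]
        assert f[res.best_n] >= f[3]
        assert f[res.best_n] >= f[100]

    def test_planted_structure_outscores_null_labels(self):
        matrix, pheno, _ = self.landscape(seed=1)
        grid = [10, 50]
        planted = threshold_sweep(
            matrix, pheno, FIRConfig(), grid,
            ["pluripotent", "multipotent", "cancer", "normal"],
        )
        # same landscape, but evaluate across two groups drawn from one
        # distribution: relabel normal samples arbitrarily in halves
        ph2 = pheno.data.copy()
        normals = ph2.index[ph2["group"] == "normal"]
        ph2.loc[normals[: len(normals) // 2], "group"] = "normalA"
        ph2.loc[normals[len(normals) // 2:], "group"] = "normalB"
        null = threshold_sweep(
            matrix, PhenotypeTable(ph2), FIRConfig(), grid,
            ["normalA", "normalB"],
        )
        assert null.table["f_stat"].max() < planted.table["f_stat"].max()

    def test_length_one_grid(self):
        matrix, pheno, _ = self.landscape(seed=2)
        res = threshold_sweep(matrix, pheno, FIRConfig(), [20],
                              ["pluripotent", "normal"])
        assert len(res.table) == 1
        assert res.best_n == 20
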