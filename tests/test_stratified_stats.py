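"""The statistical core: CMH, MH odds ratio + CI, pooled view, Woolf,
Simpson flagging and candidate selection."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.contingency_tables import StratifiedTable as SmTable

import stratdeg as sd
from stratdeg.count_engine import CountMatrix
from stratdeg.stratified_stats import StratifiedTable, StratumTable


def make_table(cells, gene="G"):
    """cells: list of (a, b, c, d)."""
    return StratifiedTable(gene_id=gene, strata=tuple(
        StratumTable(tissue=f"t{i}", a=a, b=b, c=c, d=d)
        for i, (a, b, c, d) in enumerate(cells)
    ))


def to_statsmodels(table):
    return SmTable([np.array([[s.a, s.b], [s.c, s.d]]) for s in table.strata])


def cmh_by_direct_formula(cells, correction=True):
    """Independent evaluation of the 2x2xk formula in plain Python."""
    num = 0.0
    expect = 0.0
    var = 0.0
    for a, b, c, d in cells:
        n = a + b + c + d
        r1, r2, c1, c2 = a + b, c + d, a + c, b + d
        if min(r1, r2, c1, c2) == 0 or n <= 1:
            continue
        num += a
        expect += r1 * c1 / n
        var += r1 * r2 * c1 * c2 / (n * n * (n - 1))
    dev = abs(num - expect)
    if correction:
        dev = max(dev - 0.5, 0.0)
    return dev * dev / var


TABLE1_CELLS = [(580, 280, 80_000, 20_000), (20, 20, 620_000, 380_000)]

# hand evaluation of the MH estimator on the demonstration table
_R = 580 * 20_000 / 100_860 + 20 * 380_000 / 1_000_040
_S = 280 * 80_000 / 100_860 + 20 * 620_000 / 1_000_040
TABLE1_MH_OR = _R / _S          # = 0.5229 to 4 figures
TABLE1_POOLED_OR = (600 * 400_000) / (300 * 700_000)  # = 8/7


class TestBuildGeneTable:
    def test_demonstration_matrix_strata(self, table1_table):
        got = [(s.a, s.b, s.c, s.d) for s in table1_table.strata]
        assert got == TABLE1_CELLS
        assert table1_table.k == 2

    def test_single_gene_matrix_has_empty_other_row(self):
        m = CountMatrix(genes=["G"], tissues=["t"],
                        counts=np.array([[[5, 9]]]), retained_tissues=["t"])
        t = sd.build_gene_table(m, "G")
        assert t.strata[0].c == 0 and t.strata[0].d == 0
        assert t.n_informative == 0

    def test_all_zero_gene_is_undefined_downstream(self, table1_matrix):
        m = CountMatrix(
            genes=["Z", "OTHER"], tissues=["t"],
            counts=np.array([[[0, 0]], [[10, 10]]]), retained_tissues=["t"],
        )
        r = sd.gene_test(sd.build_gene_table(m, "Z"))
        assert math.isnan(r.or_mh) and r.simpson_flag == "undefined"
        assert not r.selected

    def test_unknown_gene_raises(self, table1_matrix):
        with pytest.raises(sd.ValidationError):
            sd.build_gene_table(table1_matrix, "nope")

    def test_non_retained_tissues_excluded(self, table1_matrix):
        m = CountMatrix(
            genes=table1_matrix.genes, tissues=table1_matrix.tissues,
            counts=table1_matrix.counts, retained_tissues=["tissue_I"],
        )
        assert sd.build_gene_table(m, "GENE_A").k == 1


class TestCMH:
    def test_matches_direct_formula_on_demonstration_table(self, table1_table):
        stat, p = sd.cmh_test(table1_table)
        assert stat == pytest.approx(cmh_by_direct_formula(TABLE1_CELLS), abs=1e-9)
        assert p < 1e-15

    def test_correction_flag(self, table1_table):
        stat_c, _ = sd.cmh_test(table1_table, continuity_correction=True)
        stat_u, _ = sd.cmh_test(table1_table, continuity_correction=False)
        assert stat_u > stat_c
        assert stat_u == pytest.approx(
            cmh_by_direct_formula(TABLE1_CELLS, correction=False), abs=1e-9)

    def test_balanced_single_stratum_is_null(self):
        stat, p = sd.cmh_test(make_table([(10, 10, 10, 10)]))
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_duplicating_strata_scales_per_direct_formula(self):
        cells = [(30, 20, 200, 300), (12, 25, 400, 380)]
        stat, _ = sd.cmh_test(make_table(cells + cells))
        assert stat == pytest.approx(cmh_by_direct_formula(cells + cells), abs=1e-9)

    def test_degenerate_margins_contribute_nothing(self):
        cells = [(30, 20, 200, 300), (0, 0, 50, 60)]
        stat, _ = sd.cmh_test(make_table(cells))
        assert stat == pytest.approx(cmh_by_direct_formula([cells[0]]), abs=1e-9)

    def test_all_degenerate_raises(self):
        with pytest.raises(sd.UndefinedResultError):
            sd.cmh_test(make_table([(0, 0, 5, 5), (3, 4, 0, 0)]))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.permutations(list(range(4))))
    def test_stratum_order_invariance(self, order):
        cells = [(30, 20, 200, 300), (12, 25, 400, 380),
                 (5, 2, 90, 80), (40, 41, 600, 610)]
        base = make_table(cells)
        shuffled = make_table([cells[i] for i in order])
        assert sd.cmh_test(shuffled)[0] == pytest.approx(sd.cmh_test(base)[0])
        assert sd.mh_common_or(shuffled) == pytest.approx(sd.mh_common_or(base))
        assert sd.woolf_test(shuffled)[0] == pytest.approx(sd.woolf_test(base)[0])


class TestMHOddsRatio:
    def test_demonstration_table_value(self, table1_table):
        assert sd.mh_common_or(table1_table) == pytest.approx(TABLE1_MH_OR, rel=1e-12)
        assert sd.mh_common_or(table1_table) == pytest.approx(0.523, abs=5e-4)

    def test_single_stratum_equals_cross_product(self):
        t = make_table([(580, 280, 80_000, 20_000)])
        assert sd.mh_common_or(t) == pytest.approx(580 * 20_000 / (280 * 80_000),
                                                   rel=1e-12)
        assert sd.mh_common_or(t) == pytest.approx(0.5179, abs=5e-5)

    def test_zero_denominator_is_undefined(self):
        with pytest.raises(sd.UndefinedResultError):
            sd.mh_common_or(make_table([(5, 0, 0, 7)]))

    def test_matches_statsmodels_on_random_tables(self, rng):
        for _ in range(20):
            cells = rng.integers(1, 400, size=(rng.integers(1, 6), 4))
            table = make_table([tuple(map(int, c)) for c in cells])
            sm = to_statsmodels(table)
            assert sd.mh_common_or(table) == pytest.approx(
                sm.oddsratio_pooled, rel=1e-10)
            if table.k >= 1:
                stat, _ = sd.cmh_test(table, continuity_correction=True)
                assert stat == pytest.approx(
                    float(sm.test_null_odds(correction=True).statistic), rel=1e-9)


class TestConfidenceInterval:
    def test_k1_closed_form(self):
        a, b, c, d = 37, 12, 190, 160
        t = make_table([(a, b, c, d)])
        lo, hi = sd.mh_or_ci(t, level=0.95)
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        z = 1.959963984540054
        theta = a * d / (b * c)
        assert lo == pytest.approx(theta * math.exp(-z * se), rel=1e-9)
        assert hi == pytest.approx(theta * math.exp(z * se), rel=1e-9)

    def test_interval_brackets_the_estimate(self, table1_table):
        lo, hi = sd.mh_or_ci(table1_table)
        assert lo < sd.mh_common_or(table1_table) < hi

    def test_matches_statsmodels_rbg_interval(self, table1_table):
        sm_lo, sm_hi = to_statsmodels(table1_table).oddsratio_pooled_confint()
        lo, hi = sd.mh_or_ci(table1_table)
        assert lo == pytest.approx(float(sm_lo), rel=1e-9)
        assert hi == pytest.approx(float(sm_hi), rel=1e-9)

    def test_woolf_variance_alternative(self, table1_table):
        lo_r, hi_r = sd.mh_or_ci(table1_table, method="rbg")
        lo_w, hi_w = sd.mh_or_ci(table1_table, method="woolf")
        assert lo_w < hi_w and abs(math.log(lo_w / lo_r)) < 0.5

    def test_undefined_for_zero_estimate(self):
        with pytest.raises(sd.UndefinedResultError):
            sd.mh_or_ci(make_table([(0, 5, 100, 100)]))


class TestPooled:
    def test_demonstration_pooled_row_and_or(self, table1_table):
        (a, b, c, d), pooled_or, p = sd.pooled_analysis(table1_table)
        assert (b, a) == (300, 600)  # printed pooled row: normal 300, cancer 600
        assert (c, d) == (700_000, 400_000)
        assert pooled_or == pytest.approx(TABLE1_POOLED_OR, rel=1e-12)
        assert pooled_or == pytest.approx(1.143, abs=5e-4)

    def test_zero_cross_product_undefined(self):
        _, pooled_or, _ = sd.pooled_analysis(make_table([(3, 0, 5, 7)]))
        assert math.isnan(pooled_or)


class TestWoolf:
    def test_identical_strata_are_perfectly_homogeneous(self):
        stat, df, p = sd.woolf_test(make_table([(10, 10, 100, 100)] * 2))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert df == 1 and p == pytest.approx(1.0)

    def test_matches_brute_force_formula(self, table1_table):
        w, logr = [], []
        for s in table1_table.strata:
            a, b, c, d = s.a, s.b, s.c, s.d
            w.append(1 / (1 / a + 1 / b + 1 / c + 1 / d))
            logr.append(math.log(a * d / (b * c)))
        mean = sum(wi * li for wi, li in zip(w, logr)) / sum(w)
        expect = sum(wi * (li - mean) ** 2 for wi, li in zip(w, logr))
        stat, df, _ = sd.woolf_test(table1_table)
        assert stat == pytest.approx(expect, rel=1e-12)
        assert df == 1

    def test_constructed_heterogeneity_detected(self):
        # odds ratios 0.1 vs 10 at depth ~1000 per stratum
        t = make_table([(9, 91, 500, 500), (91, 9, 500, 500)])
        stat, _, p = sd.woolf_test(t)
        assert stat > 50 and p < 1e-10

    def test_zero_cell_policy_applies_within_stratum_only(self):
        t = make_table([(0, 5, 100, 100), (10, 10, 100, 100)])
        stat, df, _ = sd.woolf_test(t)
        # first stratum Haldane-adjusted, second untouched
        a, b, c, d = 0.5, 5.5, 100.5, 100.5
        w1 = 1 / (1 / a + 1 / b + 1 / c + 1 / d)
        w2 = 1 / (1 / 10 + 1 / 10 + 1 / 100 + 1 / 100)
        l1, l2 = math.log(a * d / (b * c)), 0.0
        mean = (w1 * l1 + w2 * l2) / (w1 + w2)
        expect = w1 * (l1 - mean) ** 2 + w2 * (l2 - mean) ** 2
        assert stat == pytest.approx(expect, rel=1e-12)

    def test_fewer_than_two_informative_strata_undefined(self):
        with pytest.raises(sd.UndefinedResultError):
            sd.woolf_test(make_table([(10, 10, 100, 100)]))


class TestSimpsonFlag:
    def test_reversal(self):
        assert sd.classify_simpson(1.14, 0.06, 0.52, 1e-19) == "reversed"
        # a pooled view significant upward, stratified view below 1
        assert sd.classify_simpson(6.69, 1e-16, 0.73, 0.15) == "reversed"

    def test_attenuation(self):
        assert sd.classify_simpson(1.86, 1.8e-4, 1.2, 0.25) == "attenuated"

    def test_concordant_and_undefined(self):
        assert sd.classify_simpson(2.0, 1e-5, 1.8, 1e-6) == "concordant"
        assert sd.classify_simpson(math.nan, 0.01, 1.8, 0.01) == "undefined"
        assert sd.classify_simpson(2.0, 0.01, math.nan, 0.01) == "undefined"


class TestSweepAndSelection:
    def test_demonstration_matrix_sweep(self, table1_matrix):
        res = sd.run_all_genes(table1_matrix)
        assert list(res["gene"]) == ["GENE_A", "OTHER"]
        row = res.set_index("gene").loc["GENE_A"]
        assert row["simpson_flag"] == "reversed"
        assert row["a_total"] == 600 and row["b_total"] == 300

    def test_sweep_is_deterministic(self, table1_matrix):
        r1 = sd.run_all_genes(table1_matrix, bh_adjust=True)
        r2 = sd.run_all_genes(table1_matrix, bh_adjust=True)
        pd.testing.assert_frame_equal(r1, r2)

    def test_tissue_order_does_not_change_results(self, table1_matrix):
        flipped = CountMatrix(
            genes=table1_matrix.genes,
            tissues=table1_matrix.tissues[::-1],
            counts=table1_matrix.counts[:, ::-1, :],
            retained_tissues=table1_matrix.tissues[::-1],
        )
        pd.testing.assert_frame_equal(
            sd.run_all_genes(table1_matrix), sd.run_all_genes(flipped)
        )

    def test_two_genes_minimum(self):
        m = CountMatrix(genes=["G"], tissues=["t"],
                        counts=np.array([[[5, 5]]]), retained_tissues=["t"])
        with pytest.raises(sd.ValidationError):
            sd.run_all_genes(m)

    def test_selection_rule(self):
        res = pd.DataFrame({
            "gene": ["pass", "wide_ci", "weak_p", "no_ci"],
            "cmh_p": [0.01, 0.01, 0.2, 0.001],
            "ci_lower": [1.70, 1.59, 1.8, math.nan],
        })
        picked = sd.select_candidates(res)
        assert list(picked["gene"]) == ["pass"]

    def test_results_tsv_scientific_notation(self, tmp_path, table1_matrix):
        res = sd.run_all_genes(table1_matrix)
        path = tmp_path / "results.tsv"
        sd.stratified_stats.write_results_tsv(res, path)
        text = path.read_text()
        assert "e-" in text.lower()  # tiny p printed in scientific notation
        assert text.splitlines()[0].split("\t")[:3] == ["gene", "a_total", "b_total"]
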