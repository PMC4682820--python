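import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from renalage import (
    DETable,
    ExpressionMatrix,
    collapse_probes,
    detection_filter,
    differential_expression,
    fit_age_model,
    gfr_attenuation,
    simulate_expression,
)


def expr_with_detection(det_rows):
    genes = [f"G{i}" for i in range(len(det_rows))]
    samples = ["S1", "S2", "S3"]
    values = pd.DataFrame(8.0, index=genes, columns=samples)
    det = pd.DataFrame(det_rows, index=genes, columns=samples)
    return ExpressionMatrix(values=values, age=pd.Series([30.0, 50, 70], index=samples),
                            detection_p=det)


class TestDetectionFilter:
    def test_detected_in_one_sample_retained(self):
        expr = expr_with_detection([[0.001, 0.5, 0.5], [0.5, 0.5, 0.5]])
        out = detection_filter(expr)
        assert out.genes == ["G0"]

    def test_alpha_one_keeps_everything(self):
        expr = expr_with_detection([[0.9, 0.9, 0.9], [0.5, 0.5, 0.5]])
        assert len(detection_filter(expr, alpha=1.0000001).genes) == 2

    def test_missing_detection_matrix_errors(self, small_expr):
        with pytest.raises(ValueError, match="detection"):
            detection_filter(small_expr)


class TestDifferentialExpression:
    def test_pooled_t_closed_form(self):
        # treated (3,5), control (2,4): pooled variance 2, se = sqrt(2),
        # t = 1/sqrt(2) at df 2; cross-checked against scipy's equal-variance
        # t-test as an independent oracle
        treated = pd.DataFrame([[3.0, 5.0]], index=["G"], columns=["t1", "t2"])
        control = pd.DataFrame([[2.0, 4.0]], index=["G"], columns=["c1", "c2"])
        de = differential_expression(treated, control)
        row = de.table.iloc[0]
        assert row["log2fc"] == pytest.approx(1.0)
        assert row["p"] == pytest.approx(2 * stats.t.sf(1 / math.sqrt(2), 2), abs=1e-12)
        oracle = stats.ttest_ind([3.0, 5.0], [2.0, 4.0], equal_var=True)
        assert row["p"] == pytest.approx(oracle.pvalue, abs=1e-12)

    def test_identical_groups_null(self):
        x = pd.DataFrame([[1.0, 2.0, 3.0]], index=["G"], columns=list("abc"))
        de = differential_expression(x, x.rename(columns=str.upper))
        assert de.table.iloc[0]["log2fc"] == 0
        assert de.table.iloc[0]["p"] == 1.0

    def test_zero_variance_shift_flagged(self):
        treated = pd.DataFrame([[2.0, 2.0]], index=["G"], columns=["a", "b"])
        control = pd.DataFrame([[1.0, 1.0]], index=["G"], columns=["c", "d"])
        with pytest.warns(UserWarning, match="zero variance"):
            de = differential_expression(treated, control)
        assert de.table.iloc[0]["log2fc"] == pytest.approx(1.0)
        assert 0 < de.table.iloc[0]["p"] < 1e-300

    def test_null_pvalues_uniform(self):
        """Under the null the t-test p-values are U(0,1) (KS check)."""
        rng = np.random.default_rng(42)
        n = 10_000
        treated = pd.DataFrame(rng.normal(0, 1, (n, 5)), index=[f"g{i}" for i in range(n)])
        control = pd.DataFrame(rng.normal(0, 1, (n, 5)), index=[f"g{i}" for i in range(n)])
        de = differential_expression(treated, control)
        ks = stats.kstest(de.table["p"], "uniform").statistic
        assert ks < 0.05


class TestCollapseProbes:
    def _de(self, rows):
        return DETable(pd.DataFrame(rows, columns=["gene_id", "log2fc", "p"]))

    def test_smallest_p_wins(self):
        de = self._de([("p1", 0.5, 0.01), ("p2", 0.4, 0.005)])
        out = collapse_probes(de, {"p1": "G", "p2": "G"})
        assert out.table.iloc[0]["log2fc"] == 0.4

    def test_tie_on_p_goes_to_larger_fold_change(self):
        de = self._de([("p1", 0.5, 0.01), ("p2", -1.2, 0.01)])
        out = collapse_probes(de, {"p1": "G", "p2": "G"})
        assert out.table.iloc[0]["log2fc"] == -1.2

    def test_full_tie_lexicographic(self):
        de = self._de([("pB", 1.0, 0.01), ("pA", 1.0, 0.01)])
        out = collapse_probes(de, {"pA": "G", "pB": "G"})
        # winner is the lexicographically smallest probe id
        assert out.table.iloc[0]["log2fc"] == 1.0
        assert len(out.table) == 1

    def test_one_row_per_mapped_gene_and_unmapped_dropped(self):
        de = self._de([("p1", 0.5, 0.01), ("p2", 0.4, 0.005), ("p3", 1.0, 0.2)])
        with pytest.warns(UserWarning, match="unmapped"):
            out = collapse_probes(de, {"p1": "G1", "p2": "G1"})
        assert sorted(out.table["gene_id"]) == ["G1"]


class TestAgeModel:
    def test_three_point_closed_form(self):
        samples = ["a", "b", "c"]
        values = pd.DataFrame([[1.0, 1.5, 2.0]], index=["G"], columns=samples)
        expr = ExpressionMatrix(values=values, age=pd.Series([40.0, 60, 80], index=samples))
        res = fit_age_model(expr)[0]
        assert res.beta_age == pytest.approx(0.025, abs=1e-12)

    def test_constant_gene_no_signal(self):
        samples = ["a", "b", "c", "d"]
        values = pd.DataFrame([[5.0] * 4], index=["G"], columns=samples)
        expr = ExpressionMatrix(values=values, age=pd.Series([30.0, 40, 50, 60], index=samples))
        res = fit_age_model(expr)[0]
        assert res.beta_age == pytest.approx(0.0, abs=1e-10)
        assert res.p_age == 1.0

    def test_collinear_gfr_rejected(self):
        samples = ["a", "b", "c", "d"]
        ages = pd.Series([30.0, 40, 50, 60], index=samples)
        values = pd.DataFrame(np.random.default_rng(0).normal(8, 1, (2, 4)),
                              index=["G1", "G2"], columns=samples)
        expr = ExpressionMatrix(values=values, age=ages, gfr=2 * ages + 1)
        with pytest.raises(ValueError, match="condition number"):
            fit_age_model(expr, include_gfr=True)

    def test_pure_gfr_gene_slope_vanishes_with_covariate(self):
        genes = [f"G{i:05d}" for i in range(20)]
        expr, truth = simulate_expression(
            genes, n_samples=30, frac_age_genes=1.0, frac_gfr_mediated=1.0,
            noise_sd=0.0, seed=3,
        )
        with_gfr = fit_age_model(expr, include_gfr=True)
        without = fit_age_model(expr, include_gfr=False)
        for rw, ro in zip(with_gfr, without):
            assert abs(rw.beta_age) < 1e-10
            assert abs(ro.beta_age) > 1e-4  # marginal slope through GFR


class TestGfrAttenuation:
    def test_pure_gfr_genes_attenuate_fully(self):
        genes = [f"G{i:05d}" for i in range(30)]
        expr, _ = simulate_expression(
            genes, n_samples=30, frac_age_genes=1.0, frac_gfr_mediated=1.0,
            noise_sd=0.0, seed=5,
        )
        frac, table = gfr_attenuation(
            fit_age_model(expr, include_gfr=True), fit_age_model(expr, include_gfr=False)
        )
        assert frac == 1.0
        assert len(table) == 30

    def test_independent_gfr_attenuates_at_chance(self):
        """With GFR unrelated to age and expression, |beta_age| shrinks ~half the time.

        The chance level is approached from below as n grows: the extra
        covariate inflates the slope's sampling variance by 1/(1 - r^2) for
        the realized age-GFR sample correlation r, an O(1/n) effect.
        """
        rng = np.random.default_rng(11)
        n_genes, n_samples = 4000, 1000
        samples = [f"S{i}" for i in range(n_samples)]
        ages = pd.Series(rng.uniform(27, 92, n_samples), index=samples)
        gfr = pd.Series(rng.normal(80, 15, n_samples), index=samples)
        values = pd.DataFrame(rng.normal(8, 1, (n_genes, n_samples)),
                              index=[f"g{i}" for i in range(n_genes)], columns=samples)
        expr = ExpressionMatrix(values=values, age=ages, gfr=gfr)
        frac, _ = gfr_attenuation(
            fit_age_model(expr, include_gfr=True), fit_age_model(expr, include_gfr=False)
        )
        se = np.sqrt(0.25 / n_genes)
        assert abs(frac - 0.5) < 3 * se + 0.02

    def test_gene_set_mismatch_rejected(self, small_expr):
        res = fit_age_model(small_expr)
        with pytest.raises(ValueError):
            gfr_attenuation(res, res[:-1])
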