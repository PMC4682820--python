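import numpy as np
import pandas as pd
import pytest

from renalage import (
    assign_peaks_to_genes,
    compute_complexity,
    fit_age_model,
    simulate_assoc,
    simulate_chipseq,
    simulate_cytokine_response,
    simulate_expression,
    simulate_genome,
    simulate_latent_activity,
)


class TestGenome:
    def test_positions_within_chromosome(self):
        tss = simulate_genome(10, 1, 1_000_000, seed=1)
        assert len(tss) == 10
        assert all(0 <= r.tss < 1_000_000 for r in tss)

    def test_deterministic_under_seed(self):
        a = simulate_genome(50, 2, 1_000_000, seed=3)
        b = simulate_genome(50, 2, 1_000_000, seed=3)
        assert a == b
        c = simulate_genome(50, 2, 1_000_000, seed=4)
        assert a != c

    def test_infeasible_density_rejected(self):
        with pytest.raises(ValueError, match="density"):
            simulate_genome(200, 1, 200 * 8000 - 1, seed=0)

    def test_promoter_windows_disjoint(self):
        """Greedy packing check: no two genes' strand-aware windows overlap."""
        tss = simulate_genome(300, 1, 300 * 8000 + 1000, seed=2)
        windows = []
        for r in tss:
            lo = r.tss - 5000 if r.strand == "+" else r.tss - 2000
            hi = r.tss + 2000 if r.strand == "+" else r.tss + 5000
            windows.append((lo, hi))
        windows.sort()
        for (a1, b1), (a2, b2) in zip(windows, windows[1:]):
            assert b1 <= a2


class TestChipseq:
    def test_no_hot_regions_gives_complexity_one(self):
        tss = simulate_genome(200, 1, 5_000_000, seed=1)
        peaksets, _ = simulate_chipseq(tss, n_tfs=1, peaks_per_experiment=50,
                                       hot_fraction=0.0, seed=1)
        cx = compute_complexity(peaksets)
        assert set(cx.values()) == {1}

    def test_hot_regions_reach_full_complexity(self):
        tss = simulate_genome(200, 1, 5_000_000, seed=1)
        peaksets, truth = simulate_chipseq(tss, n_tfs=8, peaks_per_experiment=50,
                                           hot_fraction=0.3, seed=2)
        cx = compute_complexity(peaksets)
        assert truth.hot_regions
        assert max(cx.values()) == 8  # every TF anchors each HOT region

    def test_planted_tf_enriched_at_age_genes(self):
        """Planted binding hits the age set far above the null fraction."""
        tss = simulate_genome(1000, 1, 20_000_000, seed=5)
        genes = [r.gene_id for r in tss]
        age = sorted(genes[:100])
        peaksets, _ = simulate_chipseq(
            tss, n_tfs=2, peaks_per_experiment=500,
            planted={"TF001": (10.0, age)}, hot_fraction=0.0, seed=5,
        )
        frac = {}
        for ps in peaksets:
            tm = assign_peaks_to_genes(ps, tss)
            frac[ps.tf] = len(tm.targets & set(age)) / max(len(tm.targets), 1)
        # rho=10 on 10% of genes: the planted TF's unique-target fraction in
        # the age set well exceeds the null TF's (~0.3 vs ~0.1 after
        # accounting for repeat hits on the same gene)
        assert frac["TF001"] > 2 * frac["TF002"]
        assert frac["TF001"] > 0.2

    def test_unknown_planted_tf_rejected(self):
        tss = simulate_genome(10, 1, 1_000_000, seed=1)
        with pytest.raises(ValueError, match="planted"):
            simulate_chipseq(tss, n_tfs=2, planted={"TF099": (2.0, ["G00001"])})

    def test_byte_identical_under_seed(self):
        tss = simulate_genome(100, 1, 2_000_000, seed=1)
        a, _ = simulate_chipseq(tss, n_tfs=3, peaks_per_experiment=20, seed=7)
        b, _ = simulate_chipseq(tss, n_tfs=3, peaks_per_experiment=20, seed=7)
        assert [p for ps in a for p in ps] == [p for ps in b for p in ps]


class TestExpression:
    def test_no_age_genes_slopes_center_on_zero(self):
        genes = [f"G{i:05d}" for i in range(500)]
        expr, _ = simulate_expression(genes, n_samples=40, frac_age_genes=0.0, seed=1)
        res = fit_age_model(expr)
        betas = np.array([r.beta_age for r in res])
        ses = np.array([r.se_age for r in res])
        assert abs(betas.mean()) < 3 * ses.mean() / np.sqrt(len(betas))

    def test_pure_gfr_gene_closed_form(self):
        genes = [f"G{i:05d}" for i in range(10)]
        expr, truth = simulate_expression(
            genes, n_samples=20, frac_age_genes=1.0, frac_gfr_mediated=1.0,
            noise_sd=0.0, seed=2,
        )
        with_gfr = fit_age_model(expr, include_gfr=True)
        without = fit_age_model(expr, include_gfr=False)
        assert all(abs(r.beta_age) < 1e-10 for r in with_gfr)
        assert all(abs(r.beta_age) > 1e-5 for r in without)

    def test_identical_matrix_under_seed(self):
        genes = [f"G{i}" for i in range(50)]
        a, _ = simulate_expression(genes, n_samples=10, seed=9)
        b, _ = simulate_expression(genes, n_samples=10, seed=9)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_truth_partitions_age_genes(self):
        genes = [f"G{i}" for i in range(200)]
        _, truth = simulate_expression(genes, n_samples=10, frac_age_genes=0.2,
                                       frac_gfr_mediated=0.5, seed=3)
        direct = set(truth.extra["age_direct_gene_ids"])
        mediated = set(truth.extra["gfr_mediated_gene_ids"])
        assert direct | mediated == set(truth.age_gene_ids)
        assert not direct & mediated
        assert len(truth.age_gene_ids) == 40


class TestCytokine:
    def test_full_concordance_when_c_is_one(self):
        from renalage import concordance_test
        de, slopes, _ = simulate_cytokine_response(
            [f"T{i}" for i in range(30)], concordance_c=1.0, p_induced=1.0, seed=1)
        res = concordance_test(de, slopes)
        assert res.concordance_pct == 100.0

    def test_target_pvalues_below_de_threshold(self):
        de, _, _ = simulate_cytokine_response([f"T{i}" for i in range(50)], seed=2)
        assert (de.table["p"] < 0.05).all()

    def test_identical_under_seed(self):
        a, sa, _ = simulate_cytokine_response([f"T{i}" for i in range(20)], seed=5)
        b, sb, _ = simulate_cytokine_response([f"T{i}" for i in range(20)], seed=5)
        pd.testing.assert_frame_equal(a.table, b.table)
        pd.testing.assert_series_equal(sa, sb)


class TestAssoc:
    def test_null_or_gives_p_one(self):
        recs, _ = simulate_assoc(["G"], 1, true_or=1.0, maf=0.3,
                                 n_cases=1000, n_controls=1000)
        assert recs[0].p_by_phenotype["CKD"] == 1.0

    def test_incompatible_or_rejected(self):
        # protective ORs are not representable with the minor allele as risk
        with pytest.raises(ValueError, match="incompatible"):
            simulate_assoc(["G"], 1, true_or=0.5, maf=0.3,
                           n_cases=100, n_controls=100)

    def test_records_deterministic(self):
        a, _ = simulate_assoc(["G1", "G2"], 2, seed=1)
        b, _ = simulate_assoc(["G1", "G2"], 2, seed=1)
        assert a == b


class TestLatent:
    def test_expected_pairwise_correlation(self):
        scores, truth = simulate_latent_activity(["a", "b"], n_samples=5000,
                                                 loading=0.8, seed=1)
        r = np.corrcoef(scores["a"], scores["b"])[0, 1]
        assert r == pytest.approx(truth.extra["expected_r"], abs=0.05)

    def test_independent_labels_uncorrelated(self):
        scores, _ = simulate_latent_activity(["a", "b"], n_samples=5000, loading=0.9,
                                             seed=2, independent_labels=["m"])
        assert abs(np.corrcoef(scores["a"], scores["m"])[0, 1]) < 0.05
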