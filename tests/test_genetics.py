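import numpy as np
import pytest
from scipy import stats

from renalage import (
    SNPAssocRecord,
    annotate_linked_snps,
    bonferroni_threshold,
    estimate_allelic_or,
    select_lead_snps,
    simulate_assoc,
)


class TestBonferroni:
    def test_study_threshold_renders_as_printed(self):
        thr, rendered = bonferroni_threshold(217, 2, 0.05)
        assert thr == pytest.approx(0.05 / 434)
        assert rendered == "1.1 x 10^-4"

    @pytest.mark.parametrize("n_snps,n_pheno,alpha,expect", [
        (1, 1, 0.05, 0.05),
        (10, 2, 0.05, 2.5e-3),
    ])
    def test_direct_division(self, n_snps, n_pheno, alpha, expect):
        thr, _ = bonferroni_threshold(n_snps, n_pheno, alpha)
        assert thr == pytest.approx(expect)
        assert thr * n_snps * n_pheno == pytest.approx(alpha)

    def test_counts_validated(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0, 2)


def record(snp_id, gene, p_egfr, p_ckd=0.5, maf=0.3):
    return SNPAssocRecord(
        snp_id=snp_id, gene=gene,
        p_by_phenotype={"eGFR": p_egfr, "CKD": p_ckd},
        major_allele="C", minor_allele="T", maf=maf,
        n_cases=6000, n_controls=60000,
    )


class TestLeadSNPs:
    def test_minimum_p_wins_and_flagging(self):
        recs = [record("rs_a", "NFKB1", 0.01), record("rs_b", "NFKB1", 4.4e-5)]
        leads = select_lead_snps(recs, "eGFR", threshold=1.15e-4)
        lead, sig = leads["NFKB1"]
        assert lead.snp_id == "rs_b" and sig

    def test_lead_reported_even_when_not_significant(self):
        recs = [record("rs_a", "RELA", 0.02), record("rs_b", "RELA", 0.01)]
        lead, sig = select_lead_snps(recs, "eGFR", threshold=1e-4)["RELA"]
        assert lead.snp_id == "rs_b" and not sig

    def test_tie_broken_lexicographically(self):
        recs = [record("rs_z", "STAT1", 0.01), record("rs_a", "STAT1", 0.01)]
        lead, _ = select_lead_snps(recs, "eGFR", threshold=1e-4)["STAT1"]
        assert lead.snp_id == "rs_a"


class TestORReconstruction:
    def test_p_one_gives_null_or(self):
        res = estimate_allelic_or(1.0, maf=0.3, n_cases=1000, n_controls=10000)
        assert res.or_estimate == pytest.approx(1.0)
        assert res.target_chi2 == 0.0

    def test_forward_table_round_trip(self):
        # build the exact table with f_case 0.22, f_ctl 0.20 and recover its OR
        n_cases, n_controls = 5000, 50000
        f1, f2 = 0.22, 0.20
        n1, n2 = 2 * n_cases, 2 * n_controls
        a, b, c, d = n1 * f1, n1 * (1 - f1), n2 * f2, n2 * (1 - f2)
        chi2 = (a * d - b * c) ** 2 * (n1 + n2) / (n1 * n2 * (a + c) * (b + d))
        p = float(stats.chi2.sf(chi2, 1))
        maf = (a + c) / (n1 + n2)
        res = estimate_allelic_or(p, maf=maf, n_cases=n_cases, n_controls=n_controls)
        want = (0.22 / 0.78) / (0.20 / 0.80)
        assert res.or_estimate == pytest.approx(want, abs=1e-6)
        assert res.f_case == pytest.approx(0.22, abs=1e-8)
        assert res.f_control == pytest.approx(0.20, abs=1e-8)

    def test_reconstruction_invariants(self):
        res = estimate_allelic_or(1e-4, maf=0.37, n_cases=6000, n_controls=60000)
        # implied table reproduces the target chi-square
        n1, n2 = 2 * 6000, 2 * 60000
        f1, f2 = res.f_case, res.f_control
        a, b, c, d = n1 * f1, n1 * (1 - f1), n2 * f2, n2 * (1 - f2)
        chi2 = (a * d - b * c) ** 2 * (n1 + n2) / (n1 * n2 * (a + c) * (b + d))
        assert chi2 == pytest.approx(res.target_chi2, abs=1e-8)
        # pooled frequency equals the input MAF
        pooled = (a + c) / (n1 + n2)
        assert pooled == pytest.approx(0.37, abs=1e-10)

    def test_monotone_in_p(self):
        ors = [
            estimate_allelic_or(p, maf=0.3, n_cases=5000, n_controls=50000).or_estimate
            for p in (0.5, 0.1, 1e-3, 1e-6, 1e-10)
        ]
        assert all(a < b for a, b in zip(ors, ors[1:]))

    def test_protective_direction_inverts(self):
        risk = estimate_allelic_or(1e-4, maf=0.3, n_cases=5000, n_controls=50000)
        prot = estimate_allelic_or(1e-4, maf=0.3, n_cases=5000, n_controls=50000,
                                   direction="protective")
        assert prot.or_estimate == pytest.approx(1 / risk.or_estimate, rel=1e-10)

    def test_carrier_mode_differs_but_agrees_in_sign(self):
        allelic = estimate_allelic_or(1e-4, maf=0.3, n_cases=5000, n_controls=50000)
        carrier = estimate_allelic_or(1e-4, maf=0.3, n_cases=5000, n_controls=50000,
                                      mode="carrier")
        assert carrier.mode == "carrier"
        assert carrier.or_estimate > 1 and allelic.or_estimate > 1
        assert carrier.or_estimate != pytest.approx(allelic.or_estimate, rel=1e-3)

    def test_impossible_p_for_maf_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            estimate_allelic_or(None, maf=0.01, n_cases=20, n_controls=20,
                                neg_log10_p=300.0)

    def test_simulator_round_trip(self):
        recs, truth = simulate_assoc(["NFKB1"], 1, true_or=1.2, maf=0.3,
                                     n_cases=5000, n_controls=50000)
        r = recs[0]
        est = estimate_allelic_or(None, r.maf, r.n_cases, r.n_controls,
                                  neg_log10_p=r.neg_log10_p_by_phenotype["CKD"])
        assert est.or_estimate == pytest.approx(1.2, abs=1e-6)

    def test_null_or_emits_p_one(self):
        recs, _ = simulate_assoc(["X"], 1, true_or=1.0, maf=0.2,
                                 n_cases=1000, n_controls=1000)
        assert recs[0].p_by_phenotype["CKD"] == 1.0


class TestLinkedSNPAnnotation:
    LD = [("rs_lead", 1.0), ("rs_hi", 0.9), ("rs_edge", 0.8), ("rs_lo", 0.3)]
    POS = {"rs_lead": ("chr4", 1000), "rs_hi": ("chr4", 2000),
           "rs_edge": ("chr4", 3000), "rs_lo": ("chr4", 4000)}
    ANN = [("DNase", "chr4", 1500, 2500), ("H3K4me1", "chr4", 1900, 2000)]

    def test_strict_r2_threshold(self):
        out = annotate_linked_snps("rs_lead", self.LD, self.POS, self.ANN)
        ids = [o.snp_id for o in out]
        assert "rs_hi" in ids and "rs_edge" not in ids and "rs_lo" not in ids

    def test_point_in_interval_half_open(self):
        out = annotate_linked_snps("rs_lead", self.LD, self.POS, self.ANN)
        by_id = {o.snp_id: o for o in out}
        # rs_hi at 2000: inside DNase [1500,2500) but NOT H3K4me1 [1900,2000)
        types = {t for t, _ in by_id["rs_hi"].overlapping_annotations}
        assert types == {"DNase"}

    def test_matches_bruteforce_all_pairs(self):
        rng = np.random.default_rng(0)
        ld = [(f"rs{i}", float(rng.uniform(0, 1))) for i in range(30)] + [("lead", 1.0)]
        pos = {s: ("chr1", int(rng.integers(0, 5000))) for s, _ in ld}
        ann = [("T", "chr1", int(a), int(a) + 200)
               for a in rng.integers(0, 5000, size=10)]
        out = annotate_linked_snps("lead", ld, pos, ann, r2_min=0.5)
        expect = {}
        for s, r2 in ld:
            if r2 > 0.5:
                c, x = pos[s]
                expect[s] = sorted((t, (ac, st, en)) for t, ac, st, en in ann
                                   if ac == c and st <= x < en)
        assert {o.snp_id: sorted(o.overlapping_annotations) for o in out} == expect

    def test_missing_lead_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            annotate_linked_snps("rs_missing", self.LD, self.POS, self.ANN)
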