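"""Candidate-gene SNP analysis.

Bonferroni threshold over SNP × phenotype tests, lead-SNP selection within
each candidate gene, reconstruction of the allelic odds ratio from a summary
p-value (chi-square matching: find the case/control minor-allele frequency
split that keeps the pooled frequency at the reported MAF and reproduces the
association chi-square statistic), and functional-annotation overlap for
SNPs in strong LD (R² > 0.8) with a lead SNP.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .types import SNPAssocRecord

__all__ = [
    "ORReconstruction",
    "LinkedSNPAnnotation",
    "bonferroni_threshold",
    "select_lead_snps",
    "estimate_allelic_or",
    "annotate_linked_snps",
]

_LN10 = math.log(10.0)


@dataclass
class ORReconstruction:
    snp_id: str
    target_chi2: float
    or_estimate: float
    f_case: float
    f_control: float
    mode: str  # "allelic" or "carrier"


@dataclass
class LinkedSNPAnnotation:
    snp_id: str
    r2_with_lead: float
    overlapping_annotations: list[tuple[str, tuple[str, int, int]]] = field(default_factory=list)


def bonferroni_threshold(
    n_snps: int, n_phenotypes: int = 1, alpha: float = 0.05
) -> tuple[float, str]:
    """Per-test threshold alpha/(n_snps·n_phenotypes) and its 2-sig-fig form.

    The rendering truncates the mantissa to one decimal place (0.05/434 =
    1.152…e-4 → "1.1 x 10^-4"), matching the convention of reporting the
    largest 2-significant-figure threshold not exceeding the exact one.
    """
    if n_snps < 1 or n_phenotypes < 1:
        raise ValueError("counts must be >= 1")
    thr = alpha / (n_snps * n_phenotypes)
    exponent = math.floor(math.log10(thr))
    mantissa = thr / 10**exponent
    mantissa = math.floor(mantissa * 10 + 1e-9) / 10  # truncate, guarding float fuzz
    rendered = f"{mantissa:g} x 10^{exponent}"
    return thr, rendered


def select_lead_snps(
    records: list[SNPAssocRecord], phenotype: str, threshold: float
) -> dict[str, tuple[SNPAssocRecord, bool]]:
    """Per-gene lead SNP (minimum p for the phenotype; ties lexicographic).

    Returns gene → (lead record, significant flag where p < threshold).
    """
    leads: dict[str, tuple[SNPAssocRecord, bool]] = {}
    by_gene: dict[str, list[SNPAssocRecord]] = {}
    for rec in records:
        if phenotype not in rec.p_by_phenotype:
            continue
        by_gene.setdefault(rec.gene, []).append(rec)
    for gene, recs in by_gene.items():
        lead = min(recs, key=lambda r: (r.p_by_phenotype[phenotype], r.snp_id))
        leads[gene] = (lead, lead.p_by_phenotype[phenotype] < threshold)
    return leads


def _chi2_target_from_p(p: float | None, neg_log10_p: float | None) -> float:
    """1-df chi-square statistic matching a (possibly log-scale) p-value.

    Uses the chi-square(1) ↔ normal identity p = 2·Φ(−√x) so that p-values
    far below double-precision underflow can be supplied as −log10(p).
    """
    if neg_log10_p is not None:
        log_p = -neg_log10_p * _LN10
        if log_p > 0:
            raise ValueError("neg_log10_p must be >= 0")
        if log_p == 0:
            return 0.0
        z = special.ndtri_exp(log_p - math.log(2.0))  # Φ⁻¹(p/2) in log space
        return float(z * z)
    if p is None:
        raise ValueError("supply p or neg_log10_p")
    if not (0 < p <= 1):
        raise ValueError(f"p must be in (0,1], got {p}")
    if p == 1:
        return 0.0
    z = special.ndtri(p / 2.0)
    return float(z * z)


def _log_p_from_chi2(chi2: float) -> float:
    """Natural-log p for a 1-df chi-square statistic (stable for huge chi2)."""
    if chi2 <= 0:
        return 0.0
    return float(math.log(2.0) + special.log_ndtr(-math.sqrt(chi2)))


def _pearson_chi2(f1: float, f2: float, n1: float, n2: float) -> float:
    """Pearson chi-square (1 df, no continuity correction) of the 2×2 table
    with group frequencies f1, f2 and group totals n1, n2 (expected counts)."""
    a, b = n1 * f1, n1 * (1 - f1)
    c, d = n2 * f2, n2 * (1 - f2)
    n = n1 + n2
    col1, col2 = a + c, b + d
    if col1 == 0 or col2 == 0:
        return 0.0
    num = (a * d - b * c) ** 2 * n
    return num / (n1 * n2 * col1 * col2)


def _carrier_freq(f: float) -> float:
    """Minor-allele carrier frequency under Hardy–Weinberg: 2f(1−f) + f²."""
    return 2 * f * (1 - f) + f * f


def estimate_allelic_or(
    p: float | None,
    maf: float,
    n_cases: int,
    n_controls: int,
    direction: str = "risk",
    mode: str = "allelic",
    snp_id: str = "",
    neg_log10_p: float | None = None,
    tol: float = 1e-10,
) -> ORReconstruction:
    """Reconstruct the allelic odds ratio implied by a summary p-value.

    Solves for the frequency split δ ≥ 0 with f_case = maf + δ·w_ctl and
    f_ctl = maf − δ·w_case (w = each group's share of total allele counts,
    so the pooled frequency stays at the reported MAF) such that the Pearson
    chi-square of the implied expected-count 2×2 table matches
    qchisq(1−p, 1). OR = odds(f_case)/odds(f_ctl), inverted when
    ``direction`` is "protective". ``mode`` "carrier" tests minor-allele
    carrier counts (Hardy–Weinberg) on person totals instead of allele
    counts.
    """
    if not (0 < maf <= 0.5):
        raise ValueError("maf must be in (0, 0.5]")
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("cohort sizes must be > 0")
    if mode not in {"allelic", "carrier"}:
        raise ValueError("mode must be 'allelic' or 'carrier'")
    if direction not in {"risk", "protective"}:
        raise ValueError("direction must be 'risk' or 'protective'")
    target = _chi2_target_from_p(p, neg_log10_p)
    if mode == "allelic":
        n1, n2 = 2.0 * n_cases, 2.0 * n_controls
    else:
        n1, n2 = float(n_cases), float(n_controls)
    w_case = 2.0 * n_cases / (2.0 * n_cases + 2.0 * n_controls)
    w_ctl = 1.0 - w_case

    def freqs(delta: float) -> tuple[float, float]:
        return maf + delta * w_ctl, maf - delta * w_case

    def chi2_of(delta: float) -> float:
        f1, f2 = freqs(delta)
        if mode == "carrier":
            f1, f2 = _carrier_freq(f1), _carrier_freq(f2)
        return _pearson_chi2(f1, f2, n1, n2)

    if target == 0.0:
        delta = 0.0
    else:
        # bracket: delta may push f_case toward 1 or f_ctl toward 0
        delta_max = min((1.0 - maf) / w_ctl, maf / w_case)
        hi = delta_max * (1 - 1e-12)
        if chi2_of(hi) < target:
            raise ValueError(
                f"{snp_id or 'SNP'}: p too small for the given MAF and cohort sizes "
                "(required frequency split leaves (0,1))"
            )
        delta = float(optimize.brentq(lambda d: chi2_of(d) - target, 0.0, hi, xtol=tol, maxiter=200))
    f_case, f_ctl = freqs(delta)
    odds = lambda f: f / (1 - f)
    if f_ctl <= 0 or f_case >= 1:
        raise ValueError(f"{snp_id or 'SNP'}: implied frequency on the boundary")
    or_est = odds(f_case) / odds(f_ctl)
    if direction == "protective":
        or_est = 1.0 / or_est
        f_case, f_ctl = f_ctl, f_case
    return ORReconstruction(
        snp_id=snp_id,
        target_chi2=target,
        or_estimate=or_est,
        f_case=f_case,
        f_control=f_ctl,
        mode=mode,
    )


def annotate_linked_snps(
    lead_snp: str,
    ld_table: list[tuple[str, float]],
    snp_positions: dict[str, tuple[str, int]],
    annotations: list[tuple[str, str, int, int]],
    r2_min: float = 0.8,
) -> list[LinkedSNPAnnotation]:
    """Functional annotations overlapping SNPs in strong LD with the lead.

    ``ld_table`` holds (snp_id, R² with the lead); SNPs with R² strictly
    greater than ``r2_min`` are reported (the lead itself, if listed with
    R² 1, included). ``annotations`` are typed intervals (type, chrom,
    start, end), half-open; a SNP at the end coordinate is outside.
    """
    linked = {snp for snp, r2 in ld_table}
    if lead_snp not in linked:
        raise ValueError(f"lead SNP {lead_snp} absent from LD table")
    out: list[LinkedSNPAnnotation] = []
    for snp, r2 in sorted(ld_table):
        if not (0 <= r2 <= 1):
            raise ValueError(f"{snp}: R² must lie in [0,1], got {r2}")
        if r2 <= r2_min:
            continue
        if snp not in snp_positions:
            raise ValueError(f"no position for linked SNP {snp}")
        chrom, pos = snp_positions[snp]
        hits = [
            (ann_type, (ann_chrom, start, end))
            for ann_type, ann_chrom, start, end in annotations
            if ann_chrom == chrom and start <= pos < end
        ]
        out.append(LinkedSNPAnnotation(snp_id=snp, r2_with_lead=r2, overlapping_annotations=hits))
    return out
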