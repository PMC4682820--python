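"""Synthetic inputs with the statistical structure the pipeline assumes.

Defaults mirror the study's shape: a compendium of 161 TFs (up to 961
experiments) with HOT regions and one or more planted regulators enriched
for binding an age-gene set; 73 kidney samples aged 27–92 whose expression
is driven by age directly or through GFR (GFR ≈ 130 − 0.9·age + noise, the
textbook adult decline); cytokine-response tables with a tunable
direction-concordance; and SNP association tables built from exact
expected-count 2×2 allele tables. Everything is deterministic under a fixed
seed: one global seed fans out to per-generator substreams keyed by stable
labels, so adding a generator does not shift the others' streams.

Ground truth is returned in a :class:`SimTruth` sidecar consumed only by
tests and recovery analyses, never by pipeline code.
"""
from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .types import DETable, ExpressionMatrix, Peak, PeakSet, SNPAssocRecord, TSSRecord

__all__ = [
    "SimTruth",
    "simulate_genome",
    "simulate_chipseq",
    "simulate_expression",
    "simulate_cytokine_response",
    "simulate_assoc",
    "simulate_latent_activity",
]

# promoter window −5 kb/+2 kb plus a 1 kb pad: one gene slot per 8 kb
_UP, _DOWN, _PAD = 5000, 2000, 1000
_SLOT = _UP + _DOWN + _PAD


@dataclass
class SimTruth:
    """Ground truth recorded by each generator."""

    seed: int
    planted_regulators: dict[str, float] = field(default_factory=dict)  # tf -> rho
    age_gene_ids: list[str] = field(default_factory=list)
    hot_regions: list[tuple[str, int, int]] = field(default_factory=list)
    true_concordance: dict[str, float] = field(default_factory=dict)
    true_or: dict[str, float] = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tf, rho in self.planted_regulators.items():
            if rho < 1:
                raise ValueError(f"enrichment factor for {tf} must be >= 1")
        for label, c in self.true_concordance.items():
            if not (0 <= c <= 1):
                raise ValueError(f"concordance for {label} must be in [0,1]")


def _rng(seed: int, label: str) -> np.random.Generator:
    """Independent substream for one generator, stable under code evolution."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(label.encode())]))


def simulate_genome(
    n_genes: int,
    n_chrom: int = 1,
    chrom_length: int = 10_000_000,
    seed: int = 0,
) -> list[TSSRecord]:
    """Place genes uniformly with non-overlapping promoter windows.

    Each gene occupies an 8 kb slot (−5 kb/+2 kb window plus a 1 kb pad);
    an infeasible density raises. Strands are Bernoulli(0.5). The window is
    oriented within the slot by strand — a + gene's TSS sits 5 kb into its
    slot, a − gene's 2 kb in — so windows of adjacent genes cannot overlap
    whatever strands they draw.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = _rng(seed, "genome")
    per_chrom = [n_genes // n_chrom + (1 if i < n_genes % n_chrom else 0) for i in range(n_chrom)]
    records: list[TSSRecord] = []
    gene_no = 0
    for ci, k in enumerate(per_chrom):
        if k * _SLOT > chrom_length:
            raise ValueError(
                f"infeasible gene density: {k} genes x {_SLOT} bp slots exceed "
                f"chromosome length {chrom_length}"
            )
        chrom = f"chr{ci + 1}"
        slack = chrom_length - k * _SLOT
        offsets = np.sort(rng.uniform(0, slack, size=k))
        strands = rng.random(k) < 0.5
        for i in range(k):
            gene_no += 1
            base = int(i * _SLOT + offsets[i])
            tss = base + (_UP if strands[i] else _DOWN)
            records.append(
                TSSRecord(
                    gene_id=f"G{gene_no:05d}",
                    chrom=chrom,
                    strand="+" if strands[i] else "-",
                    tss=tss,
                )
            )
    return records


def simulate_chipseq(
    tss: list[TSSRecord],
    n_tfs: int = 161,
    cell_lines_per_tf: int = 1,
    peaks_per_experiment: int = 300,
    planted: dict[str, tuple[float, list[str]]] | None = None,
    hot_fraction: float = 0.0,
    seed: int = 0,
    n_hot_regions: int | None = None,
) -> tuple[list[PeakSet], SimTruth]:
    """ChIP-seq compendium with optional planted regulators and HOT regions.

    TF names are TF001…; each has ``cell_lines_per_tf`` experiments. A
    non-planted TF places each summit in a uniformly chosen gene's promoter
    window, or (with probability ``hot_fraction``) inside a shared HOT
    region, where every TF also deposits one anchor peak — so HOT-region
    complexity equals the compendium size and the complexity filter removes
    those sites. A planted TF picks age genes with probability proportional
    to its enrichment factor rho relative to non-age genes.
    """
    if not (0 <= hot_fraction < 1):
        raise ValueError("hot_fraction must lie in [0, 1)")
    planted = planted or {}
    tf_names = [f"TF{i + 1:03d}" for i in range(n_tfs)]
    unknown = set(planted) - set(tf_names)
    if unknown:
        raise ValueError(f"planted TFs not in compendium: {sorted(unknown)}")
    for tf, (rho, _) in planted.items():
        if rho < 1:
            raise ValueError(f"enrichment factor for {tf} must be >= 1")
    rng = _rng(seed, "chipseq")
    genes = np.array([r.gene_id for r in tss])
    chroms = np.array([r.chrom for r in tss])
    tss_pos = np.array([r.tss for r in tss])
    strands = np.array([1 if r.strand == "+" else -1 for r in tss])

    # HOT regions live in the 1 kb pad past each promoter window (the window
    # ends tss+2kb on +, tss+5kb on −) so they never enter an assignment window
    hot_regions: list[tuple[str, int, int]] = []
    if hot_fraction > 0:
        if n_hot_regions is None:
            n_hot_regions = max(1, n_tfs // 10)
        host = rng.choice(len(tss), size=n_hot_regions, replace=False)
        for gi in host:
            window_end = tss_pos[gi] + (_DOWN if strands[gi] > 0 else _UP)
            start = int(window_end) + 100
            hot_regions.append((str(chroms[gi]), start, start + 400))

    age_genes: list[str] = sorted({g for _, (_, ids) in planted.items() for g in ids})

    peaksets: list[PeakSet] = []
    for tf in tf_names:
        if tf in planted:
            rho, ids = planted[tf]
            weights = np.where(np.isin(genes, list(ids)), rho, 1.0)
            weights = weights / weights.sum()
        else:
            weights = None
        for cl in range(1, cell_lines_per_tf + 1):
            cell_line = f"CL{cl}"
            exp_id = f"{tf}_{cell_line}"
            n = peaks_per_experiment
            use_hot = (rng.random(n) < hot_fraction) if hot_regions else np.zeros(n, bool)
            gene_idx = rng.choice(len(tss), size=n, p=weights)
            window_u = rng.random(n)
            hot_idx = rng.integers(0, max(len(hot_regions), 1), size=n)
            hot_u = rng.random(n)
            lengths = rng.integers(150, 400, size=n)
            sigs = 5.0 + rng.exponential(3.0, size=n)
            peaks: list[Peak] = []
            # one anchor peak per HOT region from every TF (first cell line)
            if cl == 1:
                for chrom, start, end in hot_regions:
                    peaks.append(
                        Peak(chrom, start, end, (start + end) // 2, 10.0, tf, cell_line, exp_id)
                    )
            for j in range(n):
                if use_hot[j]:
                    chrom, hstart, hend = hot_regions[hot_idx[j]]
                    summit = hstart + int(hot_u[j] * (hend - hstart))
                else:
                    gi = gene_idx[j]
                    chrom = chroms[gi]
                    # strand-aware promoter window, inclusive bounds
                    d = int(window_u[j] * (_UP + _DOWN + 1)) - _UP
                    summit = tss_pos[gi] + d * strands[gi]
                half = int(lengths[j]) // 2
                start = max(0, summit - half)
                end = max(start + int(lengths[j]), summit + 1)
                peaks.append(Peak(chrom, start, end, summit, float(sigs[j]), tf, cell_line, exp_id))
            peaksets.append(PeakSet(peaks, provenance=f"simulate_chipseq(seed={seed})"))
    truth = SimTruth(
        seed=seed,
        planted_regulators={tf: rho for tf, (rho, _) in planted.items()},
        age_gene_ids=age_genes,
        hot_regions=hot_regions,
        extra={"tf_names": tf_names},
    )
    return peaksets, truth


def simulate_expression(
    genes: list[str],
    n_samples: int = 73,
    age_range: tuple[float, float] = (27.0, 92.0),
    frac_age_genes: float = 0.1,
    beta_age_sd: float = 0.01,
    gfr_model: tuple[float, float] = (-0.9, 12.0),
    frac_gfr_mediated: float = 0.5,
    noise_sd: float = 0.25,
    seed: int = 0,
    gfr_intercept: float = 130.0,
    with_detection_p: bool = False,
) -> tuple[ExpressionMatrix, SimTruth]:
    """Normalized log2 expression driven by age directly or through GFR.

    Ages are uniform in ``age_range``; GFR = intercept + slope·age + noise
    with (slope, noise sd) = ``gfr_model``. A fraction ``frac_age_genes`` of
    genes are age-related; of those, ``frac_gfr_mediated`` act through GFR
    (expression = mu + beta_gfr·GFR + eps, so their marginal age slope
    attenuates once GFR is a covariate) and the rest directly through age
    (expression = mu + beta_age·age + eps). beta_gfr is scaled by the GFR
    slope so marginal age effects have sd ``beta_age_sd`` either way.
    """
    lo, hi = age_range
    if not (0 < lo < hi < 120):
        raise ValueError("age_range must lie within (0, 120)")
    for name, frac in [("frac_age_genes", frac_age_genes), ("frac_gfr_mediated", frac_gfr_mediated)]:
        if not (0 <= frac <= 1):
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = _rng(seed, "expression")
    n_genes = len(genes)
    ages = rng.uniform(lo, hi, size=n_samples)
    gfr_slope, gfr_noise = gfr_model
    gfr = gfr_intercept + gfr_slope * ages + rng.normal(0, gfr_noise, size=n_samples)

    n_age = round(frac_age_genes * n_genes)
    age_idx = rng.choice(n_genes, size=n_age, replace=False)
    n_gfr = round(frac_gfr_mediated * n_age)
    gfr_idx = set(age_idx[:n_gfr].tolist())
    age_only_idx = set(age_idx[n_gfr:].tolist())

    mu = rng.normal(8.0, 1.5, size=n_genes)
    values = np.tile(mu[:, None], (1, n_samples))
    beta_age = np.zeros(n_genes)
    beta_gfr = np.zeros(n_genes)
    for i in range(n_genes):
        if i in age_only_idx:
            beta_age[i] = rng.normal(0, beta_age_sd)
            values[i] += beta_age[i] * ages
        elif i in gfr_idx:
            beta_gfr[i] = rng.normal(0, beta_age_sd) / gfr_slope
            values[i] += beta_gfr[i] * gfr
    values += rng.normal(0, noise_sd, size=values.shape)

    samples = [f"S{j + 1:03d}" for j in range(n_samples)]
    detection_p = None
    if with_detection_p:
        # expressed genes detect confidently in most samples
        detection_p = pd.DataFrame(
            rng.uniform(0, 0.01, size=(n_genes, n_samples)),
            index=genes,
            columns=samples,
        )
    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        age=pd.Series(ages, index=samples),
        gfr=pd.Series(gfr, index=samples),
        detection_p=detection_p,
    )
    truth = SimTruth(
        seed=seed,
        age_gene_ids=sorted(genes[i] for i in age_idx),
        extra={
            "age_direct_gene_ids": sorted(genes[i] for i in age_only_idx),
            "gfr_mediated_gene_ids": sorted(genes[i] for i in gfr_idx),
            "beta_age": {genes[i]: float(beta_age[i]) for i in age_only_idx},
            "beta_gfr": {genes[i]: float(beta_gfr[i]) for i in gfr_idx},
            "gfr_model": gfr_model,
        },
    )
    return expr, truth


def simulate_cytokine_response(
    target_genes: list[str],
    concordance_c: float = 0.875,
    effect_mu: float = 1.0,
    effect_sd: float = 0.5,
    p_induced: float = 0.8,
    seed: int = 0,
    perturbation: str = "cytokine",
    non_target_genes: list[str] | None = None,
) -> tuple[DETable, pd.Series, SimTruth]:
    """Cytokine-response DE table plus matching age slopes.

    Each target is induced with probability ``p_induced`` (positive log2fc
    of magnitude |N(effect_mu, effect_sd)|) else repressed; with probability
    ``concordance_c`` an induced target's age slope is set positive (and a
    repressed one's negative). Target DE p-values are drawn below 0.05;
    non-targets get null log2fc and U(0,1) p-values. Returns (DE table,
    per-gene age slopes, truth).
    """
    if not (0 <= concordance_c <= 1):
        raise ValueError("concordance_c must lie in [0, 1]")
    rng = _rng(seed, "cytokine")
    rows = []
    slopes: dict[str, float] = {}
    for g in target_genes:
        induced = rng.random() < p_induced
        mag = abs(rng.normal(effect_mu, effect_sd)) + 0.05
        log2fc = mag if induced else -mag
        concordant = rng.random() < concordance_c
        slope_mag = abs(rng.normal(0.01, 0.004)) + 1e-4
        if induced:
            slope = slope_mag if concordant else -slope_mag
        else:
            slope = -slope_mag if concordant else slope_mag
        rows.append({"gene_id": g, "log2fc": log2fc, "p": rng.uniform(1e-6, 0.05)})
        slopes[g] = slope
    for g in non_target_genes or []:
        rows.append({"gene_id": g, "log2fc": rng.normal(0, 0.1), "p": rng.uniform(0, 1)})
        slopes[g] = rng.normal(0, 0.01)
    de = DETable(pd.DataFrame(rows), perturbation=perturbation)
    truth = SimTruth(
        seed=seed,
        true_concordance={perturbation: concordance_c},
        extra={"p_induced": p_induced, "age_slopes": dict(slopes)},
    )
    return de, pd.Series(slopes), truth


def _allelic_or_forward(true_or: float, maf: float, n_cases: int, n_controls: int) -> tuple[float, float, float]:
    """Exact (f_case, f_control, chi2) for a pooled-MAF table with a given OR."""
    from scipy import optimize

    w_case = n_cases / (n_cases + n_controls)
    w_ctl = 1.0 - w_case

    def freqs(delta: float) -> tuple[float, float]:
        return maf + delta * w_ctl, maf - delta * w_case

    def or_of(delta: float) -> float:
        f1, f2 = freqs(delta)
        return (f1 / (1 - f1)) / (f2 / (1 - f2))

    if true_or < 1.0:
        # the construction enriches the minor allele in cases (delta >= 0);
        # protective effects are encoded by swapping case/control labels
        raise ValueError(
            f"true_or {true_or} incompatible with the minor-allele risk "
            "parametrization; encode protective alleles by swapping cohorts"
        )
    if true_or == 1.0:
        delta = 0.0
    else:
        delta_max = min((1.0 - maf) / w_ctl, maf / w_case) * (1 - 1e-12)
        if or_of(delta_max) < true_or:
            raise ValueError(f"true_or {true_or} incompatible with maf {maf}")
        delta = float(optimize.brentq(lambda d: or_of(d) - true_or, 0.0, delta_max, xtol=1e-14))
    f1, f2 = freqs(delta)
    n1, n2 = 2.0 * n_cases, 2.0 * n_controls
    a, b, c, d = n1 * f1, n1 * (1 - f1), n2 * f2, n2 * (1 - f2)
    n = n1 + n2
    chi2 = (a * d - b * c) ** 2 * n / (n1 * n2 * (a + c) * (b + d)) if (a + c) and (b + d) else 0.0
    return f1, f2, chi2


def simulate_assoc(
    genes: list[str],
    snps_per_gene: int = 2,
    true_or: float = 1.2,
    maf: float = 0.3,
    n_cases: int = 5000,
    n_controls: int = 50000,
    seed: int = 0,
    phenotype: str = "CKD",
) -> tuple[list[SNPAssocRecord], SimTruth]:
    """SNP association records from exact expected-count 2×2 allele tables.

    For each SNP the case/control minor-allele frequencies are set so the
    pooled frequency equals ``maf`` and the allelic odds ratio equals
    ``true_or``; the Pearson chi-square p-value of that table is emitted
    (with a −log10 side channel, since extreme tables underflow p in double
    precision). The construction is deterministic; the seed is recorded in
    the truth sidecar for provenance.
    """
    if true_or <= 0:
        raise ValueError("true_or must be > 0")
    if not (0 < maf <= 0.5):
        raise ValueError("maf must be in (0, 0.5]")
    _, _, chi2 = _allelic_or_forward(true_or, maf, n_cases, n_controls)
    if chi2 > 0:
        log_p = float(math.log(2.0) + special.log_ndtr(-math.sqrt(chi2)))
        neg_log10_p = -log_p / math.log(10.0)
        p = max(math.exp(log_p) if log_p > -745 else 0.0, 5e-324)
    else:
        p, neg_log10_p = 1.0, 0.0
    records: list[SNPAssocRecord] = []
    truths: dict[str, float] = {}
    for gene in genes:
        for i in range(1, snps_per_gene + 1):
            snp_id = f"rs_{gene}_{i}"
            records.append(
                SNPAssocRecord(
                    snp_id=snp_id,
                    gene=gene,
                    p_by_phenotype={phenotype: p},
                    major_allele="C",
                    minor_allele="T",
                    maf=maf,
                    n_cases=n_cases,
                    n_controls=n_controls,
                    neg_log10_p_by_phenotype={phenotype: neg_log10_p},
                )
            )
            truths[snp_id] = true_or
    truth = SimTruth(seed=seed, true_or=truths, extra={"chi2": chi2, "phenotype": phenotype})
    return records, truth


def simulate_latent_activity(
    labels: list[str],
    n_samples: int = 73,
    loading: float = 0.85,
    seed: int = 0,
    independent_labels: list[str] | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Activity-like scores sharing one latent factor.

    Each labelled score is loading·f + sqrt(1 − loading²)·e with f and e
    standard normal over samples, so any two share expected Pearson r =
    loading². ``independent_labels`` get pure-noise scores (no loading).
    """
    if not (0 <= loading <= 1):
        raise ValueError("loading must lie in [0, 1]")
    rng = _rng(seed, "latent")
    samples = [f"S{j + 1:03d}" for j in range(n_samples)]
    f = rng.normal(0, 1, size=n_samples)
    cols = {}
    for lab in labels:
        cols[lab] = loading * f + math.sqrt(1 - loading**2) * rng.normal(0, 1, size=n_samples)
    for lab in independent_labels or []:
        cols[lab] = rng.normal(0, 1, size=n_samples)
    truth = SimTruth(seed=seed, extra={"loading": loading, "expected_r": loading**2})
    return pd.DataFrame(cols, index=samples), truth
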