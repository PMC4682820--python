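# Methods

This note records the statistical models, conventions and design choices
behind `renalage`, in the spirit of a methods appendix: what each stage
assumes, which knobs matter, and what the synthetic-data experiments do and
do not establish.

## Coordinates, peaks and target assignment

All genomic intervals are 0-based half-open (BED convention); TSS positions
are 0-based. Peak files are narrowPeak (BED6+4) or BED6 plus a
−log10-scaled significance column; per the narrowPeak convention the q
column is used when present and ≥ 0, otherwise the p column. The ingest
filter keeps peaks with −log10 significance ≥ −log10(threshold), default
threshold 10⁻⁵, and length ≥ 20 bp (strict reading: length-19 peaks are
discarded at any significance). The summit is start + offset, falling back
to the interval midpoint (floor) when the offset is −1 — deterministic and
standard practice.

A gene is a target of an experiment when any of its TSS satisfies
−5000 ≤ d ≤ 2000 with d = summit − tss on the + strand and d = tss − summit
on the − strand. Both bounds are inclusive; boundary tests pin this choice.
Only the summit is used, never the full peak interval, since the summit
marks maximum read density. Genes with several annotated TSS match if any
window matches; duplicate TSS records are therefore kept at ingest.

**Binding-site complexity** is the number of distinct TFs with a
significant site overlapping a peak (≥ 1 bp intersection; the peak's own TF
counts; repeat observations of one TF across cell lines count once). The
filter retains peaks with complexity ≤ ⌈f·N⌉ for compendium size N and
max fraction f = 0.5, giving the 81-of-161 cutoff. The "≤ 81 or < 81"
convention is genuinely ambiguous at one unit; we use ≤ ⌈f·N⌉ and expose f,
so either reading is reachable.

## The enrichment screen

For target set T, query set Q and universe U the screen builds the 2×2
table of membership counts. Test selection follows the classical validity
rule: the 1-df Pearson chi-square without continuity correction when all
four expected cell counts exceed 5, otherwise Fisher's exact test. The
Fisher tail is one-sided toward enrichment, P(overlap ≥ k) — the screen is
for enrichment only; chi-square is inherently two-sided, but a chi-square
hit with fold ≤ 1 can never pass the fold criterion, so the decision rule
is one-sided either way. Fold = observed/expected with expected =
|T|·|Q|/|U|. Degenerate margins (empty or universe-spanning sets) return
p = 1 rather than an undefined statistic.

Candidates must clear fold > 1.5 and p < α/m with m = number of experiments
screened (a literal threshold override is available for reproducing a
printed cutoff such as 5×10⁻⁵ at m = 961), must not be on the excluded list
(non-specific DNA-binding machinery), and must be on the
epithelial-expression allow-list when one is supplied. The specificity
filter flags a TF for a query set only when one of its experiments is
simultaneously fold > 1.5, p < 5×10⁻⁵ and ranked in the top 5% of all
experiments for that set (ties broken by larger fold, then experiment id).
The background universe should be the genes assayable on the expression
platform, not the whole genome.

## Expression statistics

Detection filtering keeps genes with detection p < 0.01 in ≥ 1 sample.
Differential expression is the classical pooled-variance (Student) t-test,
two-sided, with log2fc = mean difference of already-log2 values. Genes with
zero variance in both groups get p = 1 when means agree; when means differ
(possible in microarray data after clipping) p is set to the smallest
representable double and the event is warned about. Probe-to-gene collapse
keeps the most differentially expressed probe (smallest p, then largest
|log2fc|, then lexicographic probe id).

The age model is per-gene OLS of expression on intercept + age, optionally
+ GFR, fitted in closed form simultaneously for all genes (the estimates
are identical to any per-gene OLS routine; the vectorised normal-equations
path is simply orders of magnitude faster across thousands of genes).
Exact age–GFR collinearity raises with the design condition number.
Constant genes report β = 0, SE = 0, p = 1. The attenuation statistic is
the fraction of genes with |β_age(age+GFR)| < |β_age(age)|; equal
magnitudes count as not reduced. Note a finite-sample subtlety the tests
respect: for genes truly unrelated to both covariates the attenuation
probability sits slightly below ½ at moderate n, because the extra
covariate inflates the slope's sampling variance by 1/(1 − r²) for the
realized age–GFR sample correlation r; chance level is approached as n
grows.

## Concordance and cross-species overlap

Direct targets = bound (ChIP-seq, proximal assignment) ∧ DE p < 0.05 under
the TF's activating cytokine. Exclusivity filtering removes genes shared
with any other TF's set; which TFs are filtered is a parameter (the study
description applies it to the NFκB and STAT1 sets; STAT3 defaults to
unfiltered).

The concordance test conditions on the induced targets (log2fc > 0);
a target is concordant when its age slope is > 0, with a slope of exactly 0
counted as non-concordant (a measure-zero event needing a deterministic
rule). The p-value is the exact one-sided binomial tail against ½ — the
only natural null for direction symmetry, and the choice that reproduces
p < 10⁻⁵ for 35 concordant of 40. Profile correlation is the sample
Pearson r with the usual t-transform p at n − 2 df.

Cross-species overlap restricts to one-to-one orthologs present in both
datasets, correlates human age slopes with the other species'
old-versus-young log2fc, and tests the overlap of significance calls with
the hypergeometric upper tail within the ortholog universe; fold is
observed/expected under independence. When one margin spans the whole
universe the fold degenerates to 1 by construction and the result is
flagged. The universe is a parameter because enrichment against the
ortholog set and against all expressed genes are both defensible.

## TF activity and covariation

Gene z-scores use the sample sd (n − 1 denominator), pinned by
(1,2,3) → (−1,0,1). Activity = unweighted mean z over the member genes;
age adjustment = OLS residuals of activity on intercept + age, which are
exactly orthogonal to age (checked to 10⁻¹⁰). Covariation is pairwise
Pearson r of adjusted profiles, clustered agglomeratively with distance
1 − r and average linkage (a common default of the heat-map tools in this
field; the linkage is configurable). Profiles are sorted by label before
clustering so the leaf order is deterministic under input permutation. The
macrophage abundance score is the identical composition applied to marker
transcripts, default CD163/CD14/TYROBP and configurable for other leukocyte
marker sets.

## SNP analysis and odds-ratio reconstruction

The Bonferroni threshold is α/(n_SNPs·n_phenotypes); its printed rendering
truncates the mantissa to one decimal (0.05/434 = 1.152…×10⁻⁴ → "1.1 x
10^-4"), i.e. the largest 2-significant-figure threshold not exceeding the
exact one. Lead SNP = minimum p within the gene for the phenotype, ties
lexicographic.

The allelic odds ratio implied by a summary p-value is reconstructed by
chi-square matching: with group shares w of total allele counts, set
f_case = MAF + δ·w_ctl and f_ctl = MAF − δ·w_case (pooled frequency pinned
at the reported MAF) and solve for δ ≥ 0 by Brent's method so the Pearson
chi-square (1 df, no continuity correction) of the expected-count table
equals qchisq(1 − p, 1), to 10⁻¹⁰. OR = odds(f_case)/odds(f_ctl), inverted
for protective alleles. Carrier mode replaces allele frequencies with
Hardy–Weinberg carrier frequencies 2f(1−f)+f² on person totals, for the
reading of "minor allele carriers" as people rather than chromosomes;
allelic mode is the default. The chi-square ↔ p conversion runs through
the normal identity p = 2·Φ(−√x) in log space (`log_ndtr`/`ndtri_exp`), so
associations whose p-values underflow double precision round-trip exactly
via a −log10(p) channel that the simulator also emits.

LD is consumed as a table, never computed; proxy SNPs need R² strictly
greater than 0.8, and annotation overlap is point-in-half-open-interval
(a SNP at an interval's end coordinate is outside).

## The synthetic-data generator

The generator emulates the statistical structure of the study's inputs, at
configurable scale. Defaults: 161 TFs (up to 961 experiments), 73 samples
aged uniformly 27–92, GFR = 130 − 0.9·age + N(0, 12²) mL/min/1.73 m²
(textbook adult decline), log2 expression noise sd 0.25, age-slope sd
0.01/yr, half of age-related genes GFR-mediated, cytokine effect sizes
|N(1, 0.5)| log2 units with induction probability 0.8 and direction
concordance 0.875 (the 35/40 condition). One global seed fans out to
per-generator substreams keyed by stable labels (CRC32 of the generator
name), so adding a generator does not shift the others' streams; every
generator is byte-deterministic under its seed and returns a truth sidecar
that only tests and recovery analyses may read.

Genome placement packs one gene per 8 kb slot with the promoter window
oriented inside the slot by strand, so windows never overlap whatever
strands are drawn; densities above one gene per 8 kb raise. HOT regions
are placed in the 1 kb pad past each hosting gene's window — outside every
assignment window — and every TF deposits one anchor peak in each HOT
region, so HOT complexity equals the compendium size and the complexity
filter provably removes those sites. A planted regulator picks genes with
probability proportional to ρ on the age set versus 1 elsewhere. The SNP
generator is fully deterministic: it builds the exact expected-count
allele table for the requested OR and MAF and emits its chi-square p;
protective ORs (< 1) are rejected since the construction designates the
minor allele as the risk allele (swap cohorts to encode them).

What the generator does **not** emulate: read-level ChIP-seq signal and
peak-calling noise, probe-level microarray artifacts and normalization,
correlated gene–gene expression structure beyond the explicit latent
factor, LD structure (LD is an input table), and genotype sampling noise
(association tables are expected counts). Passing recovery tests therefore
show that the estimators are correct and calibrated under the assumed
structure, not that the study's specific real-data values would reproduce.

## Recovery and calibration experiments

The study's real-data numbers (screen enrichments such as 4.4-fold at
p = 1.3×10⁻⁵, the 74% GFR attenuation, human–rat r = 0.46 and 114/427
overlap, the activity–macrophage r = 0.66–0.81, the Table-1 odds ratios)
depend on external microarray, ENCODE and GWAS data and are not
desk-reproducible; the package replaces them with properties computed in
`renalage.calibration` and asserted in the test suite:

- planted-regulator recovery: a ρ = 10 TF among 20, 300 peaks/experiment,
  400-gene query in a 10⁴-gene universe, tops the screen in ≥ 95/100 seeds;
- Fisher branch ≡ brute-force hypergeometric tail to 10⁻¹² (exhaustive over
  universes ≤ 40 — full enumeration to 200 would be ~10⁸ tables — plus 2000
  random tables up to 200);
- chi-square branch type-I error within 3·SE of α on 2000 null experiments;
- concordance estimator unbiased at c = 0.875, n = 40 over 500 seeds;
- β_age recovered within 3·SE for ≥ 95% of genes;
- OR reconstruction round-trips the generator within 10⁻⁶ over
  OR ∈ {1.01…2} × MAF ∈ {0.05…0.5} × n ∈ {10³…10⁵};
- mean pairwise activity correlation recovers the latent loading² within
  3·SE over 200 seeds;
- age-adjusted scores are uncorrelated with age to 10⁻¹⁰.

Problem sizes (2000-gene expression matrices, 10⁴-gene screens, 100–500
seed replications) were chosen as the smallest that leave Monte-Carlo error
well below each decision margin.

## Known limitations

- The screen treats experiments as independent when Bonferroni-correcting;
  replicate cell lines of one TF are correlated, making the correction
  conservative at the TF level.
- The pooled-variance t-test assumes equal group variances; no
  empirical-Bayes moderation is applied (deliberately out of scope).
- The age model fits intercept + age (+ GFR) only; additional clinical
  covariates (e.g. tissue source) are not modelled.
- Carrier-mode OR assumes Hardy–Weinberg within cases and controls
  separately, an approximation for a disease cohort.
- The cross-species analysis requires a pre-resolved one-to-one ortholog
  map; many-to-many orthology must be handled upstream.
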