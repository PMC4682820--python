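"""Direct-target definition, direction concordance and cross-species overlap.

A TF's direct targets are the genes both bound in ChIP-seq (promoter-proximal
assignment) and differentially expressed (p < 0.05) when the TF is activated
by its cytokine. Concordance asks whether cytokine-induced targets also rise
with age (one-sided binomial test against 0.5); profile correlation compares
induction log2 fold-changes with age slopes; the cross-species analysis
overlaps human age-gene calls with an orthologous species' old-vs-young calls.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import DETable

__all__ = [
    "DirectTargetSet",
    "ConcordanceResult",
    "define_direct_targets",
    "exclusive_targets",
    "concordance_test",
    "profile_correlation",
    "cross_species_overlap",
]


@dataclass
class DirectTargetSet:
    tf: str
    genes: set[str]
    source: dict = field(default_factory=dict)
    exclusive: bool = False


@dataclass
class ConcordanceResult:
    n_induced: int
    n_concordant: int
    p_binomial: float

    @property
    def concordance_pct(self) -> float:
        return 100.0 * self.n_concordant / self.n_induced


def define_direct_targets(
    chip_targets: set[str],
    de: DETable,
    p_max: float = 0.05,
    tf: str = "",
) -> DirectTargetSet:
    """Genes bound by the TF and differentially expressed (p < p_max)."""
    p = de.p_of()
    de_genes = set(p.index[p < p_max])
    genes = chip_targets & de_genes
    if not genes:
        warnings.warn(f"no direct targets for {tf or 'TF'}: empty bound∩DE set", stacklevel=2)
    return DirectTargetSet(
        tf=tf,
        genes=genes,
        source={"de_perturbation": de.perturbation, "p_max": p_max},
    )


def exclusive_targets(
    sets: dict[str, DirectTargetSet],
    apply_to: set[str] | None = None,
) -> dict[str, DirectTargetSet]:
    """Remove genes shared with any other TF's target set.

    ``apply_to`` names the TFs whose sets are exclusivity-filtered (default:
    all). The study filtered the NFκB and STAT1 sets; STAT3 filtering is the
    caller's choice.
    """
    if len(sets) < 2:
        raise ValueError("exclusivity needs >= 2 TFs")
    if apply_to is None:
        apply_to = set(sets)
    out: dict[str, DirectTargetSet] = {}
    for tf, ts in sets.items():
        if tf in apply_to:
            others = set().union(*(s.genes for other, s in sets.items() if other != tf))
            genes = ts.genes - others
            out[tf] = DirectTargetSet(tf=tf, genes=genes, source=dict(ts.source), exclusive=True)
        else:
            out[tf] = ts
    return out


def concordance_test(
    de: DETable,
    age_slopes: pd.Series,
    induced_only: bool = True,
) -> ConcordanceResult:
    """Direction concordance between cytokine response and aging.

    With ``induced_only``, the denominator is the targets with log2fc > 0;
    a target is concordant iff its age slope is also > 0 (a slope of exactly
    0 counts as non-concordant). p is the one-sided binomial tail
    P(X >= n_concordant | n, 0.5).
    """
    tab = de.table
    missing = set(tab["gene_id"]) - set(age_slopes.index)
    if missing:
        raise ValueError(f"age slope missing for targets: {sorted(missing)[:5]}")
    if induced_only:
        tab = tab[tab["log2fc"] > 0]
    n = len(tab)
    if n == 0:
        raise ValueError("no induced targets: concordance undefined")
    slopes = age_slopes.loc[tab["gene_id"]].to_numpy(float)
    if induced_only:
        concordant = slopes > 0
    else:
        concordant = np.sign(slopes) == np.sign(tab["log2fc"].to_numpy(float))
        concordant &= slopes != 0
    k = int(concordant.sum())
    p = float(stats.binomtest(k, n, 0.5, alternative="greater").pvalue)
    return ConcordanceResult(n_induced=n, n_concordant=k, p_binomial=p)


def profile_correlation(
    de_log2fc: pd.Series | np.ndarray,
    age_slopes: pd.Series | np.ndarray,
) -> tuple[float, float]:
    """Pearson correlation between perturbation log2fc and age slopes.

    Returns (r, two-sided p from the t transform with n−2 df).
    """
    x = np.asarray(de_log2fc, float)
    y = np.asarray(age_slopes, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be 1-D and the same length")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def cross_species_overlap(
    human_age_genes: set[str],
    human_slopes: pd.Series,
    ortholog_map: dict[str, str],
    other_species_de: DETable,
    other_sig_p: float = 0.05,
    human_sig: set[str] | None = None,
) -> dict:
    """Overlap of age-related calls between human and an orthologous species.

    ``ortholog_map`` maps human gene → other-species gene and must be
    one-to-one on the analyzed genes. The analysis restricts to orthologs
    present in both datasets; within that universe it reports the Pearson r
    between human age slopes and the other species' old-vs-young log2fc, the
    number of genes significant in both, the fold enrichment of that overlap
    over independence, and the hypergeometric upper-tail p.

    ``human_sig`` defaults to all ``human_age_genes`` (the degenerate margin
    where every human gene in the universe is called significant, in which
    case fold reduces to 1 by construction and is flagged).
    """
    values = list(ortholog_map.values())
    if len(set(values)) != len(values):
        raise ValueError("ortholog map must be one-to-one (many-to-many unresolved)")
    other = other_species_de.table.set_index("gene_id")
    shared = [
        h for h in human_age_genes
        if h in ortholog_map and ortholog_map[h] in other.index and h in human_slopes.index
    ]
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared orthologs")
    shared.sort()
    o_genes = [ortholog_map[h] for h in shared]
    r, p_r = profile_correlation(
        human_slopes.loc[shared], other.loc[o_genes, "log2fc"]
    )
    n_universe = len(shared)
    sig_h = set(shared) if human_sig is None else set(shared) & human_sig
    sig_o = {h for h, o in zip(shared, o_genes) if other.loc[o, "p"] < other_sig_p}
    n_shared_sig = len(sig_h & sig_o)
    expected = len(sig_h) * len(sig_o) / n_universe
    fold = n_shared_sig / expected if expected > 0 else 0.0
    p_hyper = float(stats.hypergeom.sf(n_shared_sig - 1, n_universe, len(sig_h), len(sig_o)))
    degenerate = len(sig_h) == n_universe or len(sig_o) == n_universe
    if degenerate:
        warnings.warn(
            "one significance margin equals the whole ortholog universe; "
            "fold enrichment reduces to 1 by construction",
            stacklevel=2,
        )
    return {
        "r": r,
        "p_r": p_r,
        "n_universe": n_universe,
        "n_sig_human": len(sig_h),
        "n_sig_other": len(sig_o),
        "n_shared_sig": n_shared_sig,
        "fold": fold,
        "p_hyper": p_hyper,
        "degenerate_margin": degenerate,
    }
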