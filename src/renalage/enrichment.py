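"""Target-set overlap enrichment screen across a ChIP-seq compendium.

Each experiment's target genes are tested for overlap with a query gene set
(the kidney age-related genes) against a background universe. The 2×2 table
is tested with a 1-df chi-square (no continuity correction) when all four
expected cell counts exceed 5, otherwise with a one-sided Fisher's exact
test on the enrichment tail. Candidate regulators must clear a >1.5-fold
enrichment and a Bonferroni-corrected p-value threshold, survive the
exclusion of non-specific DNA-binding machinery, and (optionally) be on an
epithelial-expression allow-list.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .peaks import TargetMap

__all__ = [
    "EnrichmentResult",
    "ScreenConfig",
    "fisher_enrichment_tail",
    "overlap_enrichment",
    "screen_experiments",
    "specificity_filter",
]


def fisher_enrichment_tail(k: int, n_universe: int, n_targets: int, n_query: int) -> float:
    """One-sided Fisher enrichment p: P(overlap >= k) under the hypergeometric null."""
    return float(stats.hypergeom.sf(k - 1, n_universe, n_targets, n_query))


@dataclass
class EnrichmentResult:
    experiment_id: str
    tf: str
    cell_line: str
    n_targets_in_universe: int
    n_query_in_universe: int
    n_overlap: int
    n_universe: int
    expected: float
    fold: float
    p: float
    test_used: str  # "fisher" or "chisq"


@dataclass
class ScreenConfig:
    """Thresholds and exclusion lists for the enrichment screen.

    ``bonferroni_n`` is the number of experiments tested; the per-test
    threshold is alpha / bonferroni_n unless ``p_threshold_override`` is set
    (e.g. the study's printed 5e-5 over 961 experiments).
    """

    fold_min: float = 1.5
    alpha: float = 0.05
    bonferroni_n: int = 1
    excluded_tfs: frozenset[str] = frozenset()
    epithelial_expressed_tfs: frozenset[str] | None = None
    p_threshold_override: float | None = None

    def __post_init__(self) -> None:
        if self.fold_min <= 0:
            raise ValueError("fold_min must be > 0")
        if self.bonferroni_n < 1:
            raise ValueError("bonferroni_n must be >= 1")
        self.excluded_tfs = frozenset(self.excluded_tfs)
        if self.epithelial_expressed_tfs is not None:
            self.epithelial_expressed_tfs = frozenset(self.epithelial_expressed_tfs)

    @property
    def p_threshold(self) -> float:
        if self.p_threshold_override is not None:
            return self.p_threshold_override
        return self.alpha / self.bonferroni_n


def overlap_enrichment(
    targets: set[str],
    query: set[str],
    universe: set[str],
    experiment_id: str = "",
    tf: str = "",
    cell_line: str = "",
) -> EnrichmentResult:
    """Test a target set for enrichment of query genes within a universe.

    fold = observed / expected with expected = |targets|·|query|/|universe|.
    The chi-square branch (1 df, no continuity correction, inherently
    two-sided) is used when all four expected counts exceed 5; otherwise the
    one-sided Fisher/hypergeometric enrichment tail.
    """
    if not universe:
        raise ValueError("universe must be nonempty")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    targets = targets & universe
    n_u = len(universe)
    n_t = len(targets)
    n_q = len(query)
    k = len(targets & query)
    expected = n_t * n_q / n_u
    fold = k / expected if expected > 0 else 0.0
    table = np.array(
        [[k, n_t - k], [n_q - k, n_u - n_t - n_q + k]], dtype=float
    )
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    if (row == 0).any() or (col == 0).any():
        # degenerate margin (empty/full target or query set): no evidence
        return EnrichmentResult(
            experiment_id, tf, cell_line, n_t, n_q, k, n_u, expected, fold, 1.0, "fisher"
        )
    expected_cells = row @ col / n_u
    if (expected_cells > 5).all():
        chi2 = float(((table - expected_cells) ** 2 / expected_cells).sum())
        p = float(stats.chi2.sf(chi2, df=1))
        test_used = "chisq"
    else:
        p = fisher_enrichment_tail(k, n_u, n_t, n_q)
        test_used = "fisher"
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return EnrichmentResult(experiment_id, tf, cell_line, n_t, n_q, k, n_u, expected, fold, p, test_used)


def screen_experiments(
    target_maps: list[TargetMap],
    query: set[str],
    universe: set[str],
    config: ScreenConfig | None = None,
) -> tuple[list[EnrichmentResult], list[str], pd.DataFrame]:
    """Screen every experiment against the query set; rank and call candidates.

    Returns (results sorted by p, candidate TF names, per-TF summary). A TF
    is a candidate iff it is not excluded, is on the epithelial allow-list
    when one is supplied, and its best experiment has fold > fold_min and
    p < the Bonferroni threshold. The summary reports each TF's best
    experiment and how many of its experiments pass.
    """
    if not target_maps:
        raise ValueError("screen requires at least one target map")
    if config is None:
        config = ScreenConfig(bonferroni_n=len(target_maps))
    results = [
        overlap_enrichment(tm.targets, query, universe, tm.experiment_id, tm.tf, tm.cell_line)
        for tm in target_maps
    ]
    results.sort(key=lambda r: (r.p, -r.fold, r.experiment_id))
    thr = config.p_threshold
    rows = []
    candidates = []
    for tf, group in _group_by_tf(results).items():
        best = group[0]
        n_pass = sum(1 for r in group if r.fold > config.fold_min and r.p < thr)
        passes = best.fold > config.fold_min and best.p < thr
        eligible = tf not in config.excluded_tfs and (
            config.epithelial_expressed_tfs is None or tf in config.epithelial_expressed_tfs
        )
        if passes and eligible:
            candidates.append(tf)
        rows.append(
            {
                "tf": tf,
                "best_experiment": best.experiment_id,
                "best_cell_line": best.cell_line,
                "best_fold": best.fold,
                "best_p": best.p,
                "n_experiments": len(group),
                "n_passing": n_pass,
                "excluded": tf in config.excluded_tfs,
                "candidate": passes and eligible,
            }
        )
    summary = pd.DataFrame(rows).sort_values("best_p").reset_index(drop=True)
    candidates.sort(key=lambda t: next(r.p for r in results if r.tf == t))
    return results, candidates, summary


def _group_by_tf(results: list[EnrichmentResult]) -> dict[str, list[EnrichmentResult]]:
    groups: dict[str, list[EnrichmentResult]] = {}
    for r in results:  # results already sorted by p; groups inherit that order
        groups.setdefault(r.tf, []).append(r)
    return groups


def specificity_filter(
    results_for_query_sets: dict[str, list[EnrichmentResult]],
    tf: str,
    fold_min: float = 1.5,
    p_max: float = 5e-5,
    top_fraction: float = 0.05,
) -> dict[str, bool]:
    """Per-query-set specificity flags for one TF.

    For each query set (screened against the full compendium), an
    experiment counts as significant iff fold > fold_min, p < p_max and its
    p ranks within the top ``top_fraction`` (smallest p) of all experiments
    for that set; ties broken by larger fold then experiment id. The TF is
    flagged for a set when any of its experiments counts.
    """
    flags: dict[str, bool] = {}
    for set_name, results in results_for_query_sets.items():
        ranked = sorted(results, key=lambda r: (r.p, -r.fold, r.experiment_id))
        n = len(ranked)
        cutoff_rank = top_fraction * n  # rank is 1-based; keep rank/n <= top_fraction
        flag = False
        for rank, r in enumerate(ranked, start=1):
            if rank > cutoff_rank:
                break
            if r.tf == tf and r.fold > fold_min and r.p < p_max:
                flag = True
                break
        flags[set_name] = flag
    return flags
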