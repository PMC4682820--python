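"""Expression-side statistics.

Detection filtering, unpaired Student's t differential expression, collapse
of multiple probes per gene, per-gene OLS regression of log2 expression on
age (optionally with GFR as a second covariate), and the age-coefficient
attenuation analysis that asks how many age-related genes lose age signal
once renal function is controlled for.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import DETable, ExpressionMatrix

__all__ = [
    "AgeModelResult",
    "detection_filter",
    "differential_expression",
    "collapse_probes",
    "fit_age_model",
    "gfr_attenuation",
]

_TINY_P = 5e-324  # smallest positive double; flag value for zero-variance shifts


@dataclass
class AgeModelResult:
    """Per-gene regression of log2 expression on age (and optionally GFR)."""

    gene_id: str
    beta_age: float
    se_age: float
    p_age: float
    beta_gfr: float | None
    model: str  # "age_only" or "age_plus_gfr"


def detection_filter(expr: ExpressionMatrix, alpha: float = 0.01) -> ExpressionMatrix:
    """Retain genes with signal-detection p < alpha in at least one sample."""
    if expr.detection_p is None:
        raise ValueError(
            "expression matrix has no detection p-values; pass the unfiltered "
            "matrix explicitly if the detection filter should be skipped"
        )
    keep = (expr.detection_p < alpha).any(axis=1)
    genes = expr.detection_p.index[keep]
    return ExpressionMatrix(
        values=expr.values.loc[genes],
        age=expr.age,
        gfr=expr.gfr,
        detection_p=expr.detection_p.loc[genes],
    )


def differential_expression(
    expr_treated: pd.DataFrame,
    expr_control: pd.DataFrame,
    perturbation: str = "",
) -> DETable:
    """Unpaired pooled-variance (classical Student) t-test per gene.

    Inputs are genes × samples log2 expression for the two groups (same gene
    index). log2fc = mean(treated) − mean(control). Zero variance in both
    groups yields p = 1 when the means agree and the smallest representable
    p (flagged) when they differ.
    """
    if expr_treated.shape[1] < 2 or expr_control.shape[1] < 2:
        raise ValueError("need >= 2 samples per group")
    if not expr_treated.index.equals(expr_control.index):
        expr_control = expr_control.reindex(expr_treated.index)
    t_vals = expr_treated.to_numpy(float)
    c_vals = expr_control.to_numpy(float)
    n1, n2 = t_vals.shape[1], c_vals.shape[1]
    m1, m2 = t_vals.mean(axis=1), c_vals.mean(axis=1)
    log2fc = m1 - m2
    ss1 = ((t_vals - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((c_vals - m2[:, None]) ** 2).sum(axis=1)
    df = n1 + n2 - 2
    pooled_var = (ss1 + ss2) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(pooled_var * (1 / n1 + 1 / n2))
        t = log2fc / se
        p = 2 * stats.t.sf(np.abs(t), df)
    zero_var = pooled_var == 0
    p = np.where(zero_var & (log2fc == 0), 1.0, p)
    degenerate_shift = zero_var & (log2fc != 0)
    if degenerate_shift.any():
        warnings.warn(
            f"{int(degenerate_shift.sum())} genes with zero variance but unequal "
            "means; p set to smallest representable value",
            stacklevel=2,
        )
        p = np.where(degenerate_shift, _TINY_P, p)
    table = pd.DataFrame(
        {"gene_id": expr_treated.index, "log2fc": log2fc, "p": p}
    ).reset_index(drop=True)
    return DETable(table, perturbation=perturbation)


def collapse_probes(de: DETable, probe_to_gene: dict[str, str]) -> DETable:
    """Collapse probe-level DE to gene level: keep the most DE probe per gene.

    Ties on p go to the larger |log2fc|, remaining ties to the
    lexicographically smallest probe id. Unmapped probes are dropped (count
    logged via warning).
    """
    tab = de.table.copy()
    tab["gene"] = tab["gene_id"].map(probe_to_gene)
    n_unmapped = int(tab["gene"].isna().sum())
    if n_unmapped:
        warnings.warn(f"dropping {n_unmapped} unmapped probes", stacklevel=2)
        tab = tab.dropna(subset=["gene"])
    tab = tab.sort_values(
        by=["gene", "p", "log2fc", "gene_id"],
        key=lambda col: -col.abs() if col.name == "log2fc" else col,
    )
    best = tab.groupby("gene", sort=True).head(1)
    out = pd.DataFrame(
        {"gene_id": best["gene"].to_numpy(), "log2fc": best["log2fc"].to_numpy(), "p": best["p"].to_numpy()}
    )
    return DETable(out.reset_index(drop=True), perturbation=de.perturbation)


def _ols_per_gene(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised OLS of each row of y on design x (n × p, intercept first).

    Returns (beta: genes × p, se: genes × p, p_two_sided: genes × p).
    """
    n, k = x.shape
    xtx = x.T @ x
    cond = np.linalg.cond(xtx)
    if cond > 1e12:
        raise ValueError(f"design matrix ill-conditioned (condition number {cond:.3g}); "
                         "age and GFR may be exactly collinear")
    xtx_inv = np.linalg.inv(xtx)
    beta = y @ x @ xtx_inv  # genes × p
    resid = y - beta @ x.T
    dof = n - k
    sigma2 = (resid**2).sum(axis=1) / dof
    se = np.sqrt(np.outer(sigma2, np.diag(xtx_inv)))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2 * stats.t.sf(np.abs(t), dof)
    p = np.where(se == 0, 1.0, p)  # constant gene: no evidence against beta = 0
    return beta, se, p


def fit_age_model(expr: ExpressionMatrix, include_gfr: bool = False) -> list[AgeModelResult]:
    """Per-gene OLS of expression on intercept + age (+ GFR).

    A constant gene gets beta = 0 (numerically) and p = 1. Exact age↔GFR
    collinearity raises, naming the design condition number.
    """
    if expr.n_samples < 3:
        raise ValueError("need >= 3 samples")
    age = expr.age.to_numpy(float)
    if np.ptp(age) == 0:
        raise ValueError("age must vary across samples")
    cols = [np.ones_like(age), age]
    model = "age_only"
    if include_gfr:
        if expr.gfr is None:
            raise ValueError("include_gfr=True but the matrix has no GFR metadata")
        cols.append(expr.gfr.to_numpy(float))
        model = "age_plus_gfr"
    x = np.column_stack(cols)
    y = expr.values.to_numpy(float)
    beta, se, p = _ols_per_gene(y, x)
    constant = np.ptp(y, axis=1) == 0  # flat gene: no slope, no evidence
    beta[constant, 1:] = 0.0
    se[constant, 1:] = 0.0
    p[constant, 1:] = 1.0
    results = []
    for i, gene in enumerate(expr.genes):
        results.append(
            AgeModelResult(
                gene_id=gene,
                beta_age=float(beta[i, 1]),
                se_age=float(se[i, 1]),
                p_age=float(p[i, 1]),
                beta_gfr=float(beta[i, 2]) if include_gfr else None,
                model=model,
            )
        )
    return results


def gfr_attenuation(
    results_with: list[AgeModelResult],
    results_without: list[AgeModelResult],
) -> tuple[float, pd.DataFrame]:
    """Fraction of genes whose |age slope| shrinks once GFR is a covariate.

    Equal magnitudes count as not reduced. Returns (fraction, per-gene table
    with both slopes and the reduction flag).
    """
    with_by_gene = {r.gene_id: r for r in results_with}
    without_by_gene = {r.gene_id: r for r in results_without}
    if set(with_by_gene) != set(without_by_gene):
        raise ValueError("gene sets differ between the two model fits")
    rows = []
    for gene in with_by_gene:
        bw = with_by_gene[gene].beta_age
        bo = without_by_gene[gene].beta_age
        rows.append(
            {
                "gene_id": gene,
                "beta_age_with_gfr": bw,
                "beta_age_without_gfr": bo,
                "reduced": abs(bw) < abs(bo),
            }
        )
    table = pd.DataFrame(rows)
    fraction = float(table["reduced"].mean()) if len(table) else 0.0
    return fraction, table
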