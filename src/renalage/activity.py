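"""Per-sample transcription-factor activity scores and their covariation.

A TF's activity in a kidney sample is proxied by the mean z-score of its
direct-target genes in that sample; scores are age-adjusted by taking OLS
residuals from a score~age regression, so that covariation between TFs (or
between a TF and a macrophage-marker abundance score) is measured among
individuals of the same age. Profiles are hierarchically clustered with
1 − Pearson r distance and average linkage.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .types import ExpressionMatrix

__all__ = [
    "ActivityProfile",
    "zscore_genes",
    "activity_scores",
    "age_adjust",
    "covariation",
    "marker_abundance_score",
    "tf_activity_profile",
    "DEFAULT_MACROPHAGE_MARKERS",
]

DEFAULT_MACROPHAGE_MARKERS = ("CD163", "CD14", "TYROBP")


@dataclass
class ActivityProfile:
    """Raw and age-adjusted per-sample scores for one TF or marker set."""

    label: str
    raw: pd.Series  # per-sample mean member-gene z-score
    adjusted: pd.Series  # residual from raw ~ age


def zscore_genes(expr: ExpressionMatrix, gene_subset: list[str] | None = None) -> pd.DataFrame:
    """Per-gene z-scores across samples ((x − mean)/sd, sample sd with n−1).

    Zero-variance genes raise, naming the offenders, so the caller can drop
    them deliberately.
    """
    values = expr.values if gene_subset is None else expr.values.loc[gene_subset]
    arr = values.to_numpy(float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    zero = sd[:, 0] == 0
    if zero.any():
        bad = values.index[zero].tolist()
        raise ValueError(f"zero-variance genes cannot be z-scored: {bad[:10]}")
    return pd.DataFrame((arr - mean) / sd, index=values.index, columns=values.columns)


def activity_scores(z: pd.DataFrame, member_genes: list[str]) -> pd.Series:
    """Per-sample score: unweighted mean z over the member genes."""
    if not member_genes:
        raise ValueError("member gene set is empty")
    missing = [g for g in member_genes if g not in z.index]
    if missing:
        raise ValueError(f"member genes absent from z-matrix: {missing}")
    return z.loc[member_genes].mean(axis=0)


def age_adjust(scores: pd.Series, ages: pd.Series) -> pd.Series:
    """OLS residuals of score on intercept + age."""
    if len(scores) < 3:
        raise ValueError("need >= 3 samples")
    ages = ages.reindex(scores.index)
    a = ages.to_numpy(float)
    if np.ptp(a) == 0:
        raise ValueError("age is constant; cannot age-adjust")
    x = np.column_stack([np.ones_like(a), a])
    beta, *_ = np.linalg.lstsq(x, scores.to_numpy(float), rcond=None)
    resid = scores.to_numpy(float) - x @ beta
    return pd.Series(resid, index=scores.index)


def covariation(profiles: list[ActivityProfile]) -> tuple[pd.DataFrame, list[str], np.ndarray]:
    """Pairwise Pearson r of adjusted scores plus an average-linkage clustering.

    Distance is 1 − r. Returns (correlation matrix, leaf-order labels, the
    scipy linkage matrix). Profiles are ordered lexicographically by label
    before clustering so the leaf order is stable under input permutation.
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 profiles")
    profiles = sorted(profiles, key=lambda p: p.label)
    samples = list(profiles[0].adjusted.index)
    for p in profiles[1:]:
        if list(p.adjusted.index) != samples:
            raise ValueError(f"sample mismatch between profiles ({p.label})")
    mat = pd.DataFrame({p.label: p.adjusted for p in profiles})
    corr = mat.corr(method="pearson")
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    z = linkage(squareform(dist, checks=False), method="average")
    order = [corr.columns[i] for i in leaves_list(z)]
    return corr, order, z


def tf_activity_profile(
    expr: ExpressionMatrix, target_genes: list[str], label: str
) -> ActivityProfile:
    """Compose z-scoring, mean-score and age adjustment for one target set."""
    z = zscore_genes(expr, sorted(set(target_genes) & set(expr.values.index)))
    present = [g for g in target_genes if g in z.index]
    missing = sorted(set(target_genes) - set(present))
    if missing:
        raise ValueError(f"{label}: genes absent from matrix: {missing}")
    raw = activity_scores(z, present)
    adjusted = age_adjust(raw, expr.age)
    return ActivityProfile(label=label, raw=raw, adjusted=adjusted)


def marker_abundance_score(
    expr: ExpressionMatrix,
    marker_genes: tuple[str, ...] = DEFAULT_MACROPHAGE_MARKERS,
    label: str = "macrophage",
) -> ActivityProfile:
    """Cell-abundance proxy from marker transcripts (default macrophage set)."""
    return tf_activity_profile(expr, list(marker_genes), label)
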