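"""Core domain types shared by every stage of the pipeline.

All genomic coordinates are 0-based half-open (BED convention); TSS positions
are 0-based. Expression values are assumed normalized and on a log2 scale.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Peak",
    "PeakSet",
    "TSSRecord",
    "ExpressionMatrix",
    "DETable",
    "SNPAssocRecord",
]


@dataclass(frozen=True)
class Peak:
    """One ChIP-seq binding site.

    ``summit`` is the absolute genomic position of maximum read density;
    ``neg_log10_sig`` is the site significance as −log10(q or p).
    """

    chrom: str
    start: int
    end: int
    summit: int
    neg_log10_sig: float
    tf: str
    cell_line: str
    experiment_id: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start coordinate: {self.start}")
        if not self.start < self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")
        if not (self.start <= self.summit < self.end):
            raise ValueError(
                f"summit {self.summit} outside [{self.start}, {self.end})"
            )
        if self.neg_log10_sig < 0:
            raise ValueError("neg_log10_sig must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PeakSet:
    """Ordered collection of peaks from one experiment/file."""

    peaks: list[Peak]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = {p.experiment_id for p in self.peaks}
        if len(ids) > 1:
            raise ValueError(f"mixed experiment ids in one PeakSet: {sorted(ids)}")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def experiment_id(self) -> str | None:
        return self.peaks[0].experiment_id if self.peaks else None

    @property
    def tf(self) -> str | None:
        return self.peaks[0].tf if self.peaks else None

    @property
    def cell_line(self) -> str | None:
        return self.peaks[0].cell_line if self.peaks else None

    def sorted(self) -> "PeakSet":
        return PeakSet(
            sorted(self.peaks, key=lambda p: (p.chrom, p.start, p.end)),
            self.provenance,
        )


@dataclass(frozen=True)
class TSSRecord:
    """A gene's transcription start site."""

    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise ValueError("tss must be >= 0")


@dataclass
class ExpressionMatrix:
    """Genes × samples normalized log2 expression with sample metadata.

    ``age`` is per-sample chronological age in years; ``gfr`` (optional) is
    glomerular filtration rate in mL/min/1.73 m²; ``detection_p`` (optional)
    holds per-cell signal-detection p-values.
    """

    values: pd.DataFrame  # genes (rows) × samples (columns)
    age: pd.Series  # indexed by sample
    gfr: pd.Series | None = None
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        samples = list(self.values.columns)
        if list(self.age.index) != samples:
            self.age = self.age.reindex(samples)
        if self.age.isna().any():
            missing = self.age.index[self.age.isna()].tolist()
            raise ValueError(f"age missing for samples: {missing}")
        if (self.age <= 0).any():
            raise ValueError("ages must be > 0")
        if self.gfr is not None:
            self.gfr = self.gfr.reindex(samples)
            if self.gfr.isna().any():
                missing = self.gfr.index[self.gfr.isna()].tolist()
                raise ValueError(f"gfr missing for samples: {missing}")
        if self.detection_p is not None:
            if self.detection_p.shape != self.values.shape:
                raise ValueError("detection_p shape must match values")
            dp = self.detection_p.to_numpy()
            if np.nanmin(dp) < 0 or np.nanmax(dp) > 1:
                raise ValueError("detection_p must lie in [0, 1]")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(
            values=self.values.loc[genes],
            age=self.age,
            gfr=self.gfr,
            detection_p=None if self.detection_p is None else self.detection_p.loc[genes],
        )


def _as_detable(df: pd.DataFrame, perturbation: str) -> pd.DataFrame:
    required = {"gene_id", "log2fc", "p"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"DETable missing columns: {sorted(missing)}")
    out = df.copy()
    out["perturbation"] = perturbation
    bad = ~out["p"].between(0, 1) | ~np.isfinite(out["log2fc"])
    if bad.any():
        raise ValueError(f"invalid DETable rows: {out.index[bad].tolist()[:5]}")
    return out


@dataclass
class DETable:
    """Per-gene differential expression for one perturbation.

    Thin wrapper over a DataFrame with columns gene_id, log2fc, p.
    """

    table: pd.DataFrame
    perturbation: str = ""

    def __post_init__(self) -> None:
        self.table = _as_detable(self.table, self.perturbation)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def genes(self) -> list[str]:
        return self.table["gene_id"].tolist()

    def p_of(self) -> pd.Series:
        return self.table.set_index("gene_id")["p"]

    def log2fc_of(self) -> pd.Series:
        return self.table.set_index("gene_id")["log2fc"]


@dataclass(frozen=True)
class SNPAssocRecord:
    """SNP association summary for one variant within a candidate gene.

    ``p_by_phenotype`` maps a phenotype label (e.g. 'eGFR', 'CKD') to its
    association p-value; ``neg_log10_p_by_phenotype`` optionally carries the
    same information on a −log10 scale for p-values too small to represent
    in double precision.
    """

    snp_id: str
    gene: str
    p_by_phenotype: Mapping[str, float]
    major_allele: str
    minor_allele: str
    maf: float
    n_cases: int
    n_controls: int
    neg_log10_p_by_phenotype: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pheno, p in self.p_by_phenotype.items():
            if not (0 < p <= 1):
                raise ValueError(f"{self.snp_id}: p for {pheno} must be in (0,1], got {p}")
        if not (0 < self.maf <= 0.5):
            raise ValueError(f"{self.snp_id}: maf must be in (0, 0.5], got {self.maf}")
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError(f"{self.snp_id}: cohort sizes must be > 0")
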