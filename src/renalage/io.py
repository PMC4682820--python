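"""Readers and writers for the plain-text formats the pipeline consumes.

Peak files are ENCODE narrowPeak (BED6+4) or BED6 with a significance column;
expression and association tables are TSV. Significance columns follow the
narrowPeak convention of −log10-scaled p/q values; the q column is used when
it is present and ≥ 0, otherwise the p column.
"""
from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable

import pandas as pd

from .types import ExpressionMatrix, Peak, PeakSet, SNPAssocRecord, TSSRecord

__all__ = [
    "read_peaks",
    "write_peaks",
    "read_tss",
    "read_expression",
    "read_assoc",
]


def _parse_peak_line(
    fields: list[str], lineno: int, path: str, tf: str, cell_line: str, experiment_id: str
) -> tuple[Peak, float] | None:
    if len(fields) < 6:
        raise ValueError(f"{path}:{lineno}: expected >= 6 tab-separated fields, got {len(fields)}")
    try:
        chrom = fields[0]
        start = int(fields[1])
        end = int(fields[2])
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: malformed coordinates: {exc}") from None
    if start < 0 or end < 0:
        raise ValueError(f"{path}:{lineno}: negative coordinate")
    if len(fields) >= 10:
        # narrowPeak: signalValue pValue qValue peak
        try:
            neg_log10_p = float(fields[7])
            neg_log10_q = float(fields[8])
            offset = int(fields[9])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed narrowPeak columns: {exc}") from None
        sig = neg_log10_q if neg_log10_q >= 0 else neg_log10_p
    elif len(fields) >= 7:
        # BED6 + significance column (−log10 scaled)
        try:
            sig = float(fields[6])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed significance column: {exc}") from None
        offset = -1
    else:
        raise ValueError(f"{path}:{lineno}: no significance column (need narrowPeak or BED6+score)")
    if sig < 0:
        raise ValueError(f"{path}:{lineno}: both significance columns negative")
    summit = start + offset if offset >= 0 else (start + end) // 2
    peak = Peak(
        chrom=chrom,
        start=start,
        end=end,
        summit=summit,
        neg_log10_sig=sig,
        tf=tf,
        cell_line=cell_line,
        experiment_id=experiment_id,
    )
    return peak, sig


def read_peaks(
    path: str | Path,
    sig_threshold: float = 1e-5,
    min_length: int = 20,
    tf: str = "",
    cell_line: str = "",
    experiment_id: str | None = None,
) -> PeakSet:
    """Read a narrowPeak/BED peak file, applying significance and length filters.

    Peaks are retained when their −log10 significance is at least
    −log10(``sig_threshold``) (i.e. q or p < threshold, inclusive at the
    boundary of the −log10 scale) and their length is ≥ ``min_length`` bp.
    The summit is start + narrowPeak offset, or the interval midpoint (floor)
    when the offset is −1 or absent.
    """
    if not (0 < sig_threshold < 1):
        raise ValueError("sig_threshold must lie in (0, 1)")
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    path = Path(path)
    if experiment_id is None:
        experiment_id = path.stem
    min_sig = -math.log10(sig_threshold)
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            peak, sig = _parse_peak_line(fields, lineno, str(path), tf, cell_line, experiment_id)
            if sig >= min_sig and peak.length >= min_length:
                peaks.append(peak)
    return PeakSet(peaks, provenance=str(path))


def write_peaks(peakset: PeakSet, path: str | Path) -> None:
    """Write a PeakSet as narrowPeak (round-trips coordinates and significance)."""
    with open(path, "w") as fh:
        for p in peakset:
            offset = p.summit - p.start
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.experiment_id}\t0\t.\t0\t-1\t{p.neg_log10_sig!r}\t{offset}\n"
            )


def read_tss(path: str | Path) -> list[TSSRecord]:
    """Read a TSS table (gene_id, chrom, strand, tss; 0-based).

    Duplicate gene ids are kept: a gene may have several annotated TSS and
    peak assignment matches a gene if any of its TSS windows matches.
    """
    records: list[TSSRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene_id\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            try:
                records.append(TSSRecord(fields[0], fields[1], fields[2], int(fields[3])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return records


def write_tss(records: Iterable[TSSRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.chrom}\t{r.strand}\t{r.tss}\n")


def read_expression(
    matrix_path: str | Path,
    metadata_path: str | Path,
    detection_p_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read an expression TSV (genes × samples) plus sample metadata.

    The metadata file must have columns sample_id, age and optionally gfr;
    its rows are aligned to the matrix column order. Sample-id mismatches
    raise with the offending ids listed.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t")
    if "sample_id" not in meta.columns or "age" not in meta.columns:
        raise ValueError("metadata must have columns sample_id, age")
    meta = meta.set_index("sample_id")
    matrix_samples = set(values.columns)
    meta_samples = set(meta.index)
    if matrix_samples != meta_samples:
        missing = sorted(matrix_samples - meta_samples)
        extra = sorted(meta_samples - matrix_samples)
        raise ValueError(
            f"sample-id mismatch: missing from metadata {missing}; not in matrix {extra}"
        )
    meta = meta.reindex(values.columns)
    gfr = meta["gfr"].astype(float) if "gfr" in meta.columns else None
    detection_p = None
    if detection_p_path is not None:
        detection_p = pd.read_csv(detection_p_path, sep="\t", index_col=0)
        detection_p = detection_p.reindex(index=values.index, columns=values.columns)
    return ExpressionMatrix(values=values, age=meta["age"].astype(float), gfr=gfr, detection_p=detection_p)


_ASSOC_COLUMNS = ["snp_id", "gene", "p_egfr", "p_ckd", "major", "minor", "maf", "n_cases", "n_controls"]


def read_assoc(path: str | Path) -> list[SNPAssocRecord]:
    """Read a SNP association summary TSV (one record per row).

    Expected columns: snp_id, gene, p_egfr, p_ckd, major, minor, maf,
    n_cases, n_controls. Invariants (p ∈ (0,1], maf ∈ (0,0.5]) are enforced.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(_ASSOC_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"association table missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(
            SNPAssocRecord(
                snp_id=str(row["snp_id"]),
                gene=str(row["gene"]),
                p_by_phenotype={"eGFR": float(row["p_egfr"]), "CKD": float(row["p_ckd"])},
                major_allele=str(row["major"]),
                minor_allele=str(row["minor"]),
                maf=float(row["maf"]),
                n_cases=int(row["n_cases"]),
                n_controls=int(row["n_controls"]),
            )
        )
    return records
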