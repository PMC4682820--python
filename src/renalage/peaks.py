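"""Peak-to-gene assignment and binding-site complexity filtering.

A gene is a ChIP-seq target when a peak summit falls within the promoter
window 5 kb upstream to 2 kb downstream of any of its transcription start
sites (strand-aware, inclusive at both bounds). Binding-site complexity is
the number of distinct transcription factors with a significant site
overlapping a peak; high-complexity ("HOT") sites, which are not generally
responsive to any single factor, are filtered before the enrichment screen.
"""
from __future__ import annotations

import math
import warnings
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree

from .types import Peak, PeakSet, TSSRecord

__all__ = [
    "TargetMap",
    "assign_peaks_to_genes",
    "compute_complexity",
    "filter_by_complexity",
    "complexity_threshold",
]


@dataclass
class TargetMap:
    """Genes bound by one ChIP-seq experiment."""

    experiment_id: str
    tf: str
    cell_line: str
    targets: set[str] = field(default_factory=set)


def assign_peaks_to_genes(
    peaks: PeakSet,
    tss: list[TSSRecord],
    up: int = 5000,
    down: int = 2000,
) -> TargetMap:
    """Assign peaks to genes via strand-aware TSS windows.

    With d = summit − tss on the + strand and d = tss − summit on the −
    strand, a gene is a target iff −up ≤ d ≤ down for any of its TSS
    (inclusive at both bounds). Peaks on chromosomes absent from the
    annotation are skipped with a warning.
    """
    by_chrom: dict[str, list[TSSRecord]] = defaultdict(list)
    for rec in tss:
        by_chrom[rec.chrom].append(rec)
    # sorted summit arrays per chromosome for a windowed binary search
    chrom_arrays: dict[str, tuple[np.ndarray, list[TSSRecord]]] = {}
    for chrom, recs in by_chrom.items():
        recs = sorted(recs, key=lambda r: r.tss)
        chrom_arrays[chrom] = (np.array([r.tss for r in recs]), recs)

    targets: set[str] = set()
    skipped_chroms: set[str] = set()
    for peak in peaks:
        entry = chrom_arrays.get(peak.chrom)
        if entry is None:
            skipped_chroms.add(peak.chrom)
            continue
        positions, recs = entry
        # any TSS within `max(up, down)` of the summit is a candidate
        radius = max(up, down)
        lo = int(np.searchsorted(positions, peak.summit - radius, side="left"))
        hi = int(np.searchsorted(positions, peak.summit + radius, side="right"))
        for rec in recs[lo:hi]:
            d = peak.summit - rec.tss if rec.strand == "+" else rec.tss - peak.summit
            if -up <= d <= down:
                targets.add(rec.gene_id)
    if skipped_chroms:
        warnings.warn(
            f"peaks on chromosomes absent from annotation skipped: {sorted(skipped_chroms)}",
            stacklevel=2,
        )
    return TargetMap(
        experiment_id=peaks.experiment_id or "",
        tf=peaks.tf or "",
        cell_line=peaks.cell_line or "",
        targets=targets,
    )


def compute_complexity(all_peaksets: list[PeakSet]) -> dict[Peak, int]:
    """Per-peak complexity: distinct TFs with a site overlapping that peak.

    Overlap is ≥ 1 bp intersection of the half-open intervals. Sites of the
    same TF from multiple cell lines or replicates count once. Returns a map
    from each Peak to its complexity (the peak's own TF included).
    """
    if not all_peaksets or all(len(ps) == 0 for ps in all_peaksets):
        raise ValueError("compute_complexity requires at least one peak")
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for ps in all_peaksets:
        for p in ps:
            trees[p.chrom].addi(p.start, p.end, p.tf)
    complexity: dict[Peak, int] = {}
    for ps in all_peaksets:
        for p in ps:
            tfs = {iv.data for iv in trees[p.chrom].overlap(p.start, p.end)}
            tfs.add(p.tf)
            complexity[p] = len(tfs)
    return complexity


def complexity_threshold(n_tfs: int, max_fraction: float = 0.5) -> int:
    """Retention threshold: peaks bound by ≤ ceil(max_fraction · n_tfs) TFs.

    With the study compendium of 161 TFs and max_fraction 0.5 this is 81
    ("bound by 81 or fewer transcription factors").
    """
    if n_tfs <= 0:
        raise ValueError("n_tfs must be > 0")
    return math.ceil(max_fraction * n_tfs)


def filter_by_complexity(
    peaks: PeakSet,
    complexity: dict[Peak, int],
    n_tfs: int,
    max_fraction: float = 0.5,
) -> PeakSet:
    """Retain peaks whose complexity is at or below the compendium threshold."""
    thr = complexity_threshold(n_tfs, max_fraction)
    kept = [p for p in peaks if complexity[p] <= thr]
    return PeakSet(kept, provenance=peaks.provenance)
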