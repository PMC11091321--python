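"""Joins between peak geometry and orthogonal annotation layers.

Three joins recur in TF co-occupancy analyses and are implemented here:

* stratification of a peak set by histone-mark regions (H3K4me3 for
  promoter-proximal peaks, H3K27ac for distal peaks);
* the enhancer join, splitting distal peaks into those at known enhancer
  intervals (collecting target genes above an interaction-score cutoff)
  versus candidate novel enhancer sites;
* the differential-expression join, classifying each peak-associated gene
  as up, down, not significant, or untested at an FDR cutoff.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .core import GenomicInterval, PeakSet
from .annotation import _interval_index, _overlapping

__all__ = [
    "EnhancerRecord",
    "DifferentialExpressionRecord",
    "StratifiedPeaks",
    "stratify_by_mark",
    "enhancer_join",
    "deg_join",
    "read_enhancers",
    "write_enhancers",
    "read_de_table",
    "write_de_table",
]


@dataclass(frozen=True)
class EnhancerRecord:
    """One enhancer→target-gene link with its interaction score.

    An enhancer may target many genes; each (enhancer_id, target_gene) pair
    is one record.
    """

    interval: GenomicInterval
    enhancer_id: str
    target_gene: str
    interaction_score: float

    def __post_init__(self) -> None:
        if self.interaction_score < 0:
            raise ValueError("interaction_score must be non-negative")


@dataclass(frozen=True)
class DifferentialExpressionRecord:
    gene_id: str
    log2_fold_change: float
    adjusted_p: float

    def __post_init__(self) -> None:
        if not (0 <= self.adjusted_p <= 1):
            raise ValueError(f"adjusted_p outside [0,1] for {self.gene_id}")


@dataclass(frozen=True)
class StratifiedPeaks:
    in_mark: PeakSet
    out_of_mark: PeakSet
    mark_name: str
    fraction_in: float


def stratify_by_mark(peaks: PeakSet, mark_regions: PeakSet) -> StratifiedPeaks:
    """Split peaks by >= 1 bp overlap with any histone-mark region."""
    index = _interval_index([(p.interval, None) for p in mark_regions])
    inside, outside = [], []
    for p in peaks:
        (inside if _overlapping(index, p.interval) else outside).append(p)
    total = max(1, len(peaks))
    return StratifiedPeaks(
        in_mark=PeakSet(f"{peaks.name}_in_{mark_regions.name}", inside, peaks.genome),
        out_of_mark=PeakSet(f"{peaks.name}_out_{mark_regions.name}", outside, peaks.genome),
        mark_name=mark_regions.name,
        fraction_in=len(inside) / total,
    )


def enhancer_join(
    distal_peaks: PeakSet,
    enhancers: Sequence[EnhancerRecord],
    min_score: float = 10.0,
) -> tuple[PeakSet, PeakSet, set[str]]:
    """Split distal peaks into enhancer-annotated vs novel, collecting
    regulated genes.

    A peak is annotated iff it overlaps >= 1 enhancer interval (any score);
    the regulated-gene set is the distinct target genes of overlapped
    enhancer records with interaction_score strictly greater than
    ``min_score``.  Annotated + novel partition the input.
    """
    index = _interval_index([(e.interval, e) for e in enhancers])
    annotated, novel = [], []
    genes: set[str] = set()
    for p in distal_peaks:
        hits = _overlapping(index, p.interval)
        if hits:
            annotated.append(p)
            genes.update(
                e.target_gene for e in hits if e.interaction_score > min_score
            )
        else:
            novel.append(p)
    g = distal_peaks.genome
    return (
        PeakSet(f"{distal_peaks.name}_enhancer", annotated, g),
        PeakSet(f"{distal_peaks.name}_novel", novel, g),
        genes,
    )


def deg_join(
    peak_gene_map: Mapping[str, Sequence[str]],
    de_table: Sequence[DifferentialExpressionRecord],
    fdr: float = 0.05,
) -> dict[str, str]:
    """Classify each distinct peak-associated gene against a DE table.

    up:   adjusted_p < fdr and log2FC > 0
    down: adjusted_p < fdr and log2FC < 0
    ns:   tested but not significant (including padj exactly at the cutoff)
    untested: absent from the DE table

    Classification is per distinct gene, not per peak: a gene reached by
    many peaks is counted once.
    """
    if not (0 < fdr < 1):
        raise ValueError("fdr must be in (0, 1)")
    by_gene: dict[str, DifferentialExpressionRecord] = {}
    for rec in de_table:
        if rec.gene_id in by_gene:
            raise ValueError(f"duplicate gene_id in DE table: {rec.gene_id}")
        by_gene[rec.gene_id] = rec
    out: dict[str, str] = {}
    for genes in peak_gene_map.values():
        for g in genes:
            if g in out:
                continue
            rec = by_gene.get(g)
            if rec is None:
                out[g] = "untested"
            elif rec.adjusted_p < fdr and rec.log2_fold_change > 0:
                out[g] = "up"
            elif rec.adjusted_p < fdr and rec.log2_fold_change < 0:
                out[g] = "down"
            else:
                out[g] = "ns"
    return out


# ---------------------------------------------------------------------------
# I/O

_ENH_COLUMNS = ["chrom", "start", "end", "enhancer_id", "target_gene", "interaction_score"]


def read_enhancers(path: str | Path) -> list[EnhancerRecord]:
    """Read the enhancer TSV (chrom, start, end, enhancer_id, target_gene,
    interaction_score; one row per enhancer–gene link)."""
    out = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_ENH_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            out.append(
                EnhancerRecord(
                    interval=GenomicInterval(
                        row["chrom"], int(row["start"]), int(row["end"])
                    ),
                    enhancer_id=row["enhancer_id"],
                    target_gene=row["target_gene"],
                    interaction_score=float(row["interaction_score"]),
                )
            )
    return out


def write_enhancers(records: Iterable[EnhancerRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_ENH_COLUMNS)
        for e in records:
            w.writerow(
                [
                    e.interval.chrom,
                    e.interval.start,
                    e.interval.end,
                    e.enhancer_id,
                    e.target_gene,
                    f"{e.interaction_score:g}",
                ]
            )


def read_de_table(path: str | Path) -> list[DifferentialExpressionRecord]:
    """Read a DE results TSV with header columns gene_id, log2FoldChange,
    padj (extra columns ignored)."""
    out = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        needed = {"gene_id", "log2FoldChange", "padj"}
        missing = needed - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            out.append(
                DifferentialExpressionRecord(
                    gene_id=row["gene_id"],
                    log2_fold_change=float(row["log2FoldChange"]),
                    adjusted_p=float(row["padj"]),
                )
            )
    return out


def write_de_table(records: Iterable[DifferentialExpressionRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["gene_id", "log2FoldChange", "padj"])
        for r in records:
            w.writerow([r.gene_id, repr(r.log2_fold_change), repr(r.adjusted_p)])
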