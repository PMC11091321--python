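"""Peak-to-gene annotation: promoter windows, feature categories, TSS profiles.

Two promoter notions coexist and are both provided, because they answer
different questions:

* distance **bands** (midpoint within 1 / 2 / 3 kb upstream of the nearest
  TSS) drive the feature-category partition and its percentage breakdown;
* overlap **windows** (default 4 kb upstream to 1 kb downstream of the TSS)
  define "promoter peaks" for stratification and downstream joins.

Feature categories partition the peak set: every peak receives exactly one
category, by fixed precedence (promoter bands, then UTRs when the annotation
supplies them, then exon 1, other exons, intron 1, other introns, a 3-kb
downstream window, and finally distal intergenic).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .core import Genome, GenomicInterval, Peak, PeakSet

__all__ = [
    "GeneModel",
    "FeatureAssignment",
    "PromoterWindow",
    "FEATURE_CATEGORIES",
    "promoter_windows",
    "peaks_in_promoters",
    "assign_feature",
    "feature_distribution",
    "genes_near_peaks",
    "tss_profile",
    "read_gene_models",
    "write_gene_models",
    "read_gtf_gene_models",
]

#: Category precedence, highest first.  A peak gets the highest-precedence
#: category it qualifies for across all genes.
FEATURE_CATEGORIES: tuple[str, ...] = (
    "promoter_0_1kb",
    "promoter_1_2kb",
    "promoter_2_3kb",
    "five_utr",
    "three_utr",
    "exon_1",
    "other_exon",
    "intron_1",
    "other_intron",
    "downstream",
    "distal_intergenic",
)

_PRECEDENCE = {c: i for i, c in enumerate(FEATURE_CATEGORIES)}


@dataclass(frozen=True)
class GeneModel:
    """A gene body with strand-aware TSS and ordered exons.

    ``tss`` is the 5' end: ``span.start`` on the + strand, ``span.end - 1``
    on the - strand.  Exons are stored in 5'→3' transcription order and must
    lie within the span without overlapping each other.
    """

    gene_id: str
    chrom: str
    strand: str
    span: GenomicInterval
    exons: tuple[GenomicInterval, ...] = ()
    gene_name: str | None = None
    biotype: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r} for {self.gene_id}")
        for ex in self.exons:
            if ex.start < self.span.start or ex.end > self.span.end:
                raise ValueError(f"exon outside span in {self.gene_id}")
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping exons in {self.gene_id}")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if tuple(expected) != tuple(self.exons):
            raise ValueError(f"exons of {self.gene_id} not in 5'->3' order")

    @property
    def tss(self) -> int:
        return self.span.start if self.strand == "+" else self.span.end - 1

    @property
    def tes(self) -> int:
        """3' end position (last transcribed base)."""
        return self.span.end - 1 if self.strand == "+" else self.span.start

    def introns(self) -> tuple[GenomicInterval, ...]:
        """Regions between consecutive exons, in 5'→3' order; intron k sits
        between exon k and exon k+1."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            lo, hi = (a.end, b.start) if self.strand == "+" else (b.end, a.start)
            if hi > lo:
                out.append(GenomicInterval(self.chrom, lo, hi))
        return tuple(out)


@dataclass(frozen=True)
class FeatureAssignment:
    """One peak's genomic category and associated gene (null iff distal)."""

    peak_id: str
    category: str
    gene_id: str | None

    def __post_init__(self) -> None:
        if self.category not in _PRECEDENCE:
            raise ValueError(f"unknown category {self.category!r}")
        if (self.gene_id is None) != (self.category == "distal_intergenic"):
            raise ValueError("gene_id must be null iff category is distal_intergenic")


@dataclass(frozen=True)
class PromoterWindow:
    gene_id: str
    interval: GenomicInterval


def _window_interval(
    gene: GeneModel, upstream: int, downstream: int, genome: Genome | None
) -> GenomicInterval | None:
    """Strand-aware promoter window, clipped to chromosome bounds.

    + strand: [tss - upstream, tss + downstream); - strand mirrored so that
    the window covers `upstream` bases 5' of the TSS and `downstream` bases
    into the gene, TSS base included on both strands.
    """
    if gene.strand == "+":
        lo, hi = gene.tss - upstream, gene.tss + downstream
    else:
        lo, hi = gene.tss - downstream + 1, gene.tss + upstream + 1
    lo = max(lo, 0)
    if genome is not None and gene.chrom in genome:
        hi = min(hi, genome.chrom_sizes[gene.chrom])
    if hi <= lo:
        return None
    return GenomicInterval(gene.chrom, lo, hi)


def promoter_windows(
    genes: Iterable[GeneModel],
    upstream: int = 4000,
    downstream: int = 1000,
    genome: Genome | None = None,
) -> list[PromoterWindow]:
    """Promoter windows around each TSS (defaults: 4 kb upstream, 1 kb down)."""
    if upstream < 0 or downstream < 0 or (upstream == 0 and downstream == 0):
        raise ValueError("upstream/downstream must be >= 0 and not both zero")
    out = []
    for g in genes:
        iv = _window_interval(g, upstream, downstream, genome)
        if iv is not None:
            out.append(PromoterWindow(g.gene_id, iv))
    return out


def _interval_index(
    intervals: Sequence[tuple[GenomicInterval, object]],
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, list]]:
    """Per-chrom (starts, ends, prefix-max-end, payloads) sorted by start."""
    by: dict[str, list[tuple[GenomicInterval, object]]] = {}
    for iv, payload in intervals:
        by.setdefault(iv.chrom, []).append((iv, payload))
    out = {}
    for chrom, items in by.items():
        items.sort(key=lambda t: (t[0].start, t[0].end))
        starts = np.array([iv.start for iv, _ in items], dtype=np.int64)
        ends = np.array([iv.end for iv, _ in items], dtype=np.int64)
        out[chrom] = (starts, ends, np.maximum.accumulate(ends), [p for _, p in items])
    return out


def _overlapping(index, iv: GenomicInterval) -> list:
    """Payloads of indexed intervals sharing >= 1 base with ``iv``."""
    if iv.chrom not in index:
        return []
    starts, ends, _, payloads = index[iv.chrom]
    hi = int(np.searchsorted(starts, iv.end, side="left"))
    if hi == 0:
        return []
    hit = np.nonzero(ends[:hi] > iv.start)[0]
    return [payloads[j] for j in hit]


def peaks_in_promoters(
    peaks: PeakSet,
    genes: Iterable[GeneModel],
    upstream: int = 4000,
    downstream: int = 1000,
) -> tuple[PeakSet, dict[str, list[str]]]:
    """Peaks overlapping >= 1 promoter window, with the peak→gene multimap.

    A promoter may contain several peaks and a peak may hit several
    promoters; the multimap records every overlapped gene.
    """
    windows = promoter_windows(genes, upstream, downstream, peaks.genome)
    index = _interval_index([(w.interval, w.gene_id) for w in windows])
    mapping: dict[str, list[str]] = {}
    keep: list[Peak] = []
    for p in peaks:
        gids = sorted(set(_overlapping(index, p.interval)))
        if gids:
            keep.append(p)
            mapping[p.id] = gids
    return PeakSet(f"{peaks.name}_promoter", keep, peaks.genome), mapping


def _upstream_offset(mid: int, gene: GeneModel) -> int:
    """Signed strand-aware offset of ``mid`` from the TSS; positive upstream."""
    return gene.tss - mid if gene.strand == "+" else mid - gene.tss


def assign_feature(
    peaks: PeakSet,
    genes: Sequence[GeneModel],
    band_edges: Sequence[int] = (1000, 2000, 3000),
    downstream_extent: int = 3000,
) -> list[FeatureAssignment]:
    """Assign each peak exactly one genomic feature category.

    Promoter bands are decided by the peak *midpoint*: a midpoint within
    ``band_edges[k-1]..band_edges[k]`` bases upstream of its nearest TSS
    falls in band k (so the bands partition 0-3 kb upstream by default).
    Gene-body categories (UTRs when annotated, exon 1, other exons, intron 1,
    other introns) and the 3-kb downstream window use >= 1 bp overlap.
    Among genes the highest-precedence category wins; ties break by nearest
    TSS, then lexicographic gene id.  Peaks matching nothing are distal
    intergenic with a null gene.
    """
    genes = list(genes)
    # candidate gene index over the widest reach any category can have
    reach = max(int(band_edges[-1]), downstream_extent)
    padded = []
    for g in genes:
        lo = max(0, g.span.start - reach)
        hi = g.span.end + reach
        padded.append((GenomicInterval(g.chrom, lo, hi), g))
    index = _interval_index(padded)

    out: list[FeatureAssignment] = []
    for p in peaks:
        mid = p.interval.midpoint
        best: tuple[int, int, str, str] | None = None  # (precedence, |tss dist|, gene_id, category)
        for g in _overlapping(index, p.interval):
            cat = _categorize_for_gene(p.interval, mid, g, band_edges, downstream_extent)
            if cat is None:
                continue
            key = (_PRECEDENCE[cat], abs(mid - g.tss), g.gene_id, cat)
            if best is None or key[:3] < best[:3]:
                best = key
        if best is None:
            out.append(FeatureAssignment(p.id, "distal_intergenic", None))
        else:
            out.append(FeatureAssignment(p.id, best[3], best[2]))
    return out


def _categorize_for_gene(
    iv: GenomicInterval,
    mid: int,
    gene: GeneModel,
    band_edges: Sequence[int],
    downstream_extent: int,
) -> str | None:
    """Highest-precedence category this peak qualifies for w.r.t. one gene."""
    if gene.chrom != iv.chrom:
        return None
    up = _upstream_offset(mid, gene)
    if 0 <= up < band_edges[0]:
        return "promoter_0_1kb"
    if band_edges[0] <= up < band_edges[1]:
        return "promoter_1_2kb"
    if band_edges[1] <= up < band_edges[2]:
        return "promoter_2_3kb"
    if iv.start < gene.span.end and gene.span.start < iv.end:
        # inside the gene body: exons outrank introns, first outranks rest
        for k, ex in enumerate(gene.exons):
            if iv.start < ex.end and ex.start < iv.end:
                return "exon_1" if k == 0 else "other_exon"
        for k, intron in enumerate(gene.introns()):
            if iv.start < intron.end and intron.start < iv.end:
                return "intron_1" if k == 0 else "other_intron"
        # body overlap without exon/intron hit (single-exon edge cases)
        return "other_exon" if gene.exons else "intron_1"
    # downstream: within `downstream_extent` past the 3' end
    if gene.strand == "+":
        lo, hi = gene.span.end, gene.span.end + downstream_extent
    else:
        lo, hi = max(0, gene.span.start - downstream_extent), gene.span.start
    if hi > lo and iv.start < hi and lo < iv.end:
        return "downstream"
    return None


def feature_distribution(assignments: Iterable[FeatureAssignment]) -> dict[str, float]:
    """Percentage of peaks per category; sums to 100 within rounding."""
    assignments = list(assignments)
    if not assignments:
        raise ValueError("feature_distribution of empty assignment list")
    counts: dict[str, int] = {c: 0 for c in FEATURE_CATEGORIES}
    for a in assignments:
        counts[a.category] += 1
    n = len(assignments)
    return {c: 100.0 * k / n for c, k in counts.items()}


def genes_near_peaks(
    peaks: PeakSet, genes: Sequence[GeneModel], max_dist: int = 5000
) -> dict[str, list[str]]:
    """Peak→gene multimap: gene associated iff the gap between the peak and
    the gene span is <= ``max_dist`` bp (0 when they overlap)."""
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    # Overlap with the span padded by max_dist + 1 is exactly "gap <= max_dist"
    # under half-open coordinates (a gap of exactly max_dist still counts).
    pad = max_dist + 1
    padded = [
        (
            GenomicInterval(g.chrom, max(0, g.span.start - pad), g.span.end + pad),
            g.gene_id,
        )
        for g in genes
    ]
    index = _interval_index(padded)
    out: dict[str, list[str]] = {}
    for p in peaks:
        gids = sorted(set(_overlapping(index, p.interval)))
        if gids:
            out[p.id] = gids
    return out


def tss_profile(
    peaks: PeakSet,
    genes: Sequence[GeneModel],
    flank: int = 3000,
    step: int = 50,
    fraction: bool = False,
) -> np.ndarray:
    """Occupancy around TSSs: for each strand-oriented ``step``-bp offset bin
    in ``[-flank, +flank)``, the number (or fraction) of TSSs whose bin is
    covered by >= 1 peak.  Bin 0 of the vector is the most upstream.
    """
    if flank <= 0 or step < 1 or flank % step:
        raise ValueError("need flank > 0, step >= 1, flank divisible by step")
    nbins = 2 * flank // step
    index = _interval_index([(p.interval, None) for p in peaks])
    counts = np.zeros(nbins, dtype=np.int64)
    for g in genes:
        for j in range(nbins):
            off_lo = -flank + j * step
            off_hi = off_lo + step
            if g.strand == "+":
                lo, hi = g.tss + off_lo, g.tss + off_hi
            else:
                lo, hi = g.tss - off_hi + 1, g.tss - off_lo + 1
            if hi <= 0:
                continue
            if _overlapping(index, GenomicInterval(g.chrom, max(lo, 0), hi)):
                counts[j] += 1
    if fraction:
        n = max(1, len(list(genes)))
        return counts / n
    return counts


# ---------------------------------------------------------------------------
# Gene-model I/O

_GM_COLUMNS = [
    "gene_id",
    "gene_name",
    "chrom",
    "strand",
    "start",
    "end",
    "exon_starts",
    "exon_ends",
    "biotype",
]


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read the gene-model TSV (columns: gene_id, gene_name, chrom, strand,
    start, end, exon_starts, exon_ends, biotype; exon lists comma-separated
    in genomic order)."""
    genes = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_GM_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            chrom = row["chrom"]
            span = GenomicInterval(chrom, int(row["start"]), int(row["end"]))
            ex_s = [int(x) for x in row["exon_starts"].split(",") if x]
            ex_e = [int(x) for x in row["exon_ends"].split(",") if x]
            exons = [GenomicInterval(chrom, s, e) for s, e in zip(ex_s, ex_e)]
            if row["strand"] == "-":
                exons = exons[::-1]
            genes.append(
                GeneModel(
                    gene_id=row["gene_id"],
                    gene_name=row["gene_name"] or None,
                    chrom=chrom,
                    strand=row["strand"],
                    span=span,
                    exons=tuple(exons),
                    biotype=row["biotype"] or None,
                )
            )
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_GM_COLUMNS)
        for g in genes:
            genomic = sorted(g.exons, key=lambda e: e.start)
            w.writerow(
                [
                    g.gene_id,
                    g.gene_name or "",
                    g.chrom,
                    g.strand,
                    g.span.start,
                    g.span.end,
                    ",".join(str(e.start) for e in genomic),
                    ",".join(str(e.end) for e in genomic),
                    g.biotype or "",
                ]
            )


def read_gtf_gene_models(path: str | Path) -> list[GeneModel]:
    """Build gene models from a GTF: gene records give spans, exon records
    grouped by ``gene_id`` give exon structure.  GTF is 1-based inclusive on
    disk; coordinates are converted to 0-based half-open."""
    spans: dict[str, tuple[str, str, int, int, str | None, str | None]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            chrom, _, feat, start, end, _, strand, _, attrs = f[:9]
            attr = _parse_gtf_attrs(attrs)
            gid = attr.get("gene_id")
            if gid is None:
                continue
            s0, e0 = int(start) - 1, int(end)
            if feat == "gene":
                spans[gid] = (
                    chrom,
                    strand,
                    s0,
                    e0,
                    attr.get("gene_name"),
                    attr.get("gene_biotype") or attr.get("gene_type"),
                )
            elif feat == "exon":
                exons.setdefault(gid, []).append((s0, e0))
    genes = []
    for gid, (chrom, strand, s0, e0, name, biotype) in spans.items():
        ex = sorted(set(exons.get(gid, [])))
        ivs = [GenomicInterval(chrom, a, b) for a, b in ex]
        if strand == "-":
            ivs = ivs[::-1]
        genes.append(
            GeneModel(
                gene_id=gid,
                gene_name=name,
                chrom=chrom,
                strand=strand,
                span=GenomicInterval(chrom, s0, e0),
                exons=tuple(ivs),
                biotype=biotype,
            )
        )
    return genes


def _parse_gtf_attrs(attrs: str) -> dict[str, str]:
    out = {}
    for part in attrs.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if " " in part:
            k, v = part.split(" ", 1)
            out[k] = v.strip().strip('"')
    return out
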