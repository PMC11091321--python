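"""Synthetic genomes, gene models, co-bound peak sets, histone-mark domains,
enhancer tables and DE tables, with recorded ground truth.

The generator emulates the statistical structure of a two-factor ChIP-seq
co-occupancy study: set A plays the role of the reference factor (WT1-like),
set B the competing factor (AR-like), with a controlled fraction of B peaks
planted to overlap A peaks by >= 1 bp and the remainder placed rejecting any
A overlap — so the realized cross-set overlap fraction is exact by
construction.  Promoter-mark domains (H3K4me3-like) cover a stated fraction
of promoter windows; distal-mark domains (H3K27ac-like) cover a stated
fraction of intergenic space.  The DE table plants up/down/ns labels on
peak-target genes at stated fractions.  Every draw comes from one explicit
`numpy.random.Generator` per call; there is no global random state.

Default parameter values are set to a realistic endometrial two-factor
regime: 654-bp mean peak length, 7% cross-set overlap, about a third of
peaks promoter-biased, 77.6% / 16.1% promoter / distal mark coverage, and
roughly 11% / 16% of target genes up- / down-regulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import Genome, GenomicInterval, Peak, PeakSet, write_bed, write_chrom_sizes
from .annotation import GeneModel, promoter_windows, write_gene_models
from .integrate import (
    DifferentialExpressionRecord,
    EnhancerRecord,
    write_de_table,
    write_enhancers,
)

__all__ = [
    "SyntheticTruth",
    "simulate_genome",
    "simulate_peaks",
    "simulate_cobound_peaks",
    "simulate_annotated_peaks",
    "simulate_marks",
    "simulate_enhancers",
    "simulate_de",
    "write_bundle",
]

_MIN_PEAK_LEN = 50
_GENE_SPACING = 10_000


@dataclass
class SyntheticTruth:
    """Ground-truth generator parameters recorded for recovery tests.

    rho is the intended fraction of B peaks overlapping A; the mark
    coverages are fractions of promoter windows / intergenic space carrying
    a histone domain; the DE fractions are the fractions of peak-target
    genes planted as up- / down-regulated.
    """

    rho: float = 0.07
    peak_length_mean: float = 654.0
    peak_length_sd: float = 150.0
    promoter_bias: float = 0.34
    mark_promoter_cov: float = 0.776
    mark_distal_cov: float = 0.161
    de_target_up_frac: float = 0.112
    de_target_down_frac: float = 0.157
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = {
            "rho": self.rho,
            "promoter_bias": self.promoter_bias,
            "mark_promoter_cov": self.mark_promoter_cov,
            "mark_distal_cov": self.mark_distal_cov,
            "de_target_up_frac": self.de_target_up_frac,
            "de_target_down_frac": self.de_target_down_frac,
        }
        bad = {k: v for k, v in fracs.items() if not 0 <= v <= 1}
        if bad:
            raise ValueError(f"fractions outside [0,1]: {bad}")
        if self.de_target_up_frac + self.de_target_down_frac > 1:
            raise ValueError("de_target_up_frac + de_target_down_frac > 1")


def simulate_genome(
    n_chrom: int = 1,
    chrom_length: int = 10_000_000,
    n_genes: int = 200,
    seed: int = 0,
) -> tuple[Genome, list[GeneModel]]:
    """Place ``n_genes`` non-overlapping genes (>= 10 kb apart) with random
    strand and 2-8 exons each, uniformly spread over ``n_chrom`` equal
    chromosomes.  Deterministic given the seed."""
    rng = np.random.default_rng(seed)
    sizes = {f"chr{i + 1}": chrom_length for i in range(n_chrom)}
    genome = Genome(sizes, assembly_label="synthetic")
    per_chrom = [n_genes // n_chrom + (1 if i < n_genes % n_chrom else 0) for i in range(n_chrom)]
    genes: list[GeneModel] = []
    gid = 0
    for ci, (chrom, k) in enumerate(zip(sizes, per_chrom)):
        if k == 0:
            continue
        lengths = rng.integers(2_000, 20_001, size=k)
        needed = int(lengths.sum()) + (k + 1) * _GENE_SPACING
        if needed > chrom_length:
            raise ValueError(
                f"cannot place {k} genes with {_GENE_SPACING} bp spacing on a "
                f"{chrom_length} bp chromosome (need {needed} bp)"
            )
        free = chrom_length - needed
        extra = rng.multinomial(free, np.full(k + 1, 1 / (k + 1)))
        pos = 0
        for j in range(k):
            pos += _GENE_SPACING + int(extra[j])
            start, length = pos, int(lengths[j])
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                _make_gene(f"G{gid:04d}", chrom, strand, start, start + length, rng)
            )
            gid += 1
            pos += length
    genes.sort(key=lambda g: (g.chrom, g.span.start))
    return genome, genes


def _make_gene(gene_id, chrom, strand, start, end, rng) -> GeneModel:
    n_ex = int(rng.integers(2, 9))
    length = end - start
    # 2*n_ex - 1 alternating exon/intron segments, each >= 1 bp; exons at
    # both gene ends
    cuts = np.sort(rng.choice(np.arange(1, length), size=2 * n_ex - 2, replace=False))
    bounds = np.concatenate([[0], cuts, [length]])
    exons = [
        GenomicInterval(chrom, start + int(bounds[i]), start + int(bounds[i + 1]))
        for i in range(0, 2 * n_ex - 1, 2)
    ]
    if strand == "-":
        exons = exons[::-1]
    biotype = rng.choice(["mRNA", "lncRNA", "miRNA"], p=[0.85, 0.1, 0.05])
    return GeneModel(
        gene_id=gene_id,
        gene_name=gene_id,
        chrom=chrom,
        strand=strand,
        span=GenomicInterval(chrom, start, end),
        exons=tuple(exons),
        biotype=str(biotype),
    )


def _draw_lengths(rng, n, mean, sd) -> np.ndarray:
    """Peak lengths: normal truncated below at the minimum peak length."""
    return np.maximum(np.round(rng.normal(mean, sd, n)), _MIN_PEAK_LEN).astype(np.int64)


def _chrom_choice(rng, genome: Genome, n: int) -> list[str]:
    chroms = list(genome.chrom_sizes)
    w = np.array([genome.chrom_sizes[c] for c in chroms], dtype=float)
    idx = rng.choice(len(chroms), size=n, p=w / w.sum())
    return [chroms[i] for i in idx]


def simulate_peaks(
    genome: Genome,
    n: int,
    name: str,
    seed: int,
    length_mean: float = 654.0,
    length_sd: float = 150.0,
) -> PeakSet:
    """``n`` peaks placed independently and uniformly over the genome —
    the null configuration for calibration studies."""
    rng = np.random.default_rng(seed)
    lengths = _draw_lengths(rng, n, length_mean, length_sd)
    chroms = _chrom_choice(rng, genome, n)
    peaks = []
    for i, (c, l) in enumerate(zip(chroms, lengths)):
        start = int(rng.integers(0, genome.chrom_sizes[c] - l))
        peaks.append(Peak(GenomicInterval(c, start, start + int(l)), f"{name}_{i}"))
    return PeakSet(name, peaks, genome)


def _overlaps_any(chrom, start, end, by_chrom) -> bool:
    if chrom not in by_chrom:
        return False
    starts, ends = by_chrom[chrom]
    return bool(np.any((starts < end) & (ends > start)))


def simulate_cobound_peaks(
    genome: Genome,
    genes: Sequence[GeneModel],
    n_a: int,
    n_b: int,
    truth: SyntheticTruth,
    name_a: str = "A",
    name_b: str = "B",
    max_tries: int = 1000,
) -> tuple[PeakSet, PeakSet, dict]:
    """Two peak sets with an exact planted cross-set overlap fraction.

    Set A: ``round(promoter_bias * n_a)`` peaks centred inside promoter
    windows (4 kb upstream / 1 kb downstream of a random TSS), the rest
    uniform.  Set B: ``round(rho * n_b)`` peaks placed to overlap a random
    A peak by >= 1 bp; the remainder placed by rejection so that they
    overlap no A peak.  The returned ledger records each B peak's intended
    overlap status, so ``overlap_fraction(B, A)`` equals
    ``round(rho * n_b) / n_b`` exactly.
    """
    rng = np.random.default_rng(truth.seed)
    windows = promoter_windows(genes, 4000, 1000, genome)

    n_prom = round(truth.promoter_bias * n_a)
    a_peaks: list[Peak] = []
    lengths = _draw_lengths(rng, n_a, truth.peak_length_mean, truth.peak_length_sd)
    for i in range(n_a):
        l = int(lengths[i])
        if i < n_prom and windows:
            w = windows[int(rng.integers(0, len(windows)))].interval
            mid = int(rng.integers(w.start, w.end))
            start = max(0, min(mid - l // 2, genome.chrom_sizes[w.chrom] - l))
            chrom = w.chrom
        else:
            chrom = _chrom_choice(rng, genome, 1)[0]
            start = int(rng.integers(0, genome.chrom_sizes[chrom] - l))
        a_peaks.append(Peak(GenomicInterval(chrom, start, start + l), f"{name_a}_{i}"))
    set_a = PeakSet(name_a, a_peaks, genome)

    a_by_chrom = {
        c: (s.copy(), e.copy()) for c, (s, e, _) in set_a.by_chrom().items()
    }
    n_over = round(truth.rho * n_b)
    b_peaks: list[Peak] = []
    intended: dict[str, bool] = {}
    b_lengths = _draw_lengths(rng, n_b, truth.peak_length_mean, truth.peak_length_sd)
    for i in range(n_b):
        l = int(b_lengths[i])
        pid = f"{name_b}_{i}"
        if i < n_over:
            for _ in range(max_tries):
                a = a_peaks[int(rng.integers(0, n_a))]
                lo = max(0, a.start - l + 1)
                hi = min(a.end - 1, genome.chrom_sizes[a.chrom] - l)
                if hi < lo:
                    continue
                start = int(rng.integers(lo, hi + 1))
                if start < a.end and a.start < start + l:
                    break
            else:
                raise RuntimeError(
                    "could not plant an overlapping B peak; genome too small "
                    "for the requested peak lengths"
                )
            b_peaks.append(Peak(GenomicInterval(a.chrom, start, start + l), pid))
            intended[pid] = True
        else:
            for _ in range(max_tries):
                chrom = _chrom_choice(rng, genome, 1)[0]
                start = int(rng.integers(0, genome.chrom_sizes[chrom] - l))
                if not _overlaps_any(chrom, start, start + l, a_by_chrom):
                    break
            else:
                raise RuntimeError(
                    "rejection sampling of non-overlapping B peaks exceeded "
                    f"{max_tries} tries; lower the peak density"
                )
            b_peaks.append(Peak(GenomicInterval(chrom, start, start + l), pid))
            intended[pid] = False
    set_b = PeakSet(name_b, b_peaks, genome)
    ledger = {
        "n_a": n_a,
        "n_b": n_b,
        "n_b_planted_overlap": n_over,
        "expected_overlap_fraction_b_on_a": n_over / n_b if n_b else 0.0,
        "b_intended_overlap": intended,
    }
    return set_a, set_b, ledger


def _distal_segments(
    genome: Genome, genes: Sequence[GeneModel], pad: int
) -> dict[str, list[tuple[int, int]]]:
    """Complement of the gene spans padded by ``pad`` bp on each side."""
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, length in genome.chrom_sizes.items():
        spans = sorted(
            (max(0, g.span.start - pad), min(length, g.span.end + pad))
            for g in genes
            if g.chrom == chrom
        )
        segs, pos = [], 0
        for s, e in spans:
            if s > pos:
                segs.append((pos, s))
            pos = max(pos, e)
        if pos < length:
            segs.append((pos, length))
        out[chrom] = segs
    return out


def _sample_in_segments(rng, segs_by_chrom, length) -> GenomicInterval | None:
    flat = [
        (chrom, s, e)
        for chrom, segs in segs_by_chrom.items()
        for s, e in segs
        if e - s >= length
    ]
    if not flat:
        return None
    w = np.array([e - s - length + 1 for _, s, e in flat], dtype=float)
    chrom, s, e = flat[int(rng.choice(len(flat), p=w / w.sum()))]
    start = int(rng.integers(s, e - length + 1))
    return GenomicInterval(chrom, start, start + length)


def simulate_annotated_peaks(
    genome: Genome,
    genes: Sequence[GeneModel],
    n_per_category: int = 10,
    seed: int = 0,
    max_tries: int = 2000,
) -> tuple[PeakSet, dict[str, str]]:
    """Peaks placed so that each has a known intended feature category,
    for annotation-recovery tests.  Covers the promoter bands, exon 1,
    other exons, intron 1, other introns, downstream and distal intergenic
    (UTR categories require UTR-aware annotation and are not placed)."""
    rng = np.random.default_rng(seed)
    categories = [
        "promoter_0_1kb",
        "promoter_1_2kb",
        "promoter_2_3kb",
        "exon_1",
        "other_exon",
        "intron_1",
        "other_intron",
        "downstream",
        "distal_intergenic",
    ]
    distal = _distal_segments(genome, genes, pad=4000)
    peaks, truth = [], {}
    counter = 0
    for cat in categories:
        for _ in range(n_per_category):
            iv = _place_in_category(rng, genome, genes, cat, distal, max_tries)
            pid = f"P_{counter:04d}"
            counter += 1
            peaks.append(Peak(iv, pid))
            truth[pid] = cat
    return PeakSet("placed", peaks, genome), truth


def _place_in_category(rng, genome, genes, cat, distal_segs, max_tries) -> GenomicInterval:
    bands = {"promoter_0_1kb": (0, 1000), "promoter_1_2kb": (1000, 2000), "promoter_2_3kb": (2000, 3000)}
    for _ in range(max_tries):
        l = int(rng.integers(150, 501))
        if cat in bands:
            g = genes[int(rng.integers(0, len(genes)))]
            lo, hi = bands[cat]
            u = int(rng.integers(lo, hi))
            mid = g.tss - u if g.strand == "+" else g.tss + u
            start = mid - l // 2
            if start < 0 or start + l > genome.chrom_sizes[g.chrom]:
                continue
            return GenomicInterval(g.chrom, start, start + l)
        if cat in ("exon_1", "other_exon", "intron_1", "other_intron"):
            g = genes[int(rng.integers(0, len(genes)))]
            if cat in ("exon_1", "other_exon"):
                pool = [g.exons[0]] if cat == "exon_1" else list(g.exons[1:])
            else:
                introns = g.introns()
                pool = [introns[0]] if (cat == "intron_1" and introns) else list(introns[1:])
            pool = [iv for iv in pool if iv.length >= l + 2]
            if not pool:
                continue
            host = pool[int(rng.integers(0, len(pool)))]
            start = int(rng.integers(host.start + 1, host.end - l))
            iv = GenomicInterval(g.chrom, start, start + l)
            # the midpoint must sit inside the gene body, past the TSS, so
            # no promoter band can outrank the intended category
            mid = iv.midpoint
            u = g.tss - mid if g.strand == "+" else mid - g.tss
            if u >= 0:
                continue
            return iv
        if cat == "downstream":
            g = genes[int(rng.integers(0, len(genes)))]
            if g.strand == "+":
                lo, hi = g.span.end, min(g.span.end + 3000, genome.chrom_sizes[g.chrom])
            else:
                lo, hi = max(0, g.span.start - 3000), g.span.start
            if hi - lo < l + 2:
                continue
            start = int(rng.integers(lo + 1, hi - l))
            return GenomicInterval(g.chrom, start, start + l)
        if cat == "distal_intergenic":
            iv = _sample_in_segments(rng, distal_segs, l)
            if iv is not None:
                return iv
            continue
        raise ValueError(f"unknown category {cat!r}")
    raise RuntimeError(f"could not place a peak of category {cat} in {max_tries} tries")


def simulate_marks(
    genome: Genome,
    genes: Sequence[GeneModel],
    truth: SyntheticTruth,
    name_promoter: str = "H3K4me3",
    name_distal: str = "H3K27ac",
) -> tuple[PeakSet, PeakSet]:
    """Histone-mark domains: the promoter mark covers a ``mark_promoter_cov``
    fraction of promoter windows (one full-window domain per chosen gene);
    the distal mark covers a ``mark_distal_cov`` fraction of intergenic
    space with 500-5000 bp domains."""
    rng = np.random.default_rng(truth.seed + 1)
    windows = promoter_windows(genes, 4000, 1000, genome)
    n_marked = round(truth.mark_promoter_cov * len(windows))
    chosen = rng.choice(len(windows), size=n_marked, replace=False)
    prom_peaks = [
        Peak(windows[int(i)].interval, f"{name_promoter}_{j}")
        for j, i in enumerate(sorted(chosen))
    ]
    prom = PeakSet(name_promoter, prom_peaks, genome)

    segs = _distal_segments(genome, genes, pad=4000)
    total_distal = sum(e - s for ss in segs.values() for s, e in ss)
    target = truth.mark_distal_cov * total_distal
    placed: list[Peak] = []
    covered = 0
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    tries = 0
    while covered < target and tries < 100_000:
        tries += 1
        l = int(rng.integers(500, 5001))
        iv = _sample_in_segments(rng, segs, l)
        if iv is None:
            break
        s, e = by_chrom.get(iv.chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))
        if s.size and np.any((s < iv.end) & (e > iv.start)):
            continue  # keep domains disjoint so coverage adds up exactly
        placed.append(Peak(iv, f"{name_distal}_{len(placed)}"))
        by_chrom[iv.chrom] = (np.append(s, iv.start), np.append(e, iv.end))
        covered += iv.length
    dist = PeakSet(name_distal, placed, genome)
    return prom, dist


def simulate_enhancers(
    genome: Genome,
    genes: Sequence[GeneModel],
    n_enhancers: int = 300,
    seed: int = 0,
) -> list[EnhancerRecord]:
    """Enhancer intervals placed in intergenic space, each targeting 1-3
    genes with interaction scores spanning the usual score cutoff (half the
    links score above 10, half below)."""
    rng = np.random.default_rng(seed)
    segs = _distal_segments(genome, genes, pad=4000)
    gene_ids = [g.gene_id for g in genes]
    records: list[EnhancerRecord] = []
    for i in range(n_enhancers):
        l = int(rng.integers(1000, 3001))
        iv = _sample_in_segments(rng, segs, l)
        if iv is None:
            break
        targets = rng.choice(gene_ids, size=int(rng.integers(1, 4)), replace=False)
        for t in targets:
            score = float(np.round(rng.uniform(0, 20), 2))
            records.append(
                EnhancerRecord(
                    interval=iv,
                    enhancer_id=f"GH_{i:04d}",
                    target_gene=str(t),
                    interaction_score=score,
                )
            )
    return records


def simulate_de(
    genes: Sequence[GeneModel],
    target_genes: set[str],
    truth: SyntheticTruth,
) -> tuple[list[DifferentialExpressionRecord], dict[str, str]]:
    """DE table with planted labels on the target genes.

    Up-planted genes get log2FC ~ +|N(1.5, 0.5)| and padj ~ U(0, 0.05);
    down-planted the mirror image; everything else padj ~ U(0.05, 1) with
    small fold-changes.  Non-target genes are always ns, so planted counts
    are recovered exactly by a peak-target DE join."""
    rng = np.random.default_rng(truth.seed + 2)
    targets = sorted(target_genes)
    n_up = round(truth.de_target_up_frac * len(targets))
    n_down = round(truth.de_target_down_frac * len(targets))
    perm = rng.permutation(len(targets))
    labels: dict[str, str] = {}
    for j, idx in enumerate(perm):
        if j < n_up:
            labels[targets[idx]] = "up"
        elif j < n_up + n_down:
            labels[targets[idx]] = "down"
        else:
            labels[targets[idx]] = "ns"
    records = []
    for g in genes:
        lab = labels.get(g.gene_id, "ns")
        if lab == "up":
            lfc = abs(rng.normal(1.5, 0.5))
            padj = rng.uniform(0, 0.05)
            lfc = max(lfc, 1e-6)
        elif lab == "down":
            lfc = -abs(rng.normal(1.5, 0.5))
            padj = rng.uniform(0, 0.05)
            lfc = min(lfc, -1e-6)
        else:
            lfc = rng.normal(0, 0.3)
            padj = rng.uniform(0.05, 1)
        records.append(
            DifferentialExpressionRecord(
                gene_id=g.gene_id,
                log2_fold_change=float(lfc),
                adjusted_p=float(min(padj, 1.0)),
            )
        )
    return records, labels


def _brute_force_target_genes(
    peaks: PeakSet, genes: Sequence[GeneModel], max_dist: int
) -> set[str]:
    """Genes whose span lies within ``max_dist`` bp of any peak, by direct
    enumeration (kept independent of the annotation module's index)."""
    out = set()
    for g in genes:
        for p in peaks:
            if p.chrom != g.chrom:
                continue
            if p.start < g.span.end + max_dist + 1 and g.span.start - max_dist - 1 < p.end:
                out.add(g.gene_id)
                break
    return out


def write_bundle(
    outdir: str | Path,
    truth: SyntheticTruth | None = None,
    n_chrom: int = 1,
    chrom_length: int = 10_000_000,
    n_genes: int = 200,
    n_a: int = 1000,
    n_b: int = 1000,
    n_enhancers: int = 300,
    max_gene_dist: int = 5000,
) -> dict:
    """Generate and write a complete synthetic input bundle plus truth.json.

    Files written: chrom.sizes, genes.tsv, A.bed, B.bed, H3K4me3.bed,
    H3K27ac.bed, enhancers.tsv, de.tsv, truth.json.  Returns the truth
    dictionary (parameters plus realized bookkeeping).
    """
    truth = truth or SyntheticTruth()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes = simulate_genome(n_chrom, chrom_length, n_genes, seed=truth.seed)
    set_a, set_b, ledger = simulate_cobound_peaks(genome, genes, n_a, n_b, truth)
    marks_prom, marks_dist = simulate_marks(genome, genes, truth)
    enhancers = simulate_enhancers(genome, genes, n_enhancers, seed=truth.seed + 3)
    target_genes = _brute_force_target_genes(set_a, genes, max_gene_dist)
    de_records, de_labels = simulate_de(genes, target_genes, truth)

    write_chrom_sizes(genome, outdir / "chrom.sizes")
    write_gene_models(genes, outdir / "genes.tsv")
    write_bed(set_a, outdir / "A.bed")
    write_bed(set_b, outdir / "B.bed")
    write_bed(marks_prom, outdir / "H3K4me3.bed")
    write_bed(marks_dist, outdir / "H3K27ac.bed")
    write_enhancers(enhancers, outdir / "enhancers.tsv")
    write_de_table(de_records, outdir / "de.tsv")

    planted = {
        "up": sum(1 for g in target_genes if de_labels.get(g) == "up"),
        "down": sum(1 for g in target_genes if de_labels.get(g) == "down"),
    }

    # per-peak overlap bookkeeping by direct enumeration, independent of the
    # interval index used by the pipeline
    def _hits(p, intervals):
        return any(
            p.chrom == iv.chrom and p.start < iv.end and iv.start < p.end
            for iv in intervals
        )

    window_ivs = [w.interval for w in promoter_windows(genes, 4000, 1000, genome)]
    k4_ivs = [p.interval for p in marks_prom]
    k27_ivs = [p.interval for p in marks_dist]
    a_overlaps = {
        p.id: {
            "promoter_window": _hits(p, window_ivs),
            "mark_promoter": _hits(p, k4_ivs),
            "mark_distal": _hits(p, k27_ivs),
        }
        for p in set_a
    }
    segs = _distal_segments(genome, genes, pad=4000)
    total_distal = sum(e - s for ss in segs.values() for s, e in ss)
    realized_distal_cov = (
        sum(p.interval.length for p in marks_dist) / total_distal if total_distal else 0.0
    )
    truth_doc = {
        "parameters": asdict(truth),
        "scale": {
            "n_chrom": n_chrom,
            "chrom_length": chrom_length,
            "n_genes": n_genes,
            "n_a": n_a,
            "n_b": n_b,
            "n_enhancers": n_enhancers,
            "max_gene_dist": max_gene_dist,
        },
        "expected_overlap_fraction_b_on_a": ledger["expected_overlap_fraction_b_on_a"],
        "n_b_planted_overlap": ledger["n_b_planted_overlap"],
        "b_intended_overlap": ledger["b_intended_overlap"],
        "n_target_genes": len(target_genes),
        "planted_deg_counts": planted,
        "de_labels_target_genes": {g: de_labels[g] for g in sorted(target_genes)},
        "a_peak_overlaps": a_overlaps,
        "realized_distal_mark_coverage": realized_distal_cov,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth_doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return truth_doc
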