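"""Genomic interval primitives and peak-set algebra.

Coordinates are 0-based, half-open (the BED convention) everywhere, on disk
and in memory.  Two intervals overlap iff they share at least one base, i.e.
``a.start < b.end and b.start < a.end`` on the same chromosome; book-ended
intervals do not overlap.  Transcription-factor peaks are unstranded; strand
enters the analysis only through gene models (see :mod:`peakcoloc.annotation`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "GenomicInterval",
    "Peak",
    "PeakSet",
    "Genome",
    "MergedPeak",
    "BinGrid",
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "intervals_overlap",
    "find_overlap_pairs",
    "merge_cobound",
    "nearest_distance",
    "mean_peak_length",
    "tile_genome",
]


class BedParseError(ValueError):
    """Raised when a BED-like file contains a malformed record."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open span ``[start, end)`` on one chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    start : int
        0-based inclusive start (bp), ``>= 0``.
    end : int
        0-based exclusive end (bp), ``> start`` (empty intervals rejected).
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Integer midpoint, rounded down."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return intervals_overlap(self, other)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class Peak:
    """A called ChIP-seq peak: an interval plus identity and optional scores."""

    interval: GenomicInterval
    id: str
    score: float | None = None
    significance: float | None = None

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass(frozen=True)
class Genome:
    """Chromosome-name → length map with an assembly label."""

    chrom_sizes: Mapping[str, int]
    assembly_label: str = "custom"

    def __post_init__(self) -> None:
        bad = {c: n for c, n in self.chrom_sizes.items() if n <= 0}
        if bad:
            raise ValueError(f"non-positive chromosome lengths: {bad}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_sizes

    def __len__(self) -> int:
        return len(self.chrom_sizes)

    @property
    def total_length(self) -> int:
        return sum(self.chrom_sizes.values())


class PeakSet:
    """An ordered, genome-anchored collection of peaks from one source.

    Peaks are sorted by ``(chrom, start, end)`` on construction and ids must
    be unique.  Per-chromosome coordinate arrays are cached for the sweep
    algorithms below.
    """

    def __init__(self, name: str, peaks: Iterable[Peak], genome: Genome):
        peaks = sorted(
            peaks, key=lambda p: (p.chrom, p.start, p.end, p.id)
        )
        ids = [p.id for p in peaks]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = sorted({i for i in ids if i in seen or seen.add(i)})
            raise ValueError(f"duplicate peak ids in set '{name}': {dup[:5]}")
        missing = sorted({p.chrom for p in peaks} - set(genome.chrom_sizes))
        if missing:
            raise ValueError(
                f"peak chromosomes absent from genome: {missing}"
            )
        self.name = name
        self.peaks: list[Peak] = peaks
        self.genome = genome
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[int]]] | None = None

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __getitem__(self, i: int) -> Peak:
        return self.peaks[i]

    @property
    def chroms(self) -> list[str]:
        return sorted({p.chrom for p in self.peaks})

    def lengths(self) -> np.ndarray:
        return np.array([p.interval.length for p in self.peaks], dtype=np.int64)

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray, list[int]]]:
        """Per-chromosome ``(starts, ends, peak indices)``; starts ascending."""
        if self._by_chrom is None:
            out: dict[str, tuple[list[int], list[int], list[int]]] = {}
            for i, p in enumerate(self.peaks):
                out.setdefault(p.chrom, ([], [], []))
                s, e, idx = out[p.chrom]
                s.append(p.start)
                e.append(p.end)
                idx.append(i)
            self._by_chrom = {
                c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64), idx)
                for c, (s, e, idx) in out.items()
            }
        return self._by_chrom

    def subset(self, ids: Iterable[str], name: str | None = None) -> "PeakSet":
        wanted = set(ids)
        return PeakSet(
            name or self.name,
            [p for p in self.peaks if p.id in wanted],
            self.genome,
        )


@dataclass(frozen=True)
class MergedPeak:
    """A connected component of mutually overlapping peaks from two sources.

    ``span`` is the tightest interval covering every member; both member
    lists are non-empty by construction.
    """

    span: GenomicInterval
    members_a: tuple[str, ...]
    members_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members_a or not self.members_b:
            raise ValueError("merged peak requires members from both sets")


@dataclass(frozen=True)
class BinGrid:
    """Tiling of every chromosome into consecutive ``width``-bp windows.

    Bins start at position 0; the final partial bin is included, so each
    chromosome contributes ``ceil(length / width)`` bins.
    """

    genome: Genome
    width: int

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError(f"bin width must be >= 1, got {self.width}")

    def n_bins(self, chrom: str) -> int:
        return -(-self.genome.chrom_sizes[chrom] // self.width)

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c in self.genome.chrom_sizes)

    def bins(self, chrom: str) -> Iterator[GenomicInterval]:
        """Yield the bin intervals of one chromosome, left to right."""
        length = self.genome.chrom_sizes[chrom]
        for i in range(self.n_bins(chrom)):
            yield GenomicInterval(chrom, i * self.width, min((i + 1) * self.width, length))


# ---------------------------------------------------------------------------
# I/O


def read_chrom_sizes(path: str | Path, assembly_label: str = "custom") -> Genome:
    """Read a two-column ``chrom<TAB>length`` file into a :class:`Genome`."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise BedParseError(f"{path}:{lineno}: expected 2 columns")
            try:
                sizes[fields[0]] = int(fields[1])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: bad length {fields[1]!r}") from exc
    return Genome(sizes, assembly_label)


def write_chrom_sizes(genome: Genome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.chrom_sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def read_bed(path: str | Path, genome: Genome, name: str) -> PeakSet:
    """Read a BED3/BED5 file into a sorted :class:`PeakSet`.

    Columns: chrom, start (0-based), end (exclusive), optional name and
    score.  Lines starting with ``#``, ``track`` or ``browser`` are skipped.
    Peaks without a name column get ids ``<name>_<ordinal>``.
    """
    peaks: list[Peak] = []
    bad_chroms: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start or start < 0:
                raise BedParseError(
                    f"{path}:{lineno}: invalid interval {chrom}:{start}-{end}"
                )
            if chrom not in genome:
                bad_chroms.add(chrom)
                continue
            pid = fields[3] if len(fields) >= 4 and fields[3] not in ("", ".") else f"{name}_{len(peaks)}"
            score = None
            if len(fields) >= 5 and fields[4] not in ("", "."):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: bad score {fields[4]!r}") from exc
            peaks.append(Peak(GenomicInterval(chrom, start, end), pid, score))
    if bad_chroms:
        raise BedParseError(
            f"{path}: chromosomes absent from genome: {sorted(bad_chroms)}"
        )
    return PeakSet(name, peaks, genome)


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    """Write BED5 (score column '.' when unset)."""
    with open(path, "w") as fh:
        for p in peaks:
            score = "." if p.score is None else f"{p.score:g}"
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.id}\t{score}\n")


# ---------------------------------------------------------------------------
# Interval algebra


def intervals_overlap(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the intervals share >= 1 base (same chromosome, half-open)."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def _check_same_genome(set_a: PeakSet, set_b: PeakSet) -> None:
    if set_a.genome is not set_b.genome and set_a.genome != set_b.genome:
        raise ValueError(
            f"peak sets '{set_a.name}' and '{set_b.name}' are on different genomes"
        )


def find_overlap_pairs(set_a: PeakSet, set_b: PeakSet) -> list[tuple[str, str]]:
    """All (A-peak id, B-peak id) pairs whose intervals share >= 1 base.

    Sorted-sweep per chromosome; worst case (everything overlapping
    everything) degrades gracefully to the full |A|x|B| output.
    """
    _check_same_genome(set_a, set_b)
    pairs: list[tuple[str, str]] = []
    b_chrom = set_b.by_chrom()
    for chrom, (a_starts, a_ends, a_idx) in set_a.by_chrom().items():
        if chrom not in b_chrom:
            continue
        b_starts, b_ends, b_idx = b_chrom[chrom]
        # candidates: b.start < a.end; then filter b.end > a.start
        for s, e, ai in zip(a_starts, a_ends, a_idx):
            hi = int(np.searchsorted(b_starts, e, side="left"))
            if hi == 0:
                continue
            hit = np.nonzero(b_ends[:hi] > s)[0]
            aid = set_a.peaks[ai].id
            pairs.extend((aid, set_b.peaks[b_idx[j]].id) for j in hit)
    return pairs


def merge_cobound(set_a: PeakSet, set_b: PeakSet) -> list[MergedPeak]:
    """Connected components of the >=1-bp overlap graph over A ∪ B, keeping
    only components with members from *both* sets.

    Several peaks of one set overlapping a single peak of the other collapse
    into one merged peak; the component span runs from the minimum member
    start to the maximum member end.  Because overlap of intervals is
    interval-chainable, a single left-to-right sweep over the pooled sorted
    peaks yields exactly the connected components.
    """
    _check_same_genome(set_a, set_b)
    tagged = [(p, "a") for p in set_a] + [(p, "b") for p in set_b]
    tagged.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end, t[1], t[0].id))
    merged: list[MergedPeak] = []
    cur: list[tuple[Peak, str]] = []
    cur_end = -1

    def flush() -> None:
        mem_a = tuple(p.id for p, s in cur if s == "a")
        mem_b = tuple(p.id for p, s in cur if s == "b")
        if mem_a and mem_b:
            span = GenomicInterval(
                cur[0][0].chrom,
                min(p.start for p, _ in cur),
                max(p.end for p, _ in cur),
            )
            merged.append(MergedPeak(span, mem_a, mem_b))

    for peak, src in tagged:
        if cur and peak.chrom == cur[0][0].chrom and peak.start < cur_end:
            cur.append((peak, src))
            cur_end = max(cur_end, peak.end)
        else:
            if cur:
                flush()
            cur = [(peak, src)]
            cur_end = peak.end
    if cur:
        flush()
    return merged


def nearest_distance(query: PeakSet, subject: PeakSet) -> dict[str, int | None]:
    """Gap (bp) from each query peak to its nearest subject peak on the same
    chromosome: 0 when overlapping, ``None`` (undefined) when the chromosome
    carries no subject peak.  Undefined distances are excluded from
    downstream histograms rather than set to infinity.
    """
    _check_same_genome(query, subject)
    out: dict[str, int | None] = {}
    s_chrom = subject.by_chrom()
    # per chromosome: subject starts ascending; prefix max of ends for
    # overlap detection; ends sorted separately for the left neighbour.
    for chrom, (q_starts, q_ends, q_idx) in query.by_chrom().items():
        if chrom not in s_chrom:
            for i in q_idx:
                out[query.peaks[i].id] = None
            continue
        s_starts, s_ends, _ = s_chrom[chrom]
        prefix_max_end = np.maximum.accumulate(s_ends)
        ends_sorted = np.sort(s_ends)
        for qs, qe, qi in zip(q_starts, q_ends, q_idx):
            qid = query.peaks[qi].id
            lo = int(np.searchsorted(s_starts, qe, side="left"))
            if lo > 0 and prefix_max_end[lo - 1] > qs:
                out[qid] = 0
                continue
            best = None
            if lo < len(s_starts):  # nearest subject entirely to the right
                best = int(s_starts[lo] - qe)
            j = int(np.searchsorted(ends_sorted, qs, side="right"))
            if j > 0:  # nearest subject entirely to the left
                left = int(qs - ends_sorted[j - 1])
                best = left if best is None else min(best, left)
            out[qid] = best
    return out


def mean_peak_length(set_a: PeakSet, set_b: PeakSet) -> int:
    """Arithmetic mean length of the pooled A ∪ B peaks, rounded half-up.

    This pooled mean is what sets the default co-localization bin width.
    """
    if len(set_a) == 0 or len(set_b) == 0:
        raise ValueError("mean_peak_length requires two non-empty peak sets")
    lengths = np.concatenate([set_a.lengths(), set_b.lengths()])
    return int(math.floor(lengths.sum() / lengths.size + 0.5))


def tile_genome(genome: Genome, width: int) -> BinGrid:
    """Tile every chromosome from position 0 into ``width``-bp bins."""
    return BinGrid(genome, width)
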