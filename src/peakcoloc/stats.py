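"""Binned co-localization significance testing and gene-set overlap tests.

The co-localization test tiles the genome into equal bins (default width:
the pooled mean peak length of the two sets), scores each bin for the
presence of each set's peaks, and asks whether joint occupancy (the n11
cell) is enriched over the margins.  The one-sided p-value is the upper
tail of the hypergeometric distribution — the enrichment-sided Fisher's
exact test — evaluated in log space via log-gamma so that genome-scale
tables (hundreds of thousands of bins) do not underflow.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import gammaln

from .core import BinGrid, Genome, PeakSet, find_overlap_pairs, mean_peak_length, tile_genome

__all__ = [
    "ContingencyTable2x2",
    "OverlapTestResult",
    "bin_occupancy_table",
    "hypergeom_upper_tail",
    "fisher_exact_one_sided",
    "colocalization_test",
    "overlap_fraction",
    "gene_overlap_test",
]

#: Smallest reported p-value; tails that underflow double precision are
#: floored here rather than reported as an exact zero.
MIN_P = 5e-324


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Bin-occupancy counts: empty / A-only / B-only / both."""

    n00: int
    n10: int
    n01: int
    n11: int

    def __post_init__(self) -> None:
        if min(self.n00, self.n10, self.n01, self.n11) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def total(self) -> int:
        return self.n00 + self.n10 + self.n01 + self.n11

    @property
    def odds_ratio(self) -> float:
        """(n00·n11)/(n10·n01); NaN when the denominator is zero."""
        denom = self.n10 * self.n01
        if denom == 0:
            return math.nan
        return (self.n00 * self.n11) / denom


@dataclass(frozen=True)
class OverlapTestResult:
    table: ContingencyTable2x2
    p_value: float
    odds_ratio: float
    bin_width: int
    set_a: str = "A"
    set_b: str = "B"
    assembly: str = "custom"

    def to_dict(self) -> dict:
        return {
            "set_a": self.set_a,
            "set_b": self.set_b,
            "assembly": self.assembly,
            "bin_width": self.bin_width,
            "n00": self.table.n00,
            "n10": self.table.n10,
            "n01": self.table.n01,
            "n11": self.table.n11,
            "odds_ratio": self.odds_ratio,
            "p_value": self.p_value,
        }

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    def write_tsv(self, path: str | Path) -> None:
        d = self.to_dict()
        with open(path, "w") as fh:
            fh.write("\t".join(d) + "\n")
            fh.write("\t".join(str(v) for v in d.values()) + "\n")


def _occupied_bins(grid: BinGrid, peaks: PeakSet) -> dict[str, np.ndarray]:
    """Boolean occupancy per chromosome: a bin is occupied iff >= 1 bp of
    some peak lies in it."""
    out = {c: np.zeros(grid.n_bins(c), dtype=bool) for c in grid.genome.chrom_sizes}
    w = grid.width
    for chrom, (starts, ends, _) in peaks.by_chrom().items():
        occ = out[chrom]
        first = starts // w
        last = (ends - 1) // w  # last base of a half-open interval is end-1
        for a, b in zip(first, last):
            occ[a : b + 1] = True
    return out


def bin_occupancy_table(grid: BinGrid, set_a: PeakSet, set_b: PeakSet) -> ContingencyTable2x2:
    """Count bins by joint occupancy of the two peak sets.

    Every bin of every chromosome in the grid's genome is counted, including
    chromosomes carrying no peaks (they contribute to n00).
    """
    occ_a = _occupied_bins(grid, set_a)
    occ_b = _occupied_bins(grid, set_b)
    n10 = n01 = n11 = 0
    for chrom in grid.genome.chrom_sizes:
        a, b = occ_a[chrom], occ_b[chrom]
        n11 += int((a & b).sum())
        n10 += int((a & ~b).sum())
        n01 += int((~a & b).sum())
    n00 = grid.total_bins - n10 - n01 - n11
    return ContingencyTable2x2(n00=n00, n10=n10, n01=n01, n11=n11)


def hypergeom_upper_tail(N: int, K: int, n: int, k) -> float | np.ndarray:
    """P[X >= k] for X ~ Hypergeometric(N, K, n), in log space.

    ``N`` objects, ``K`` marked, ``n`` drawn without replacement, ``k``
    scalar or array of thresholds.  Terms are accumulated with compensated
    (Kahan) summation over the exact log-pmf computed from log-gamma; a tail
    below double-precision range is floored at the smallest positive double
    rather than reported as zero.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
    if K > n:
        # the distribution is symmetric in (K, n); canonicalize so transposed
        # contingency tables give bitwise-identical p-values
        K, n = n, K
    lo = max(0, K + n - N)
    hi = min(K, n)
    i = np.arange(lo, hi + 1)
    logpmf = (
        _log_comb(K, i)
        + _log_comb(N - K, n - i)
        - _log_comb(N, n)
    )
    k_arr = np.atleast_1d(np.asarray(k, dtype=np.int64))
    out = np.empty(k_arr.shape, dtype=float)
    # suffix compensated sums of exp(logpmf), largest terms shifted to ~1
    for j, kv in enumerate(k_arr.ravel()):
        if kv <= lo:
            out.ravel()[j] = 1.0
            continue
        if kv > hi:
            out.ravel()[j] = MIN_P  # impossible event; floored, never 0
            continue
        sel = logpmf[kv - lo :]
        m = sel.max()
        total = comp = 0.0
        for t in np.exp(sel - m):
            y = t - comp
            s = total + y
            comp = (s - total) - y
            total = s
        val = math.exp(m) * total if m > -700 else math.exp(m + math.log(total))
        out.ravel()[j] = min(1.0, max(val, MIN_P))
    if np.isscalar(k) or np.asarray(k).ndim == 0:
        return float(out.ravel()[0])
    return out


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact_one_sided(table: ContingencyTable2x2) -> float:
    """Enrichment-sided exact p for joint bin occupancy.

    With N total bins, K = n11 + n10 bins holding A peaks, n = n11 + n01
    bins holding B peaks and k = n11 jointly occupied, the p-value is
    P[X >= k] for X ~ Hypergeometric(N, K, n) — the upper-tail (one-sided)
    Fisher's exact test.  Always > 0; underflow is floored distinctly from
    an exact zero.
    """
    N = table.total
    K = table.n11 + table.n10
    n = table.n11 + table.n01
    return hypergeom_upper_tail(N, K, n, table.n11)


def colocalization_test(
    set_a: PeakSet,
    set_b: PeakSet,
    genome: Genome | None = None,
    width: int | None = None,
) -> OverlapTestResult:
    """Binned co-localization test between two peak sets.

    The bin width defaults to the pooled mean peak length of the two sets;
    the genome defaults to the sets' shared genome.
    """
    if len(set_a) == 0 or len(set_b) == 0:
        raise ValueError("colocalization_test requires two non-empty peak sets")
    if genome is None:
        genome = set_a.genome
    if width is None:
        width = mean_peak_length(set_a, set_b)
    grid = tile_genome(genome, width)
    table = bin_occupancy_table(grid, set_a, set_b)
    p = fisher_exact_one_sided(table)
    return OverlapTestResult(
        table=table,
        p_value=p,
        odds_ratio=table.odds_ratio,
        bin_width=width,
        set_a=set_a.name,
        set_b=set_b.name,
        assembly=genome.assembly_label,
    )


def overlap_fraction(set_a: PeakSet, set_b: PeakSet) -> tuple[float, int, int]:
    """Fraction of A peaks overlapping >= 1 B peak, with (numerator,
    denominator) counts."""
    if len(set_a) == 0:
        raise ValueError("overlap_fraction of an empty query set")
    hit = {a for a, _ in find_overlap_pairs(set_a, set_b)}
    return len(hit) / len(set_a), len(hit), len(set_a)


def gene_overlap_test(list_a: set, list_b: set, universe: set) -> float:
    """Hypergeometric upper-tail p for the overlap of two gene sets drawn
    from a common universe: P[X >= |A ∩ B|] drawing |B| genes from a
    universe containing |A| successes."""
    extra_a = set(list_a) - set(universe)
    extra_b = set(list_b) - set(universe)
    if extra_a or extra_b:
        raise ValueError(
            f"gene lists not contained in universe: A\\U={sorted(extra_a)[:5]}, "
            f"B\\U={sorted(extra_b)[:5]}"
        )
    k = len(set(list_a) & set(list_b))
    return hypergeom_upper_tail(len(set(universe)), len(set(list_a)), len(set(list_b)), k)
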