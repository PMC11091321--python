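import numpy as np
import pytest

from peakcoloc.core import Genome, GenomicInterval, Peak, PeakSet


@pytest.fixture(scope="session")
def toy_genome() -> Genome:
    return Genome({"chr1": 1_000_000, "chr2": 500_000}, "toy")


def random_peakset(rng: np.random.Generator, genome: Genome, n: int, name: str,
                   max_len: int = 2000) -> PeakSet:
    """Random peaks for oracle comparisons (duplicates and nesting allowed)."""
    chroms = list(genome.chrom_sizes)
    peaks = []
    for i in range(n):
        c = chroms[int(rng.integers(0, len(chroms)))]
        length = int(rng.integers(1, max_len + 1))
        start = int(rng.integers(0, genome.chrom_sizes[c] - length))
        peaks.append(Peak(GenomicInterval(c, start, start + length), f"{name}{i}"))
    return PeakSet(name, peaks, genome)


def brute_force_pairs(set_a: PeakSet, set_b: PeakSet) -> set[tuple[str, str]]:
    """Quadratic all-pairs overlap oracle."""
    out = set()
    for a in set_a:
        for b in set_b:
            if a.chrom == b.chrom and a.start < b.end and b.start < a.end:
                out.add((a.id, b.id))
    return out
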