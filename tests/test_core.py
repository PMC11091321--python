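"""Interval algebra, peak-set containers and BED I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from peakcoloc.core import (
    BedParseError,
    Genome,
    GenomicInterval,
    Peak,
    PeakSet,
    find_overlap_pairs,
    intervals_overlap,
    mean_peak_length,
    merge_cobound,
    nearest_distance,
    read_bed,
    read_chrom_sizes,
    tile_genome,
    write_bed,
    write_chrom_sizes,
)
from conftest import brute_force_pairs, random_peakset


# ---------------------------------------------------------------------------
# interval basics


def test_empty_and_negative_intervals_rejected():
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 200, 200)
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 300, 200)
    with pytest.raises(ValueError):
        GenomicInterval("chr1", -1, 5)


@pytest.mark.parametrize(
    "a, b, expected",
    [
        (("chr1", 100, 200), ("chr1", 199, 250), True),   # share base 199
        (("chr1", 100, 200), ("chr1", 200, 250), False),  # book-ended
        (("chr1", 100, 200), ("chr2", 100, 200), False),  # different chrom
        (("chr1", 100, 200), ("chr1", 100, 200), True),
        (("chr1", 100, 200), ("chr1", 50, 101), True),
    ],
)
def test_overlap_definition(a, b, expected):
    ia, ib = GenomicInterval(*a), GenomicInterval(*b)
    assert intervals_overlap(ia, ib) is expected
    assert intervals_overlap(ib, ia) is expected  # symmetry


@given(
    s1=st.integers(0, 500), l1=st.integers(1, 100),
    s2=st.integers(0, 500), l2=st.integers(1, 100),
)
@settings(derandomize=True, max_examples=200)
def test_overlap_symmetric_and_matches_shared_base_count(s1, l1, s2, l2):
    a = GenomicInterval("chr1", s1, s1 + l1)
    b = GenomicInterval("chr1", s2, s2 + l2)
    shared = max(0, min(a.end, b.end) - max(a.start, b.start))
    assert intervals_overlap(a, b) == (shared >= 1)
    assert intervals_overlap(a, b) == intervals_overlap(b, a)


# ---------------------------------------------------------------------------
# containers


def test_peakset_sorted_unique_ids_and_genome_check(toy_genome):
    peaks = [
        Peak(GenomicInterval("chr2", 10, 20), "p2"),
        Peak(GenomicInterval("chr1", 50, 80), "p1"),
        Peak(GenomicInterval("chr1", 5, 30), "p0"),
    ]
    ps = PeakSet("x", peaks, toy_genome)
    assert [p.id for p in ps] == ["p0", "p1", "p2"]
    with pytest.raises(ValueError, match="duplicate"):
        PeakSet("x", [peaks[0], peaks[0]], toy_genome)
    with pytest.raises(ValueError, match="absent"):
        PeakSet("x", [Peak(GenomicInterval("chrX", 0, 10), "p")], toy_genome)


def test_genome_rejects_nonpositive_lengths():
    with pytest.raises(ValueError):
        Genome({"chr1": 0})


# ---------------------------------------------------------------------------
# BED I/O


def test_read_bed_basic_and_errors(tmp_path, toy_genome):
    p = tmp_path / "a.bed"
    p.write_text("# comment\ntrack name=x\nchr1\t100\t200\nchr1\t150\t250\n")
    ps = read_bed(p, toy_genome, "wt1")
    assert len(ps) == 2
    assert [(x.start, x.end) for x in ps] == [(100, 200), (150, 250)]
    assert ps[0].id.startswith("wt1_")

    (tmp_path / "empty_iv.bed").write_text("chr1\t200\t200\n")
    with pytest.raises(BedParseError, match=":1"):
        read_bed(tmp_path / "empty_iv.bed", toy_genome, "x")

    (tmp_path / "badchrom.bed").write_text("chrUn\t1\t10\n")
    with pytest.raises(BedParseError, match="chrUn"):
        read_bed(tmp_path / "badchrom.bed", toy_genome, "x")

    (tmp_path / "short.bed").write_text("chr1\t100\n")
    with pytest.raises(BedParseError, match="3 columns"):
        read_bed(tmp_path / "short.bed", toy_genome, "x")


def test_bed_round_trip_preserves_interval_multiset(tmp_path, toy_genome):
    rng = np.random.default_rng(7)
    ps = random_peakset(rng, toy_genome, 1000, "rt")
    path = tmp_path / "rt.bed"
    write_bed(ps, path)
    back = read_bed(path, toy_genome, "rt")
    orig = sorted((p.chrom, p.start, p.end, p.id) for p in ps)
    got = sorted((p.chrom, p.start, p.end, p.id) for p in back)
    assert orig == got


def test_chrom_sizes_round_trip(tmp_path, toy_genome):
    path = tmp_path / "g.sizes"
    write_chrom_sizes(toy_genome, path)
    g2 = read_chrom_sizes(path, "toy")
    assert dict(g2.chrom_sizes) == dict(toy_genome.chrom_sizes)


# ---------------------------------------------------------------------------
# overlap pairs / merge / nearest


def test_find_overlap_pairs_examples(toy_genome):
    A = PeakSet("A", [Peak(GenomicInterval("chr1", 100, 200), "a1")], toy_genome)
    B = PeakSet(
        "B",
        [
            Peak(GenomicInterval("chr1", 150, 300), "b1"),
            Peak(GenomicInterval("chr1", 400, 500), "b2"),
        ],
        toy_genome,
    )
    assert set(find_overlap_pairs(A, B)) == {("a1", "b1")}
    # reflexivity: A vs A contains every self pair
    self_pairs = set(find_overlap_pairs(A, A))
    assert ("a1", "a1") in self_pairs


def test_find_overlap_pairs_genome_mismatch(toy_genome):
    other = Genome({"chr1": 1000})
    A = PeakSet("A", [Peak(GenomicInterval("chr1", 0, 10), "a")], toy_genome)
    B = PeakSet("B", [Peak(GenomicInterval("chr1", 0, 10), "b")], other)
    with pytest.raises(ValueError, match="different genomes"):
        find_overlap_pairs(A, B)


def test_merge_cobound_multiple_overlap_rule(toy_genome):
    A = PeakSet(
        "A",
        [
            Peak(GenomicInterval("chr1", 100, 200), "a1"),
            Peak(GenomicInterval("chr1", 300, 400), "a2"),
        ],
        toy_genome,
    )
    B = PeakSet("B", [Peak(GenomicInterval("chr1", 150, 350), "b1")], toy_genome)
    merged = merge_cobound(A, B)
    assert len(merged) == 1
    m = merged[0]
    assert (m.span.start, m.span.end) == (100, 400)
    assert set(m.members_a) == {"a1", "a2"}
    assert set(m.members_b) == {"b1"}


def test_merge_cobound_requires_both_sets(toy_genome):
    A = PeakSet("A", [Peak(GenomicInterval("chr1", 100, 200), "a1")], toy_genome)
    B = PeakSet("B", [Peak(GenomicInterval("chr1", 500, 600), "b1")], toy_genome)
    assert merge_cobound(A, B) == []
    # within-set overlaps alone never produce merged peaks
    A2 = PeakSet(
        "A",
        [
            Peak(GenomicInterval("chr1", 100, 200), "a1"),
            Peak(GenomicInterval("chr1", 150, 250), "a2"),
        ],
        toy_genome,
    )
    assert merge_cobound(A2, B) == []


def _union_find_components(set_a, set_b):
    """Independent oracle: union-find over the brute-force overlap pair list
    of the pooled peaks."""
    pooled = [(p, "a") for p in set_a] + [(p, "b") for p in set_b]
    parent = list(range(len(pooled)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, (pi, _) in enumerate(pooled):
        for j, (pj, _) in enumerate(pooled):
            if i < j and pi.chrom == pj.chrom and pi.start < pj.end and pj.start < pi.end:
                parent[find(i)] = find(j)
    comps = {}
    for i, (p, src) in enumerate(pooled):
        comps.setdefault(find(i), {"a": set(), "b": set(), "lo": 10**18, "hi": -1, "chrom": p.chrom})
        c = comps[find(i)]
        c[src].add(p.id)
        c["lo"] = min(c["lo"], p.start)
        c["hi"] = max(c["hi"], p.end)
    return sorted(
        (c["chrom"], c["lo"], c["hi"], frozenset(c["a"]), frozenset(c["b"]))
        for c in comps.values()
        if c["a"] and c["b"]
    )


def test_merge_cobound_matches_union_find_oracle(toy_genome):
    rng = np.random.default_rng(11)
    for _ in range(20):
        A = random_peakset(rng, toy_genome, int(rng.integers(5, 120)), "a", max_len=5000)
        B = random_peakset(rng, toy_genome, int(rng.integers(5, 120)), "b", max_len=5000)
        merged = merge_cobound(A, B)
        got = sorted(
            (m.span.chrom, m.span.start, m.span.end, frozenset(m.members_a), frozenset(m.members_b))
            for m in merged
        )
        assert got == _union_find_components(A, B)
        # spans pairwise non-overlapping; members unique
        by_chrom = {}
        for m in merged:
            by_chrom.setdefault(m.span.chrom, []).append(m.span)
        for spans in by_chrom.values():
            spans.sort(key=lambda s: s.start)
            for x, y in zip(spans, spans[1:]):
                assert x.end <= y.start
        all_members = [i for m in merged for i in m.members_a + m.members_b]
        assert len(all_members) == len(set(all_members))


def test_nearest_distance_examples(toy_genome):
    Q = PeakSet("q", [Peak(GenomicInterval("chr1", 100, 200), "q1")], toy_genome)
    S1 = PeakSet("s", [Peak(GenomicInterval("chr1", 300, 400), "s1")], toy_genome)
    assert nearest_distance(Q, S1) == {"q1": 100}
    S2 = PeakSet("s", [Peak(GenomicInterval("chr1", 150, 300), "s1")], toy_genome)
    assert nearest_distance(Q, S2) == {"q1": 0}
    # no subject on the query's chromosome -> undefined
    S3 = PeakSet("s", [Peak(GenomicInterval("chr2", 0, 10), "s1")], toy_genome)
    assert nearest_distance(Q, S3) == {"q1": None}


def test_nearest_distance_zero_iff_overlap_and_matches_brute_force(toy_genome):
    rng = np.random.default_rng(5)
    for _ in range(10):
        Q = random_peakset(rng, toy_genome, 200, "q", max_len=3000)
        S = random_peakset(rng, toy_genome, 200, "s", max_len=3000)
        got = nearest_distance(Q, S)
        pairs = brute_force_pairs(Q, S)
        overlapping_q = {a for a, _ in pairs}
        for q in Q:
            best = None
            for s in S:
                if s.chrom != q.chrom:
                    continue
                gap = max(0, max(s.start - q.end, q.start - s.end))
                best = gap if best is None else min(best, gap)
            assert got[q.id] == best
            if best is not None and got[q.id] == 0:
                # gap 0 means overlap, except for exactly book-ended subjects
                book_ended = any(
                    s.chrom == q.chrom and (s.start == q.end or s.end == q.start)
                    for s in S
                )
                assert (q.id in overlapping_q) or book_ended
            if best is not None and q.id in overlapping_q:
                assert got[q.id] == 0


# ---------------------------------------------------------------------------
# mean length and binning


def test_mean_peak_length_pooled_and_rounding(toy_genome):
    def mk(name, lengths):
        return PeakSet(
            name,
            [
                Peak(GenomicInterval("chr1", 1000 * i, 1000 * i + l), f"{name}{i}")
                for i, l in enumerate(lengths)
            ],
            toy_genome,
        )

    assert mean_peak_length(mk("a", [100, 200]), mk("b", [300])) == 200
    assert mean_peak_length(mk("a", [100]), mk("b", [101])) == 101  # half-up
    with pytest.raises(ValueError):
        mean_peak_length(mk("a", [100]), PeakSet("b", [], toy_genome))

    rng = np.random.default_rng(3)
    A = random_peakset(rng, toy_genome, 500, "a")
    B = random_peakset(rng, toy_genome, 500, "b")
    lengths = [p.interval.length for p in A] + [p.interval.length for p in B]
    expected = int(np.floor(sum(lengths) / len(lengths) + 0.5))
    assert mean_peak_length(A, B) == expected


def test_tile_genome_bin_counts():
    g = Genome({"c": 10})
    assert [(b.start, b.end) for b in tile_genome(g, 5).bins("c")] == [(0, 5), (5, 10)]
    assert [(b.start, b.end) for b in tile_genome(g, 4).bins("c")] == [(0, 4), (4, 8), (8, 10)]
    hg = Genome({"chr1": 248_956_422})
    grid = tile_genome(hg, 654)
    assert grid.n_bins("chr1") == -(-248_956_422 // 654)
    with pytest.raises(ValueError):
        tile_genome(g, 0)
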