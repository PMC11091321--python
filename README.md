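# peakcoloc

Co-occupancy analysis of transcription-factor ChIP-seq peak sets.

When two transcription factors (say WT1 and the androgen receptor) are
profiled by ChIP-seq in the same cell type, the immediate questions are
geometric: how often do their binding peaks share genomic coordinates, is
that sharing more than chance, where do the shared sites sit relative to
genes, and do the genes they reach change expression?  `peakcoloc` is a
small, tested pipeline for exactly that analysis:

* **Interval algebra** on 0-based half-open peaks: overlap (≥ 1 shared
  base; book-ended intervals do not overlap), merged co-bound peaks
  (connected components of the cross-set overlap graph that contain members
  of *both* sets), nearest-peak gap distances, and genome binning.
* **Co-localization significance.**  The genome is tiled into equal bins
  whose width defaults to the pooled mean peak length of the two sets; each
  bin is scored for the presence of each set's peaks, giving a 2×2 table
  (empty / A-only / B-only / both).  Significance of joint occupancy is the
  one-sided Fisher's exact test — the upper tail of the hypergeometric
  distribution,

  P = Σ_{i≥n11} C(K, i) · C(N−K, n−i) / C(N, n),

  with N total bins, K = n11+n10 bins holding A peaks and n = n11+n01 bins
  holding B peaks, computed in log space via log-gamma so genome-scale
  tables never underflow to zero.
* **Feature annotation** against gene models: promoter distance bands
  (0–1 / 1–2 / 2–3 kb upstream of the nearest TSS, by peak midpoint),
  exon 1 / other exons, intron 1 / other introns, a 3-kb downstream window,
  and distal intergenic; plus overlap-based promoter windows (default 4 kb
  upstream / 1 kb downstream of the TSS), gene association within 5 kb, and
  TSS occupancy profiles.
* **Integration**: stratification of peaks by histone-mark regions
  (H3K4me3 for promoters, H3K27ac for distal sites), an enhancer join that
  splits distal peaks into annotated vs novel sites and collects target
  genes above an interaction-score cutoff (> 10), and a differential-
  expression join classifying peak-target genes as up/down/ns/untested at
  FDR < 0.05.
* **A synthetic-data generator** that emulates the whole input bundle —
  genome, gene models, two peak sets with an exact planted cross-set
  overlap fraction, histone-mark domains with stated coverages, enhancer
  and DE tables with planted labels — and records its ground truth so every
  stage is testable without downloads.

## Worked example

```python
import peakcoloc as pc

genome, genes = pc.simulate_genome(n_chrom=1, chrom_length=10_000_000, n_genes=200, seed=7)
truth = pc.SyntheticTruth(rho=0.07, seed=7)
wt1, ar, ledger = pc.simulate_cobound_peaks(genome, genes, 1000, 1000, truth, "WT1", "AR")

frac, n, d = pc.overlap_fraction(ar, wt1)
print(f"AR peaks overlapping WT1: {n}/{d} ({100*frac:.1f}%)")

merged = pc.merge_cobound(wt1, ar)
print(f"merged co-bound peaks: {len(merged)}")

res = pc.colocalization_test(wt1, ar)
print(f"bin width {res.bin_width} bp; table (n00,n10,n01,n11) = "
      f"({res.table.n00},{res.table.n10},{res.table.n01},{res.table.n11}); "
      f"one-sided P = {res.p_value:.3g}")
```

prints

```
AR peaks overlapping WT1: 70/1000 (7.0%)
merged co-bound peaks: 68
bin width 650 bp; table (n00,n10,n01,n11) = (11932,1590,1702,161); one-sided P = 1
```

Reading the output: exactly 70 of 1000 AR-like peaks were planted to share
≥ 1 bp with a WT1-like peak (the generator makes the 7% fraction exact by
construction), and chaining overlaps collapses them into 68 merged
co-bound peaks.  The co-localization table counts 650-bp bins: 161 bins
hold peaks from both sets.  Because the generator places the *other* 93%
of AR peaks away from WT1 peaks, joint occupancy is actually below the
level expected at random, so the enrichment-sided P is ≈ 1 — a reminder
that the test is one-sided for co-occurrence.

The same analysis is available from the shell:

```bash
peakcoloc simulate --outdir bundle --seed 7
peakcoloc coloc --a bundle/A.bed --b bundle/B.bed --genome bundle/chrom.sizes
peakcoloc run-all --config cfg.yaml     # full pipeline, writes summary.json
```

`run-all` executes feature annotation → merged co-bound peaks → nearest-
distance table → binned co-localization test → promoter/distal splits →
histone-mark stratification → enhancer join → DEG join, and writes
per-stage TSVs, `summary.json`, and a `pipeline.log` echoing every resolved
parameter.

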