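# Methods

## Coordinate conventions and overlap semantics

All intervals are 0-based half-open (`[start, end)`), on disk (BED) and in
memory.  Two intervals overlap iff they share at least one base:
`a.start < b.end and b.start < a.end` on the same chromosome.  Book-ended
intervals (one ending where the other starts) share no base and do not
overlap; they do, however, have a gap distance of 0 under the nearest-
distance convention (`gap = subject.start − query.end`, mirrored on the
left, floored at 0), matching the usual `bedtools closest` behaviour.
Query peaks on chromosomes carrying no subject peak get an *undefined*
distance and are excluded from histograms rather than mapped to infinity.

TF peaks are unstranded throughout; strand enters only via gene models.
Duplicate identical intervals are legitimate distinct peaks (distinct ids).

## Merged co-bound peaks

Co-bound sites are the connected components of the ≥ 1-bp overlap graph
over the pooled peaks of both sets, keeping only components containing at
least one peak from each set.  Two A peaks overlapping one B peak therefore
collapse into a single merged peak whose span runs from the minimum member
start to the maximum member end.  Because interval overlap is chainable
left-to-right, one sorted sweep produces exactly these components; the test
suite checks this against a union-find oracle built on the brute-force pair
list.

## The binned co-localization test

For a pair of peak sets the genome is tiled from position 0 of every
chromosome into equal bins (the final partial bin is a bin).  The default
bin width is the arithmetic mean length of the pooled peaks of the two
sets, rounded half-up — the convention that produces widths of ~650 bp at
ChIP-seq peak scale.  A bin *contains* a set iff ≥ 1 bp of one of its peaks
lies in the bin.  The 2×2 table (empty / A-only / B-only / both) is tested
for enrichment of joint occupancy with the upper tail of the
hypergeometric distribution — the one-sided Fisher's exact test.  Only the
enrichment side is implemented; depletion is not a question this pipeline
asks.

Numerics: the tail is evaluated in log space from `scipy.special.gammaln`,
terms re-exponentiated after subtracting the maximum and accumulated with
compensated (Kahan) summation.  The parameters (K, n) are canonicalized to
(min, max) — the distribution is symmetric in them — so transposing the
table gives a bitwise-identical p-value.  Tails below double-precision
range are floored at the smallest positive double (5e-324), never reported
as exact 0.  The test suite verifies agreement with exact rational
enumeration on every table with N ≤ 60 to 12 significant digits, and with
`scipy.stats.hypergeom` at genome scale.

Bins on chromosomes bearing no peaks still count in the empty cell; the
gene-set overlap test (`gene_overlap_test`) uses the same hypergeometric
tail with a gene universe in place of bins.

### Calibration at desk scale

The Fisher test conditions on the margins and assumes bins are
exchangeable.  Peaks are not points: with bin width equal to the mean peak
length, almost every peak straddles two adjacent bins, so each set's
occupied bins arrive in runs of ~2 and the exchangeability assumption is
mildly violated.  At the dense desk scale used for simulation studies
(1000 peaks of ~654 bp per set on a 10 Mb genome, ≈ 6.5% occupancy per
set) the empirical type-I error at nominal 0.05 is ≈ 0.08 rather than
0.05, measured over thousands of replicates under both an independent
uniform null and a within-set non-overlapping (hard-core) null.  The
inflation shrinks with occupancy, so it is smaller at whole-genome ChIP
densities (tens of thousands of peaks on 3 Gb ≈ 0.4% occupancy), but
p-values near the threshold should be read with this in mind.  Power is
not an issue: at a planted co-occupancy fraction of 0.3 with only 200
peaks per set, p < 0.001 in essentially every replicate.

## Feature annotation

Two promoter notions coexist deliberately:

* **Bands** for the feature-category breakdown: a peak whose *midpoint*
  lies 0–1 / 1–2 / 2–3 kb upstream of its nearest TSS falls into the
  corresponding promoter band.  Midpoint banding makes the categories a
  partition.
* **Windows** for promoter-peak sets and all downstream joins: ≥ 1-bp
  overlap with `[TSS − 4 kb, TSS + 1 kb)` (strand-aware, clipped to the
  chromosome).  A peak may hit several windows and a window several peaks;
  the multimap keeps all of them.

Category precedence (highest first): promoter bands, 5′/3′ UTR (assigned
only when the annotation supplies UTR records; the plain gene-model TSV
does not, so those categories simply never fire), exon 1, other exons,
intron 1, other introns, downstream (≤ 3 kb past the 3′ end), distal
intergenic.  Exons are kept in 5′→3′ transcription order, so "intron 1" is
the region between exon 1 and exon 2 in the direction of transcription on
either strand.  A peak overlapping features of several genes takes the
highest-precedence category over all genes; ties break by nearest TSS,
then lexicographic gene id.  Distal intergenic peaks, and only they, carry
a null gene id.

Gene association (`genes_near_peaks`) links a gene iff the gap between the
peak and the gene span is ≤ 5000 bp; a gap of exactly 5000 bp counts (the
padded-interval query pads by `max_dist + 1` to get this boundary right
under half-open coordinates).

## Integration joins

* Histone stratification is plain ≥ 1-bp overlap with mark regions; the
  pipeline stratifies promoter peaks against the promoter mark (H3K4me3)
  and distal-intergenic peaks against the distal mark (H3K27ac), and the
  merged co-bound set against both.
* The enhancer join partitions distal peaks into annotated (overlapping
  any enhancer interval) vs novel; regulated genes are the distinct target
  genes of overlapped enhancer records with interaction score strictly
  greater than 10.
* The DE join classifies each distinct peak-associated gene: up
  (padj < 0.05 and log2FC > 0), down (padj < 0.05 and log2FC < 0), ns
  (tested, not significant; padj exactly at the cutoff is ns), untested
  (absent).  Counting is per gene, never per peak.

All thresholds (4 kb/1 kb windows, 5 kb association, score > 10,
FDR < 0.05, bin-width override) are config parameters echoed to
`pipeline.log`; reruns with identical inputs produce byte-identical
`summary.json` (sorted keys, no timestamps).

## Synthetic-data generator

The generator emulates the statistical structure of a two-factor
co-occupancy study, not its sequence content: no reads, no signal shapes,
no peak-caller artifacts.

* **Genome/genes**: equal-length chromosomes; genes of 2–20 kb with
  random strand and 2–8 exons, placed uniformly with ≥ 10 kb spacing
  (infeasible densities raise).
* **Peak sets**: lengths from a normal (mean 654 bp, sd 150 bp — the
  ~650-bp scale of TF ChIP peaks) truncated below at 50 bp.  A fraction
  `promoter_bias` (default 0.34) of A peaks is centred inside promoter
  windows, the rest uniform.  Exactly `round(rho · n_b)` B peaks are
  planted to overlap a random A peak by ≥ 1 bp (the overlap amount is
  uniform — the ≥ 1-bp overlap definition makes the amount irrelevant to
  counts); the remaining B peaks are rejection-sampled to overlap no A
  peak.  The realized `overlap_fraction(B, A)` is therefore exact, and a
  ledger records each B peak's intended status.  Default rho = 0.07, the
  cross-factor overlap regime the pipeline is designed around.
* **Histone marks**: the promoter mark covers a `mark_promoter_cov`
  fraction (default 0.776) of promoter windows with one full-window domain
  each — window-level Bernoulli, so peak-level recovery is binomial around
  the coverage.  The distal mark covers a `mark_distal_cov` fraction
  (default 0.161) of intergenic space with disjoint 500–5000-bp domains.
  Note the peak-level hit fraction on the distal mark slightly exceeds the
  space coverage (a peak of length ℓ touching a domain of length L has
  effective target ℓ + L), which is why the truth ledger also records
  per-peak mark overlaps computed by direct enumeration — recovery tests
  compare against those exactly, and against the coverage for the
  window-level promoter mark.
* **Enhancers**: intervals of 1–3 kb in intergenic space, 1–3 target
  genes each, interaction scores uniform on [0, 20] so the score-> 10
  filter bites.
* **DE table**: planted fractions of peak-target genes (defaults 0.112
  up, 0.157 down) get |log2FC| ~ |N(1.5, 0.5)| with padj ~ U(0, 0.05);
  everything else is null (padj ~ U(0.05, 1)), so a DE join recovers the
  planted counts exactly.
* Every generator takes an explicit seed and is bit-reproducible; there
  is no global random state.  Default toy scale: 1 × 10 Mb chromosome,
  200 genes, 1000 + 1000 peaks — the full pipeline runs in well under a
  second.

What passing tests on this generator do **not** show: robustness to
peak-caller artifacts (blacklist regions, summit trimming), copy-number or
mappability biases, clustered gene architecture (real promoters are far
more clumped than uniformly spaced genes), or realistic DE effect-size
distributions.  Conclusions about real data rest on the geometry and
statistics being correct, which is what the oracle tests pin down.

## Known limitations

* Depletion-sided and two-sided Fisher variants are not implemented.
* UTR categories require an annotation that carries UTR records.
* The binned test's mild anticonservativeness at high peak density
  (see calibration above) is inherent to binning peaks wider than a bin;
  a permutation null would avoid it but is out of scope.
* The generator's rejection sampler for non-overlapping B peaks fails
  loudly (with a suggestion to lower density) rather than degrading.
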