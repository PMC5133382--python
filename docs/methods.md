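# Methods

This note records the conventions, models and numerical choices behind
`metaplots`, the defaults and why they were chosen, and what the synthetic
data used by the tests does and does not show about real data.

## Coordinates and missing data

All internal coordinates are 0-based half-open; conversion happens once, at
parse time (BED and bedGraph are taken as-is; GFF/GTF and wiggle positions
are 1-based and shifted by −1). A single convention eliminates off-by-one
errors downstream.

Missing signal is an explicit marker (NaN), never zero: a bigWig gap means
"not measured", while 0.0 means "measured, nothing there", and the two
average differently. Missing bases are excluded from both the numerator and
the denominator of every mean; a fully missing bin or window is itself
missing. Windows that extend past a chromosome end contribute missing, not
zero, keeping averages unbiased near edges. The one deliberate exception is
alignment (BAM/SAM) input: coverage computed from reads is defined
genome-wide, so uncovered bases on header-declared chromosomes are explicit
zeros.

BAM coverage counts every aligned read's reference span — primary,
secondary and duplicate alignments alike, any MAPQ, no fragment extension
and no normalization. Overlapping bedGraph intervals are rejected rather
than summed: the format carries values, not events, and summing would
silently corrupt normalized tracks. Wiggle `span > step` is rejected for
the same reason (self-overlap).

## Track storage and summary levels

A `SignalTrack` holds one float64 array per chromosome in memory, plus
summary levels: NaN-aware (sum, count) pairs for blocks of width 2, 4, 8, …
up to the chromosome length. A binned query uses the coarsest level whose
block width is at most half the bin width, resolving full blocks from the
level and only the fractional edges at base resolution. This mirrors the
zoom-level strategy of indexed binary track formats while remaining exactly
testable: level-based and base-level results agree to well below 1e-6
(the only differences are float summation order).

In-memory storage is appropriate for the genome sizes this package is
exercised at (up to a few Mb per chromosome in the test suite and tens of
Mb in practice); a memory-mapped or windowed backend would be the natural
extension for mammalian-scale genomes, and the indexed bigWig written by
`convert_to_indexed` is the interchange point for such tools.

## The anchoring engine

For point anchors (start / end / center), bins of width `bin` tile outward
from the anchor, which sits on a bin edge — the left edge of the first
downstream bin, matching the TSS-at-zero convention of metaplot figures.
When a flank length is not a multiple of the bin width, the outermost
(furthest from the anchor) bin is truncated. The column count is therefore
`ceil(upstream/bin) + ceil(downstream/bin)`, plus `body_bins` in scaled
mode. Minus-strand features are computed over the mirrored genomic window
and the row reversed, so a column always means one biological offset;
`ignore_strand` disables the reflection. The center anchor uses the floor
midpoint, a deterministic tie-break for odd-length features.

Scaled ("both ends") mode stretches each feature body to `body_bins`
windows of fractional width L/body_bins; each output is the length-weighted
mean of the covered bases (missing excluded from both sides of the
fraction). Flanks reuse the point-mode `bin` width, as no separate flank
parameter exists. For plotting, the body is drawn on a pseudo-axis where
each body bin is `bin` bp wide, flanks in real bp.

Defaults: `upstream=1000`, `downstream=1500`, `bin=10`. A 10 bp bin is fine
enough for 1–2 kb windows while keeping matrices small; all are plain
parameters.

Bit-level reproducibility note: mirroring a genome and flipping all strands
reverses every matrix row exactly in the point modes. In scaled mode the
fractional window weights make the result order-dependent at the ~1e-13
level unless the feature length is a multiple of `body_bins`; the generic
guarantee is agreement with a per-base reference to 1e-9.

## Profile statistics

Per matrix column, over non-missing entries: sample mean, sample standard
deviation with n−1 denominator, standard error s/√n, and a
normal-approximation 95% interval with z = 1.959964. With the hundreds to
thousands of rows typical of feature sets, the Student-t correction is
negligible; columns with n = 0 have missing mean and columns with n < 2
missing SE/CI. Missing entries are excluded per column, not by dropping
rows, preserving information near chromosome edges. Bootstrap intervals
and trimmed means are out of scope.

## Clustering

All three algorithms run on the same assembled input: the column-wise
concatenation of the matrices selected by the inclusion mask, with missing
entries imputed as 0.0 — distances need complete vectors and zero is the
neutral value for coverage-like data. Display matrices are never imputed.

- **k-means**: Lloyd iterations to convergence (maximum centroid shift
  < 1e-6, at most 300 iterations) from a seeded greedy farthest-point
  initialization (first center a seeded random row, each next the row
  farthest from its nearest chosen center). Deterministic given the seed —
  reproducibility of figures is valued over the marginal loss quality of
  random restarts. An emptied cluster is re-seeded at the worst-fit point.
- **Hierarchical**: Euclidean distance, Ward linkage (scipy), tree cut to
  k clusters. Ward shares k-means' variance objective, so the two are
  directly comparable; the result is deterministic.
- **SOM**: rectangular grid, codebook initialized from seeded random rows,
  batch training for 100 epochs with a Gaussian neighborhood whose radius
  decays linearly from max(grid dims)/2 to 0.5. Rows are labeled by best
  matching unit; empty units are dropped so numbering is dense. A bare
  neuron count n is interpreted as a 1×n grid.

Row strength is the per-row mean of the clustering input; clusters are
renumbered 1..C by decreasing mean strength (ties broken deterministically),
making "cluster 1" meaningful and stable across methods, seeds and reruns.
Display order is cluster blocks, each optionally sorted by descending
strength. The exported spreadsheet (chrom, start, end, name, strand,
cluster, display_rank — one row per feature in display order) round-trips:
filtering to one cluster and converting to BED reproduces that subset
bit-exactly.

## Motif density

Patterns are IUPAC strings compiled to character classes over ACGT only, so
N in the genome matches nothing — assembly gaps cannot create phantom
density (this includes pattern N positions). Overlapping matches all count.
With both-strand scanning the reverse complement is scanned independently
and reported at its leftmost base; palindromic patterns therefore count
double, a predictable convention that is simply documented. The window
(default 200, rounded up to odd 201) is centered on each base; truncated
windows at chromosome ends use the truncated width as the per-kb
denominator. Per-kb normalization is the default so densities are
comparable across window choices; raw per-window counts are available.

## Collection and cache

The collection is a plain directory — `registry.json`, normalized stored
files, and a matrix cache — chosen over an embedded database for
inspectability and portability. Entries are keyed by a content hash, so
re-adding identical bytes is a no-op; text and alignment signal formats are
converted to indexed bigWig at add time, features to normalized 6-column
BED. The cache key is a pure function of (signal content hash, feature
content hash, anchor parameters): changing any anchoring parameter
invalidates exactly the affected entries, and reruns are pure cache hits.
A failing pair is logged and skipped; the remaining grid still computes.

## Rendering

Every render writes a JSON manifest next to the PDF (legend lines, axis
limits, row order, cluster boundaries, per-panel color limits), making
visual output verifiable without image diffing. Heatmap color scales are
clipped per panel at the (0.01, 0.99) quantiles of the panel's non-missing
values by default — coverage outliers otherwise flatten the gradient — and
missing cells render in a neutral grey distinct from the gradient.
Defaults are a qualitative palette for profile lines and a white→blue
gradient for heatmaps; all are overridable.

## Synthetic data: what it emulates and what it does not

`synth.make_scenario` emulates a TSS-centric chromatin study: genes in five
expression classes on a random-sequence chromosome, a promoter mark peaking
~150 bp downstream of the TSS with class-scaled height, a variant-histone
mark flanking the TSS at ±250 bp, and a gene-body mark whose per-gene
pattern is planted as one of three subtypes — bidirectional (covering the
whole analysis window), unidirectional (downstream only) or absent — with
heights ordered so the subtypes map to clusters 1..3 under strength
renumbering. Per-base Gaussian noise (default SD 0.5, a realistic
bin-level signal-to-noise for normalized coverage) is added to every track;
SD 0 gives the noise-free variant with analytically exact profiles. Tracks
are written as fixedStep wiggle so every consumer exercises the
text-to-indexed path, and all outputs are byte-identical for a given seed.

The generator does not emulate read-level sampling noise, mappability
artifacts, copy-number variation, overlapping genes, or correlated
biological heterogeneity between marks. Passing tests therefore demonstrate
the correctness of the aggregation, statistics, clustering and I/O
machinery under known ground truth — not the biological robustness of any
particular clustering on real data.

Test and acceptance problem sizes (150 features, ~750 kb genome for the
full workflow; a few kb for unit fixtures) were chosen to keep the suite
fast while exercising every code path; all sizes are parameters of the
generator.

## Known limitations

- Tracks are fully materialized in memory (see above).
- BAM coverage ignores CIGAR structure beyond the reference span: spliced
  or padded alignments contribute their whole span. Spliced-aware coverage
  and read normalization (RPKM/CPM) are out of scope.
- BED thick/block columns (7–12) are ignored for anchoring.
- No position weight matrices or repeat masking in motif scanning.
- No automatic choice of k, consensus clustering, or toroidal SOM
  topologies.
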