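# Methods

This note documents the models, conventions, numerical choices and known
limitations of `cnvcat`, in the order data flows through the toolkit.

## Coordinates and domain model

All in-memory coordinates are 0-based half-open (BED convention).  Readers
for 1-based formats (SAM `POS`, or tables imported with
`ColumnMap(coordinate_base=1)`) shift at the boundary; writers emit BED
semantics unchanged.  Zero-length intervals are rejected at construction —
no measurement can anchor to an empty span — and chromosome names are
matched verbatim (`chr1` ≠ `1`), because silent renaming corrupts joins
across tracks; any aliasing must be done explicitly at import.

A `Track` is an immutable, sorted sequence of interval-anchored values plus
an append-only history of `ProcessingRecord`s (operation, parameters,
ISO-8601 timestamp, parent track).  Every transform returns a new track;
the parameter mapping is required to reconstruct the call exactly and
round-trips through JSON.  Timestamps are wall-clock by design — they are
provenance, not data — so history files are the one output excluded from
the byte-identical-reruns guarantee; all data outputs of a seeded command
are byte-reproducible.

## Noise: the raw MAD

Noise is estimated as the *raw* median absolute deviation
`median(|vᵢ − median(v)|)`, without the 1.4826 Gaussian consistency factor.
The quality score below is defined directly in MAD units, so rescaling to a
pseudo-SD would only change all scores by a constant factor.  When a
segmentation exists, the reference switches from the track median to each
probe's segment mean (residual MAD), which removes the signal's
contribution to the spread estimate; on a clean step profile the residual
MAD converges to the MAD of the injected noise alone.  The MAD is computed
genome-wide by default; a per-chromosome variant is available
(`call_thresholds(..., per_chrom_noise=True)`) for profiles with
chromosome-scale artifacts.

## Threshold calling

Fixed mode applies user thresholds verbatim.  Dynamic mode derives them as
`median ± k·MAD` with default `k = 3` — the common robust outlier rule —
and refuses to run when the MAD is zero (a degenerate, noise-free profile;
the error message points to fixed mode).  Calls are maximal runs of at
least `min_probes` consecutive same-direction probes beyond the threshold;
an optional `max_gap` (bp) splits runs across large genomic gaps.  Dynamic
thresholds are shift-equivariant: adding a constant to every probe moves
both thresholds by that constant and leaves the *called regions* unchanged
(their reported means shift with the data; a shift large enough to flip the
sign of a region's mean also flips the call's direction label, since a
"gain" is definitionally positive).

## Circular binary segmentation

For probes x₁…xₙ on one chromosome, every arc (i, j] of the circularized
sequence is scored with the standardized mean-difference statistic
`Z(i,j) = |mean(x[i:j]) − mean(rest)| / √(1/k + 1/(n−k))`, `k = j − i`.
The common variance factor is omitted because significance is assessed by
permutation, where any constant scale cancels.  Wrapping arcs are not
enumerated separately: a wrapping arc has the same statistic as its
contiguous complement and implies the same two breakpoints.

The maximum of Z is found exhaustively (vectorized over all arcs with both
sides ≥ `min_width`, default 2).  Its significance is the permutation
p-value `(1 + #{perm ≥ observed}) / (1 + n_perm)` over `n_perm` random
permutations of the probe values (default 10,000; the test suite and
acceptance script use 1,000).  If p < α (default 0.01) the implied
breakpoints are accepted and both sides are segmented recursively.  Probes
are treated as an ordered index sequence; inter-probe distance is ignored,
matching the standard probe-index formulation.  Ties in the maximum are
broken by smallest (i, then j).  No post-hoc segment-merging ("undo")
heuristics are applied.  The permutation test makes the procedure
stochastic, so a seed is mandatory in the CLI.

Measured behavior under the default study conditions (computed by
`scripts/acceptance.py`, not asserted here): a step of 1.0 at probe 50 of
100 with noise SD 0.05 is localized within ±2 probes in ≥ 95 of 100
replicates, and pure-noise profiles split in ≤ 5% of replicates at α = 0.01
(within binomial tolerance).

## Hidden Markov model

Three states (loss, neutral, gain) with Gaussian emissions; default means
(−0.5, 0, +0.5) reflect mosaicism-compressed single-copy changes on the
log2 scale, default common SD 0.15, uniform start distribution, and a
symmetric transition matrix with self-probability 0.99 (off-diagonal mass
split evenly).  Decoding is exact Viterbi in log space; backtrace ties
resolve to the lowest state index, making the path deterministic.  Maximal
same-state runs become segments carrying their state label, so calling can
map loss/gain directly.  Each chromosome is decoded independently (the
chain does not persist across chromosome boundaries).

## Quality score

`quality = segment mean / MAD`.  Signed, dimensionless, homogeneous of
degree zero under common rescaling of data and noise.  Undefined at
MAD = 0, which raises a "degenerate noise" error rather than returning an
infinity.  The BED5 export maps quality to the UCSC score column as
`round(100·|q|)` clamped to [0, 1000]; the TSV export keeps full precision.

## Common data matrix

Bins come from one of three schemes: fixed-width tiling of every chromosome
(`ceil(L/width)` bins, last bin truncated), annotation intervals (genes),
or custom intervals.  The cell statistic is the overlap-length-weighted
mean of the measurements touching the bin — each measurement weighted by
the bases it shares with the bin — which is value-preserving for constant
sources and fair across platforms with unequal probe lengths.  This equals
a per-base accumulation: sum of values over all (base, measurement)
incidences divided by their count.  Overlapping annotation intervals are
scored independently (no flattening); a measurement may contribute to
several rows.  A bin with no overlapping measurement is *missing* and
exports as `NA`, never 0, because 0 is a meaningful log2 ratio.

## Region-of-interest summaries

Each ROI is split into exactly 10 half-open sub-bins whose widths differ by
at most 1 bp (the `width mod 10` remainder goes to the leftmost bins, so
widths sum exactly).  ROIs shorter than 10 bp are rejected.  Sub-bin values
use the weighted rule shared with the data matrix; the interval-level mean
and SD are *unweighted* over the values of all overlapping measurements —
the plain average of a probe list — with the SD using the n−1 denominator
and reported as missing below 2 values.  Summaries are sorted by mean,
descending by default (gains first; configurable), ties by (chrom, start),
ROIs with no data last; ranks are 1…n.

## Group analysis

The absolute view is a lossless per-call table (sample, group, coordinates,
direction, mean log2 ratio, quality), sorted by (group, sample, chrom,
start); mean and quality are exported precisely so downstream plotting can
drive opacity/saturation from them.  The relative view counts, per bin ×
group × direction, the *distinct samples* with at least one overlapping
call, divided by the group size.  Consequences: multiple overlapping calls
by one sample count once; a sample with both directions in a bin counts in
both; samples without any call still count in the denominator.  The overlap
criterion is ≥ 1 bp by default; `min_overlap_frac` tightens it to a
fraction of the call's length.  Records are emitted for every
(group, direction) of every bin touched by any call — including explicit
zeros — while completely untouched bins are omitted (their frequencies are
0 by definition).

## Synthetic data generators

The generators define the conditions under which the machinery is tested.

* `make_acgh_track`: evenly spaced 60 bp probes (100 per chromosome by
  default), value = sum of overlapping event shifts + N(0, sd) with default
  sd 0.15 (typical aCGH probe noise; recovery checks use 0.05 with a unit
  step, a clean single-copy change).  Events may not overlap each other, so
  the planted truth is unambiguous and returned alongside the track.
* `make_cohort`: every group member carries the group's shared events;
  private events are Poisson-distributed per sample (default widths 500 kb,
  |shift| 0.8) at uniform random positions.  Ground truth for the shared
  events is retained per sample.
* `make_sam_fixture`: single-end 50 bp reads, flag 0, MAPQ 60, placed by a
  piecewise-constant rate (uniform base rate, multiplied inside enrichment
  intervals), written as plain-text SAM.

All generators take an explicit seed and are bit-reproducible.  They do not
model GC/wave artifacts, probe-specific variance, sequencing error, or
paired ends — so green tests demonstrate algorithmic correctness under
idealized noise, not robustness to platform artifacts.

## NGS coverage ratios

BAM/SAM import counts mapped primary alignments (MAPQ-filtered) into
fixed-width bins by the leftmost aligned base — the simplest well-defined
assignment rule.  The log2-ratio conversion is
`log2(((t+p)/T) / ((r+p)/R))` with pseudocount `p = 1` and `T`, `R` the
pseudocount-augmented library totals; bins empty in both libraries are
omitted.  Note that library-size normalization makes the transform
insensitive to any global multiplicative difference: a test library that is
a uniform 2× of the reference yields ratios of 0, not 1 — only *relative*
enrichment is visible, which is the intended semantics for copy-number
data.  The construction is antisymmetric under swapping test and reference.

## Numerical and engineering choices

* Exported floats use `repr` (shortest round-tripping decimal), so every
  export→import cycle is exact, not approximate.
* The overlap index is an interval tree per chromosome; its contract is
  multiset equality with a linear `overlaps()` scan, results sorted by
  (start, end) with ties in insertion order.  Duplicate intervals are
  preserved (co-located probes are real).
* Problem sizes in the test suite and acceptance script — 100-probe CBS
  replicates at 1,000 permutations, 10⁴-interval index checks, 3¹⁰-path HMM
  enumerations — were chosen so each oracle comparison is exhaustive at a
  scale where exhaustion is feasible while the whole suite completes in
  minutes on one CPU.

## Known limitations

* CBS cost is O(n² · n_perm) per tested split; very dense tracks (≫ 10⁴
  probes per chromosome) need down-binning first.
* No GC-content or wave normalization; inputs are assumed pre-normalized.
* SOFT support is deliberately minimal: one ^SAMPLE block with an embedded
  table, positional columns by name or explicit `ColumnMap`, optional
  probe-position platform mapping.  No GEO network access.
* Single genome per project; no multi-assembly lift-over.
* Paired-end fragments are counted as two independent reads by position.
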