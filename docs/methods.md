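# Methods

This note documents the models, conventions and numerical choices behind
`s1seqmap`, and what the simulator-based validation does and does not
establish about real data.

## Coordinate and endpoint conventions

All coordinates are 0-based, half-open (BED dialect); an interval
[a, a+1) is the single base at position a. 1-based coordinates appear only
in SAM input, which pysam converts on read.

The resection endpoint of an accepted alignment is the first aligned
genomic base of the adaptor-proximal mate (read 1): the leftmost aligned
position for a forward alignment, counted on the top strand, and the
rightmost aligned position (leftmost + span − 1) for a reverse alignment,
counted on the bottom strand. The adaptor itself is trimmed upstream, so
the first aligned base is the nucleotide adjacent to it — the
ssDNA/dsDNA junction. Acceptance requires: first-in-pair, properly
paired, not flagged duplicate, MAPQ ≥ 20 (configurable). Second mates
carry no endpoint information (they start at a random sonication break)
and are rejected with a categorized tally, as are duplicates, improper
pairs and low-MAPQ reads. Built-in duplicate removal by
(chromosome, orientation, endpoint, mate position) is available but off by
default: upstream pipelines normally mark duplicates already, and
double-filtering would bias counts.

RPM normalization multiplies every cell by 10⁶ / (total accepted
endpoints), so the genome-wide sum over both strands is 10⁶.

## Hotspot anchoring and co-orientation

Hotspots are anchored at the integer midpoint floor((start+end)/2) of
their BED interval; for even-width intervals this is the left of the two
middle bases, a deterministic convention. Ranks are assigned by descending
strength with ties broken by genomic order, so rankings are reproducible.

The anchored matrix holds, per hotspot and strand, the per-base signal at
offsets −W..+W from the center (default W = 2500 bp, the minimum needed by
the +2500-bp background rule; heatmaps default to W = 2000 so the 4001-bp
local-normalization window exactly covers the matrix). Offsets beyond a
chromosome end are zero-filled and the hotspot flagged clipped; zero-fill
biases equal-weight averages least for these rare cases, and callers can
drop flagged rows for a strict analysis.

Co-orientation folds the bottom strand through the center,
combined[h, x] = top[h, x] + bottom[h, −x], so resection signal from both
DSB sides accumulates at positive offsets. The average profile weights
hotspots equally (not by strength): the averaging is a shape summary, and
equal weighting keeps weak hotspots from being invisible. Smoothing is
applied after averaging.

## Smoothing

Hann smoothing uses the symmetric window
w[k] = 0.5·(1 − cos(2πk/(N−1))), k = 0..N−1, normalized to sum 1
(numpy's `hanning`), with N = 151 for display and N = 51 for fine
comparisons. At the array edges the weights falling outside the support
are dropped and the remainder renormalized to sum 1 — a mass-preserving,
parameter-free boundary rule under which constants are exact fixed points.
N = 3 gives weights (0, 1, 0) and is the identity.

## Internal normalization and summary statistics

Internal normalization subtracts the background — defined as the profile
value 2,500 bp to the right of the center, where resection signal has
decayed — clamps negatives to zero, and divides by the resection peak,
the maximum over offsets [100, 2500]. Restricting the peak search to
[100, 2500] prevents the central peak (a distinct, method-dependent
signal) from setting the scale. The output is invariant under positive
scaling of the input, which is what makes shapes comparable across
libraries of very different signal:noise.

Mean resection length: background-subtract, clamp, zero all signal at
offsets < 100 or > 2500, partition [100, 2500] into 24 bins of 100 bp
([100,200), …, [2400,2500]), and return the fraction-weighted mean of the
bin midpoints 150, …, 2450 nt. Midpoints (not left edges) are unbiased
for uniform within-bin mass. The estimator runs on the raw (unsmoothed)
average profile; a smoothed profile may be passed explicitly but
smoothing slightly blurs the window edges.

Windows for the companion statistics (all relative to the center):
central sum [−1500, +100) half-open; resection sum [+100, +2500]
inclusive — offset +100 is a boundary of both windows in the figure
conventions and is assigned to the resection window only, to avoid double
counting; total signal [−1500, +2500]; per-hotspot strength =
bottom-strand sum over [−2000, −250] plus top-strand sum over
[+250, +2000], both inclusive, which excludes the central region entirely.

Replicate correlation excludes hotspots with zero signal in either
replicate and computes Pearson r on log10 strengths (strengths span
orders of magnitude; the log makes the comparison relative). The 10⁻²-RPM
floor seen in scatter plots is a display transform and never enters r.
Replicate CV is 100·SD/mean with the sample SD (n−1).

## H-DNA mirror-repeat scanning

The scanner reports every maximal occurrence of C(TC)ⁿ with n ≥ 20
(default) on either strand: the regex `C(?:TC){n,}` on the top strand
(pyrimidine strand +) and `G(?:AG){n,}` (pyrimidine strand −), matched
case-insensitively. Greedy leftmost matching yields exactly the maximal,
non-overlapping runs; any non-ACGT character (N) breaks a run. Each hit
spans 2n+1 bases and is anchored at its middle base, a symmetric choice.
Motif profiles relabel map strands per hit as pyrimidine/purine, flip −
hits so all hits share one orientation, and average without co-orientation
folding — the two read classes are reported separately because H-DNA
cleavage marks the pyrimidine strand specifically.

## The simulator

The simulator is the package's validation instrument: it generates maps
with the generative structure of the real libraries plus per-read truth
labels, so every estimator can be checked against known ground truth.

Genome: i.i.d. uniform ACGT sequence; hotspot centers uniform with
≥ 10 kb separation and a margin of (max resection + 2 kb) from chromosome
ends; strengths log-normal (default location 0, scale 1, spanning roughly
two orders of magnitude as real hotspot strengths do); C(TC)20 motifs
planted non-overlapping, ≥ 10 kb from any hotspot, with one guard base on
each side (A for pyrimidine-+ motifs, C for −) so the planted run is
exactly maximal and scanner recovery can be asserted exactly.

Reads partition into four labeled sources:

- **noise** (default fraction 0.05): uniform position and strand —
  a stand-in for random fragmentation background;
- **H-DNA**: weight w = rate(pH) · n_motifs · intensity-per-motif
  (default intensity 0.04/motif, so 50 motifs at permissive pH take ~2/3
  of the non-noise budget, reproducing the observation that a large
  fraction of reads maps to motifs at low pH); reads uniform within a
  motif on its pyrimidine strand. rate(pH) is a step function — 1.0 at
  pH ≤ 4.3, 0.05 below 4.7, 0 at ≥ 4.7 — encoding the observed series
  (weak at 4.5, undetectable at ≥ 4.7) qualitatively. pH affects nothing
  else: the hotspot-RPM gain at high pH emerges purely from read-share
  renormalization under the fixed budget;
- **central** (fraction per method: s1 0.2, exo7t 0.1, exot 0 — chosen
  for relative ordering, since no quantitative per-method fraction is
  established): for S1, offset u ~ |N(0, 150 nt)| with top-strand reads
  at center − u and bottom at center + u (opposite polarity; the 150-nt
  scale is a modeling choice for "slightly offset", exposed in the
  config); for Exo7/T, position center + ε with ε uniform on {−1, 0, +1}
  (the 2-nt 5′ overhang) and strand matching the DSB side; ExoT
  structurally cannot emit central reads;
- **resection**: hotspot ∝ strength, side fair coin, distance d from a
  gamma with mean 1100 nt and shape 12, truncated to [100, 2500] by
  rejection and rounded to integer; right side → top strand at
  center + d, left → bottom at center − d. The gamma family is a modeling
  choice (the real distance distribution is unknown); mean ≈ 1.1 kb and a
  unimodal flank peak match the reported resection summaries, and shape
  12 gives a realistic ~300-nt spread.

All randomness flows through numpy's PCG64 seeded from
SeedSequence([seed, stream]) with separate integer streams for genome and
reads, so identical (config, seed) produces byte-identical outputs across
platforms; the PRNG name is recorded in run provenance.

`truth_mean_resection` is the independent oracle for the resection-length
estimator: a 10⁶-draw Monte-Carlo mean of the integer-rounded truncated
gamma under a fixed oracle seed, sharing nothing with the estimator but
the distribution parameters.

### What the simulator does not model

Sequence-content biases (mappability, GC), PCR duplication, sonication
fragment-length effects, read-level errors, chromatin accessibility, DSB
interference between hotspots, and any coupling between pH and hotspot
biology. Passing tests therefore demonstrate that the *computational
method* is correct and self-consistent under the stated generative
assumptions — estimator recovery, normalization invariances, method
contracts — not that real libraries satisfy those assumptions.

## Problem sizes

Validation runs use one simulated chromosome of 4–20 Mb, 40–200 hotspots
and 1.2–5×10⁵ reads — large enough that the resection-length estimator's
Monte-Carlo error (< 1 nt at 5×10⁵ reads) is negligible against its
±30 nt acceptance band, and the motif-peak pH ratio exceeds 100× with
wide margin.

## Degenerate inputs and tie-breaks

Empty libraries raise on RPM normalization; profiles with no signal in
[100, 2500] after masking raise a no-signal error rather than returning
0; all-zero heatmap rows are left zero and flagged instead of dividing by
zero; hotspot-strength windows are clipped at chromosome ends; strength
ties in ranking break by genomic order; u = 0 central reads sit exactly
on the center and are counted on their drawn strand.
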