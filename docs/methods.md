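# Methods

This note records the models and procedures the package implements,
the defaults and why, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## Coordinates and conventions

All internal coordinates are 0-based half-open; GFF3 input (1-based
closed) is converted at the boundary. Genomes are circular by default
(the organisms these experiments target carry circular chromosomes);
a fragment spanning the origin is one record with `end > genome
length`, which wraps in every coverage and window computation and
stays a single record on BED output so write∘read is the identity.
The dyad of a fragment or peak is `floor((start+end)/2)` — for
even-length fragments the base left of center, applied uniformly
everywhere. Size classes are inclusive on both ends: small = [40, 65]
bp, large = [70, 100] bp; inclusivity is a package choice (recorded in
track metadata), the bounds themselves are the standard footprint
classes.

## Coverage and normalization

Coverage counts fragments overlapping each base. RPGC scaling
multiplies by `effective_genome_size / Σvalues`, so the mean coverage
over the effective size is 1; it is scale-invariant and idempotent.

Replicating cells over-represent origin-proximal sequence. The
correction divides the MNase track by its sonicated-input track
smoothed over **10 kb** — smoothing prevents input sampling noise from
propagating into the signal, while the copy-number gradient varies on
a much longer scale and survives smoothing — and converts the ratio to
a Z-score (mean 0, sd 1, computed over all positions). Zeros in the
smoothed input abort with an instruction to set an explicit
pseudocount; a silent pseudocount would distort ratios unnoticed. When
no input exists, the same procedure runs against a **250 kb**-smoothed
copy of the signal itself; with the smoothing window at or beyond the
genome length this degenerates, by construction, to global-mean
normalization. The correction removes any multiplicative bias shared
by signal and input whose spatial scale is much larger than the
smoothing window; on a planted 2:1 linear gradient over 200 kb the
residual |Spearman ρ| is below 0.01.

An optional `cap_percentile` post-processor thresholds raw tracks at
an upper percentile (duplicate-bias guard for sparse datasets);
default off. Replicate pooling is concatenation of fragment lists
before coverage. Spearman correlations use average ranks for ties.

## Peak calling

Candidate dyads are local maxima of the coverage track after a
low-pass Fourier filter that keeps the lowest `keep_component_fraction`
of rFFT components (DC always kept, so the mean is preserved; the
filter is linear and idempotent). The default fraction is 0.02,
typical for footprint-scale structure; the demo and validation
simulations use 0.04, matching their shorter genomes (the retained
period should be comparable to the footprint width; fraction ≈
2/period). Equal-valued plateau maxima report their leftmost
coordinate.

Each candidate is scored as the **filtered summit height in units of
the genome-wide raw distribution**, `(filtered[c] − mean(raw)) /
sd(raw)`, and calls below 2.5 are discarded. Scoring the filtered
summit rather than the raw value at the summit is deliberate: the raw
value at a candidate position carries the full high-frequency noise
variance, so on a pure-noise track some of the ~`n_keep/2` candidate
maxima would always clear any threshold near 2.5, whereas the filtered
summit concentrates only footprint-scale signal. With this choice,
planted footprints of signal-to-noise ≥ 4 are recovered at ≥ 95 %
within ±5 bp while 100 pure-noise simulations yield zero calls. The
score is invariant under a shared affine rescaling of the tracks, so
threshold decisions do not depend on sequencing depth. An exactly
constant track has no empirical scale and is rejected.

Peak extent is the contiguous region of the filtered track at or above
half the summit height — parameter-free and directly testable. Extents
≤ 65 bp are narrow, ≥ 70 bp broad; the 66–69 bp gap mirrors the gap
between fragment classes and such peaks are kept unclassified rather
than forced into a class. Cross-condition overlap uses greedy
best-intersection matching at ≥ 50 % reciprocal overlap (configurable).
Decile decomposition ranks broad peaks by `mean(small) / (mean(small)
+ mean(large))` over the extent and splits them into ten equal-count
groups, any remainder spread from decile 1 (the small-poorest) upward.
Intergenic enrichment classifies a peak by its dyad, reports the ratio
to the genome's intergenic fraction, and an exact upper-tail
hypergeometric p-value (log-space below 1e-300).

## Dyad asymmetry

For each broad peak, `a` and `b` are the mean small-fragment coverage
over `[c−h, c)` and `[c, c+h)`; `h` defaults to half the peak extent
(the averaging span is not fixed by convention; half-extent keeps it
proportional to the footprint). The peak is flipped when `a/b < 1`;
ties and the all-zero case stay as-is; `b = 0 < a` is ratio +∞, not
flipped. Orientation is involution-consistent: reverse-complementing
the genome swaps a and b and every flag. Re-oriented aggregation
reverses flipped windows before the elementwise mean. Length × position
occupancy matrices count non-normalized fragment dyads at signed
offsets from (possibly flipped) reference points; totals are conserved.

## Nucleotide profiles

Fragments are unstranded after merging, so profiles are computed on
the reference strand; this is what makes RR vs YY asymmetry across the
dyad meaningful as a reference-strand property. Offset 0 is the dyad
base; the dinucleotide at offset d spans `[dyad+d, dyad+d+2)`; offsets
run `[−⌊L/2⌋, ⌊L/2⌋−1]` for reads of length L. The profiling filter
keeps reads with mean quality ≥ 30 (unknown quality is retained, not
failed), ≥ 90 % of their length inside a called peak, and collapses
coordinate duplicates to their first occurrence. Background
expectations average the class proportion over 25,000 uniformly placed
regions of equal size. Complementary partitions (SS+WW+SW,
RR+YY+RY+YR) sum to 1 at every offset by construction. Positions
involving N never match any class; windows containing N are excluded
from k-mer statistics.

## k-mer LASSO

Features are `count(kmer fully inside the w-window centered at p) /
(w − k + 1)` for all 340 k-mers (k = 1..4) and windows w ∈ {21, 51}
(the short window captures read-internal composition independent of
nuclease cut-site context). Materializing all 680 columns at 100 kb
would need ~0.5 GB, so the feature set is lazy: single columns are
computed in O(n) and only the ≤ 80 selected columns are ever stacked.

Pre-selection ranks features by |Pearson r| with the normalized
response over the training region — the first third of the genome, so
evaluation on the remainder is spatially disjoint — and keeps the top
80 (ties: lexicographic k-mer, then smaller window; constant features
score 0). The L1 model is fitted on standardized features over a
100-point log penalty grid spanning `[1e-4, 1]·λ_max`; CV folds are
**contiguous blocks** of the training region because adjacent base
pairs are near-duplicates and random folds would leak. The penalty is
chosen by the **one-standard-error rule** (largest penalty within one
SE of the minimum mean CV error): under the minimum rule a fit to pure
noise admits spurious features in a substantial fraction of runs,
while the 1-SE rule returns the empty model there and leaves strong
planted signals untouched; the minimum rule remains available. Fitted
weights are returned on the original feature scale, so predictions are
invariant to feature scaling. Training positions may be subsampled
every m-th base (m is recorded in the model); m = 3 is the default in
the validation runs — adjacent positions are ~97 % redundant at these
window sizes. Responses are the normalized (input-corrected,
standard-scored) tracks, separately per size class when both are
modelled. In human-facing output the dinucleotide "GC" is printed GpC
(G followed by C), the field's notation.

## EMSA quantification

A design is a set of 100 bp backbone oligos, each with 8
non-overlapping randomized dinucleotide slots. Reads are assigned by
exact match at all fixed positions — no mismatch tolerance, since the
16 randomized bases make edit-distance assignment ambiguous; designs
in which two backbones agree at all fixed positions are rejected at
load. `P_slow` is tabulated per composition class: G+C content in
integer percent over the **full oligo** (backbone context included —
configurable) or the count of GpC steps. The summary statistic is a
Pearson correlation of (composition, P_slow) weighted by per-class
read counts; a percentile bootstrap CI over reads is available.

## The synthetic generator

Every generator is a pure function of its spec and one global seed;
per-operation sub-streams are derived deterministically, so a dataset
is reproducible piecewise. What it emulates, and the defaults chosen
as the study conditions:

- i.i.d. sequence per GC segment (segments tile the genome; realized
  GC within ±2 % of target for segments ≥ 5 kb).
- Occupancy = intercept + Σ weight·windowed k-mer frequency, shifted
  (by −min, when negative) and clipped to non-negative.
- Fragment lengths: two discretized Gaussians truncated to [20, 200]
  bp at modes 50 and 85 bp (sd 5 and 7), equal mixture by default;
  the twin ~85 bp sub-modes seen in real digests are treated jointly,
  and the generator does not attempt to reproduce them. Duplicate
  structure: a 5 % fraction of records are exact coordinate copies.
- Replication gradient: copy number decays linearly with circular
  distance from the origin, 2:1 origin:terminus by default.
- Broad footprints: per nucleation site, equal numbers of large
  fragments centered on the site and small fragments centered at
  ±(large−small)/2, on the site's preferred edge with probability
  `edge_bias`; the preferred edge is drawn once per site and recorded
  as truth metadata.
- EMSA pools: randomized slots filled uniformly; band label "slow"
  drawn with probability `logistic(intercept + Σ affinity·feature)`
  with GpC-count and GC-content features; per-read band probabilities
  and source backbones are kept as truth.

What it does **not** emulate: sequencing error and base-quality
structure (a single scalar quality per read at most), adapter/trimming
artifacts, MNase cut-site sequence bias, chromatin context beyond the
planted k-mer model, and the twin large-fragment sub-modes. Passing
tests therefore demonstrate correctness of the analysis given mapped
fragments with these statistical features — not robustness to
upstream artefacts real data may carry.

## Problem sizes in the validation runs

Coverage-oracle checks use 100 instances of ≤ 1 kb / ≤ 1000 fragments;
gradient removal a 200 kb genome with 3×10⁵ fragments; peak recovery
50 planted footprints (Gaussian bumps, sd 20 bp, SNR 4, ≥ 300 bp apart)
on 50 kb plus 100 pure-noise tracks of 20 kb; LASSO recovery a 100 kb
genome with five planted k-mers (weights 2.0/−1.5/1.8/−1.2/6.0 for
GC/AA/CCG/TTA/GAGA at window 51 — the 4-mer weight is larger because a
4-mer's windowed frequency has roughly an order of magnitude less
variance than a dinucleotide's, and comparable per-position effect
sizes are what a recoverability study needs) and noise sd = 0.25 ×
signal sd; EMSA sign recovery 10⁵-read pools with planted affinity
±0.15 per GpC step; backgrounds 25,000 regions. The demo pipeline uses
a 50 kb genome and 60,000 fragments.

## Known limitations

- Single-chromosome genomes only; multi-record FASTA is rejected.
- The peak caller has no dyad refinement by fragment-midpoint
  averaging; centers come from the filtered track alone.
- Width classes leave 66–69 bp extents unclassified by design.
- The LASSO response is used as-is; any residual copy-number structure
  inside the training third propagates into the fit.
- No statistical test accompanies the a/b asymmetry; it is a
  descriptive re-orientation device.
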