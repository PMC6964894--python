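# Methods

## Model

`qtcmatch` treats every tracked entity as a moving point object sampled
uniformly in time. The qualitative state of an ordered pair (k, l) over
one inter-sample interval [t1, t2] is the sign of the change of the
Euclidean distance from k to l's *interval-start* position:

    Δ = ||k(t2) − l(t1)|| − ||k(t1) − l(t1)||,
    character = '-' (Δ < −ε), '0' (|Δ| ≤ ε), '+' (Δ > ε).

This is the basic two-character QTC variant (QTC_B): richer variants with
side or speed characters are deliberately out of scope. The anchor is the
*other* object's position at the start of the interval; after temporal
downsampling the displacement evaluated is the full displacement between
kept samples. A coincident anchor (k starting exactly on l's position)
needs no special case: Δ ≥ 0 there, giving '+' or '0'.

A *fragment* is a half-open window [start, start + length) over one or
more trajectories of identical length and sampling, plus optional static
anchor points. Per interval, the characters of every *informative* pair —
at least one member moving — form a QTC matrix; static–static pairs are
excluded outright rather than stored as constant ('0','0'), both because
they carry no information and because they would inflate the
normalization denominator. An m-sample fragment encodes to m − 1
matrices.

Because only relative distances enter, encoding at ε = 0 is invariant
under any similarity transform (translation, rotation, reflection,
uniform scaling) applied to all coordinates. Anchoring to absolute
location is opt-in: add static points (e.g. the four field corners) and
translated or rescaled copies of the same movements acquire a positive
distance.

## Sequence distance

Substituting one matrix for another costs the sum over cells and both
characters of the conceptual distance between the characters. The default
table is the conceptual-neighbourhood chain '-' ↔ '0' ↔ '+': adjacent
symbols cost 1, opposite symbols 2, identical 0. The table is exposed as
a configurable `CostScheme` and validated for symmetry, zero diagonal and
the triangle inequality; the default is integer-valued, so all raw
distances are exact integers and platform-reproducible.

Insertion and deletion are charged at the roster's maximum substitution
cost,

    C_max = (C(m + s, 2) − C(s, 2)) · 2 · d_max,

with m moving objects, s statics and d_max the largest character cost.
This makes an indel never cheaper than any substitution, which in turn
gives the distance its metric structure (the cell table is a metric and
indel ≥ substitution implies symmetry and the triangle inequality, which
the test suite verifies empirically alongside an exhaustive-enumeration
oracle for the dynamic program).

The distance between two sequences is the minimum-cost alignment,
computed with the standard (len_a + 1) × (len_b + 1) dynamic program; the
in-row dependency is resolved with a prefix-minimum identity so each row
is a vectorised operation. Normalization divides by
`max(len_a, len_b) · C_max`. That denominator is the tight upper bound on
any alignment cost (substitute min(len) positions at ≤ C_max each, indel
the length difference at C_max), so normalized distances always lie in
[0, 1]; 0 is attained exactly for equal sequences and 1 for an empty
versus non-empty comparison. Two empty sequences compare at 0 by
convention.

Two auxiliary comparisons support analysis and scaling:

- `pairwise_distance` — the position-aligned baseline with no indels,
  defined for equal lengths only. It upper-bounds the edit distance; the
  gap between the two is exactly what the alignment buys on movements
  performed at different speeds.
- `levenshtein_with_cutoff` — the same dynamic program aborted as soon as
  every entry of a row exceeds a caller-supplied threshold (row minima
  are non-decreasing, so the abort is safe). It returns the exact
  distance whenever that is ≤ threshold and `None` otherwise; `None` was
  chosen over a sentinel object as the simplest unambiguous flag.

## Matching pipeline

Candidate generation cuts the recording into fully contained half-open
windows starting at 0, stride, 2·stride, …; a trailing partial window is
never emitted, so a recording of N samples yields
⌊(N − window)/stride⌋ + 1 candidates. Both reference and candidates are
temporally downsampled (keep every f-th sample starting at index 0, drop
the remainder) before encoding; downsampling is the method's main noise
control and cost reduction. Timestamps are kept as 0-based sample
indices throughout — seconds are derived as index × sample_interval —
and non-uniform sampling is rejected rather than resampled.

Windows sharing any original-resolution sample with the reference window
are excluded before ranking; otherwise the reference would trivially
occupy rank 1. Overlap is literal interval intersection of the half-open
index ranges. Ranking sorts by ascending normalized distance with the
earlier start index breaking ties (determinism; no meaningful order
exists among exact ties). Non-overlap filtering is a greedy scan from
rank 1 keeping a window iff it is disjoint from every already-kept
window, after which survivors are re-ranked contiguously and cut to the
top k.

Role permutations are exhaustive: for each window every permutation of
the declared permutable (moving) players is encoded and the cheapest
kept, with the identity assignment always included, so the permuted
distance never exceeds the plain one. Statics are never permuted. No
pruning heuristics are applied — correctness over speed; the factorial
cost confines this to small permutable sets.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `epsilon` | 0.0 m | dead-band below which a distance change counts as '0'. 0 is the canonical continuous definition; ~0.05 m is a reasonable choice against 25 Hz tracking jitter if downsampling alone is insufficient. |
| `window` | reference length (500 samples = 20 s at 25 Hz) | candidate window length; may differ from the reference length — the alignment handles unequal lengths. |
| `stride` | 10 samples (0.4 s) | spacing of candidate windows. |
| `downsample_factor` | 10 | temporal thinning before encoding (25 Hz → 2.5 Hz). |
| cost table | chain metric 0/1/2 | conceptual distances between characters; configurable. |
| `k` | 9 | results returned after non-overlap filtering. |
| field | 105 m × 68 m | pitch dimensions used for the `field-corners` static spec and the generators. |

## Synthetic scenes

The scene generator produces what the matcher expects as input when no
real tracking feed is at hand: 25 Hz trajectories on a bounded pitch. It
emulates

- random-walk "traffic" (reflected Gaussian steps, default step σ
  0.25 m/sample ≈ brisk movement at 25 Hz) with additive Gaussian
  measurement noise (default σ 0.05 m, typical of good camera systems);
- a two-player motif — a 7 m/s parallel sprint followed by a ~110°
  direction change at 4 m/s, i.e. straight runs, a direction change and a
  speed change — planted at annotated, non-overlapping windows, either
  translated only ("exact" in relative-movement terms) or additionally
  rotated and rescaled (scale 0.7–1.2);
- optional time warps built by integer sample repetition/decimation
  (`WarpSegment(start, stop, factor, decimate)`), so a warped fragment
  revisits exactly the original coordinates and any distance to the
  original reflects timing alone.

Planted motif samples are inserted without measurement noise; this is
what makes "exact copy ⇒ distance 0" a constructible ground truth at
ε = 0. Real data would carry noise on every sample, so retrieval there
relies on downsampling and/or a positive ε, and distances to true
repetitions are small rather than zero. The generator also makes no
attempt at behavioural realism — no opponent interaction, no ball, no
tactical structure — so passing retrieval tests demonstrate the
correctness and invariances of the encoding and matching machinery, not
recall on real matches. Every generator is a pure function of its seed;
scenes are byte-reproducible.

## Numerical and design notes

- All default-scheme costs are int64; no floating-point accumulation
  enters the distances. Character extraction compares exact float
  differences of distances against ±ε.
- Rotation invariance of the encoding holds to floating-point round-off;
  the tests use exactly representable or tolerance-checked constructions.
- Degenerate inputs: fragments need ≥ 2 samples to encode; empty
  sequences are first-class values for comparison but are never produced
  by encoding; a zero-length direction vector, non-finite coordinate,
  non-positive scale or empty warp segment raises a validation error.
- Downsampling keeps index 0 and drops the trailing remainder — the
  simplest deterministic rule.
- The time-warp interface expresses slow-down as sample repetition and
  speed-up as decimation, both with positive integer factors; a single
  signed factor was rejected as ambiguous.
- Problem sizes in the test suite (scenes of 1500–3000 samples, windows
  of 100–150 samples, stride 25, thinning factor 5) are scaled-down
  analogues of the full-match geometry (144,086 samples, window 500,
  stride 10, factor 10) chosen so the whole suite runs in seconds while
  exercising identical code paths; the window-count arithmetic is checked
  at full scale, which costs nothing.

## Known limitations

- The encoding is purely qualitative: magnitudes of approach/retreat are
  discarded, so very small and very large relative movements with the
  same sign pattern are indistinguishable.
- Ball possession and play context are not represented; windows spanning
  stoppages are matched like any others and no filtering of dead-ball
  periods is applied.
- Permutation matching is exhaustive (factorial in the permutable set).
- Only 2-D coordinates and uniform sampling are supported; resampling,
  smoothing and sensor fusion are out of scope.
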