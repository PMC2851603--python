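# Methods

This note records the model implemented by `pcans`, the design choices
made where the procedure was genuinely open, the simulator's scope, and
the numerical conventions, so that results can be interpreted and
reproduced without reading the source.

## Peak model and picking

A spectrum is reduced to a peak profile: per peak, the chemical shift at
the apex (ppm), the relative intensity at the apex, and the width at
half-height (ppm).  Only the position is ever altered by alignment; height
and width are carried unchanged (averaged only when peaks merge into a
consensus peak).

Peak picking interprets "zero first derivative, negative second
derivative" on sampled data as a sign change of the first difference from
positive to negative; exact zeros are a measure-zero event on real traces.
Flat-topped plateaus yield their midpoint sample.  The minimum support
(default 8 points) is the contiguous strict rise-then-fall run around the
apex — strict, so flat baseline does not count toward a peak's support.
The neighborhood filter keeps an apex only if it strictly exceeds at least
70 % of the points in a 151-point centered window (truncated, not
discarded, at the spectrum edges; the candidate's own support is included
in the window).  No smoothing is applied before differencing: line
broadening belongs to upstream spectral processing, and smoothing here
would silently change the method.

Width at half-height comes from a triangle fitted to the peak: each side
is the secant from the apex sample to the first flank sample below half
the apex height, and the width is the ppm span of the triangle's base
evaluated at half height.  This construction is exact on exactly-sampled
triangular peaks and converges to the true half-width (2γ) on Lorentzians
for any reasonably dense grid.  Using only the samples immediately
adjacent to the apex instead would diverge as the grid refines (the secant
slope near a smooth apex vanishes), which is why the flank-based reading
was chosen.  A flank truncated by the spectrum boundary is mirrored from
the other side and flagged with a warning.

## Similarity score

Height and width similarities are relative differences scaled by the
larger value; position similarity is the difference scaled by the maximum
acceptable movement `m`.  Weights default to 1/3 each and are validated to
sum to 1.  The position term is deliberately *not* clamped below zero:
enforcement of the movement window is the alignment layer's job, which
substitutes the boundary penalty for any pairing with |Δc| > m, so the
score function itself stays a clean linear form.

Defaults: `m` = 0.04 ppm, `minScr` = 0.60, `gp` = −0.10, naive threshold
0.90.  `bp` defaults to −999: it is a sentinel, and any value far below
every reachable path difference behaves identically (−5.0, accepted via
configuration, gives the same alignments).

## Pairwise alignment

The naive stage anchors pairs whose *every* attribute similarity reaches
the threshold ("across all peak attributes" is read per-attribute, which
also makes the stage strictly more conservative than the DP stage).  The
matching procedure is: all candidate pairs within `m`, ranked by weighted
score, accepted greedily unless a candidate would reuse a peak or cross an
accepted anchor.  This is deterministic and crossover-safe; for the
near-identical peaks the stage targets, greedy and optimal matching
coincide.  Anchors are immutable thereafter.

Unanchored peaks are partitioned into corresponding segments: within each
inter-anchor block, peaks connect across profiles when within `m`, and
connected groups whose ppm spans overlap are merged so each segment maps
to contiguous index ranges on both sides.  Isolated peaks form segments
with an empty opposite side and simply gap.

The segment DP initializes the score-matrix borders as multiples of `gp`
(linear gap accumulation — the recursion's natural completion given
per-peak gap semantics) and prefers diagonal, then up, then left among
equal-score moves, maximizing the number of pairings; move identification
during traceback uses a 1e-9 tolerance, since penalty sums are not exactly
associative in floating point.  A diagonal step scored `bp` (impossible
with the sentinel default, conceivable under pathological user penalties)
is emitted as two gaps, never as a forbidden pairing.  The DP is verified
against exhaustive enumeration of all crossover-free matchings on hundreds
of random small segments.

## Progressive consensus

Profiles are rasterized (stick spectrum on a 0.001-ppm grid, smoothed with
a triangular kernel of 0.01-ppm half-width) and paired greedily by Pearson
correlation, highest first, with at most one bye per round; correlations
are recomputed on the consensus profiles each round, since a consensus is
a new object.  The kernel makes correlation tolerant of sub-window jitter;
grid step and kernel width are exposed as arguments.  Large peaks dominate
the correlation, but pair order is only a heuristic for which profiles
merge first — all peaks are eventually aligned regardless.

A merged consensus peak sits at the median of the union of both sides'
contributor *original* positions — contributors are carried forward
through every round, so the final position is the median over the whole
sample set, not a median of medians.  Height and width are the means of
the two merged peaks' values (the literal reading; a contributor-weighted
mean would be the natural alternative and is easy to add, but changes the
published behavior).  Unaligned peaks pass through unchanged.  The final
consensus defines each original peak's aligned position via its
contributor set; conservation (every input peak exactly once) is asserted
at result construction.

The single-template baseline differs only in the target: every other
profile is pairwise-aligned to one fixed profile, aligned peaks take the
template peak's position, and unaligned peaks pass through at their
original positions without merging across profiles.

## Simulator

The generator emulates urine-like 1H profiles in 2.0–4.10 ppm:

- **Base library** (when no picked-peak table is supplied): 120 peaks,
  positions uniform with 0.012-ppm minimum spacing, log-normal heights
  (median ≈ 5, σ = 0.8 in log), truncated-normal widths
  (0.004 ± 0.0015 ppm, floor 0.0015), plus two dominant creatinine-like
  peaks at 3.05 and 4.06 ppm with ten times the median height.
- **Templates**: two groups by default, 50 peaks each, 37 shared
  (always including the dominant pair) and 13 unique per group.
  Group-unique peaks are placed first with a hard mutual separation of
  max(shift-noise range, 0.05 ppm) — also from the dominant pair — so
  that group identity is well-posed: two groups' marker peaks must never
  be confusable under the configured noise or the typical alignment
  window.  Separation from the shared core is best-effort only, because a
  47-peak core in 2.1 ppm cannot leave 0.05 ppm of clearance everywhere.
- **Noise**: a configured fraction of template peaks is displaced by a
  uniform draw on ± the shift-noise range (bounded ranges read most
  naturally as uniform); height and width are independently perturbed
  multiplicatively (±10 % on 25 % of peaks by default); half the profiles
  receive 1–4 noise peaks at uniform random positions with attributes
  resampled from the (non-dominant) library.

Everything is deterministic under the configuration seed.

**Accuracy** is correct peaks over total non-noise peaks under a plurality
rule: each template peak's reference is the aligned position holding the
most of its instances, and an instance is correct iff it sits at that
reference *and* the position's unique plurality label is its template
peak.  The rule penalizes both splitting one compound over several
positions and merging different compounds into one.  Noise peaks have no
correct partner and are excluded from the denominator, otherwise 100 %
would be unreachable by definition.  Ties (reference position, plurality
label) break deterministically toward the smallest position / count as
no-majority respectively.

### What the simulator does and does not capture

It captures chemical-shift drift, height/width variability, group-specific
signals, dominant-metabolite peaks and spurious extra peaks.  It does not
capture multiplet structure, shoulder peaks, baseline artifacts, peak
overlap at the raw-trace level (profiles are generated directly, not
picked from synthetic traces), or position-correlated drift (each peak
moves independently; the alignment method itself is windowed per peak, so
systematic linear drift is neither modeled nor needed).  Passing
simulation benchmarks therefore demonstrates robustness to attribute
noise, not to picking errors on crowded real spectra.

## Benchmark problem sizes and observed behavior

The benchmark script and the corresponding tests use two groups of 32
profiles (50-peak templates, 13 unique per group), 10 replicate
simulations per condition, and a 5 × 5 noise grid (shift ranges
0.005–0.04 ppm × fractions 0.1–0.5, with ±10 % height/width noise on 25 %
of peaks and noise peaks in half the profiles throughout).

On the two-group comparison conditions (±0.02 ppm on 50 % of peaks) the
consensus alignment reaches ~93 % mean accuracy versus ~87 % for the
single-template baseline averaged over all 64 template choices; the best
single template stays a few points below the consensus.  Over the noise
grid, accuracy is essentially perfect at the low-noise end and declines
smoothly with both the range and the fraction of shift noise.

At the hardest corner (±0.04 ppm — equal to the alignment window — on
50 % of peaks) accuracy drops to ~75 %.  The failure mode is splitting,
not merging: label impurity at consensus positions is essentially zero,
but instances displaced near the window limit can miss their cluster in
the first round (two instances displaced oppositely can be up to 0.08 ppm
apart), and once a subtree's consensus carries both the main peak and such
a splinter, pairwise merging can never fuse them — the main peaks of the
two sides always pair with each other, locking the splinter out.  This
stranding is intrinsic to strictly pairwise progressive consensus; its
magnitude additionally depends on how many template peak pairs sit closer
together than the alignment window, which in this synthetic library
(uniform positions at 0.012-ppm minimum spacing) is substantial.  Results
in this regime should therefore be read as a property of the library
geometry as much as of the algorithm.

## Known limitations

- No multiplet grouping or shoulder-peak deconvolution in peak picking.
- No re-alignment refinement after the final consensus; splinter clusters
  (above) are not re-absorbed.
- The naive stage's greedy matching is order-deterministic but not
  provably optimal for pathological near-threshold configurations.
- Template-mode pass-through peaks from different profiles are left
  unmerged at their original positions.
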