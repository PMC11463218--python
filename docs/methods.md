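# Methods

## Coordinate model

The tank is a rectangular box with the origin at the viewer's
left-front-bottom corner: X along the length (the axis both cameras share),
Y along the width, Z up toward the water surface. Each camera is described
by its image size and a rectangular region of interest (ROI) delimiting the
tank face in the image. The pixel→cm map is a pure affine transform of the
ROI onto the physical face:

    a_cm = (u − x0) / (x1 − x0) · A,    b_cm = frac_v · B,

where `frac_v` runs from the ROI edge corresponding to b = 0. Image rows
run downward, so the side view inverts its vertical axis by default
(`flip_v = true`) to make Z increase toward the surface; both flips are
configurable because camera mounting varies. Perspective, lens distortion
and water refraction are deliberately outside the model: for a thin tank
viewed face-on the proportional map is a good approximation, and it makes
the transform exactly invertible — the simulator's projection is the exact
inverse, so reconstruction accuracy bottoms out at the serialization
precision of the detection files rather than at a model mismatch. The
physical extent of one pixel after the map (~0.024 cm for the bundled
1800 px / 43 cm geometry) is the natural quantization floor for judging
reconstruction error.

The bundled example geometry uses a 43 × 8 × 14 cm tank. Tank dimensions
are always explicit config, never constants, since they are experiment
properties.

## Two-view merge

The top view measures (X, Y), the side view (X, Z). Both measure X, and
nothing in a two-box frame says which estimate is better, so the merged X
is the arithmetic mean — symmetric and unbiased under symmetric
localization noise. The absolute disagreement |x_top − x_side| is stored on
every observed point; when it exceeds `x_tolerance_cm` (default 1.0 cm,
roughly a third of a body length) the frame is flagged as a suspect pairing
but still produced, leaving the accept/reject decision to the caller. An
alternative policy (prefer one camera, or reject on disagreement) would be
a one-line change; the mean-plus-flag policy is this package's documented
choice.

A frame with an accepted detection in only one view contributes nothing to
the 3D series — both planes are required — but the single-view observation
is retained in the reconstruction diagnostics.

## Gap filling

Detection dropouts leave holes in the 3D series. Interior holes of at most
`max_gap_frames` (default 5 frames = 0.5 s at 10 Hz) are filled by
per-axis linear interpolation between the flanking observations and marked
`interpolated`; the cap prevents inventing behavior across long occlusions,
and leading/trailing holes are never filled because that would be
extrapolation. Every unfilled hole is reported with its frame range, so
observed + interpolated + unfilled frames always equals the number of
synchronized pairs — a conservation law the tests assert.

## Kinematics

Instantaneous velocity at sample i is the backward difference
|p_i − p_{i−1}| / dt; the first sample (and the first sample after an
unfilled gap) reports 0 because no preceding step exists. Cumulative
distance sums step lengths. Steps spanning an unfilled gap are excluded by
default — straight-lining a multi-frame hole would understate true path
length while pretending to measure it — with `bridge_gaps=True` available
for comparison. Interpolated points lie on the straight chord between their
flanking observations, so including them adds no artificial length;
chord-length sampling of a curved path always underestimates slightly,
which at 10 Hz and typical cruise speeds is below 1 % (the helix-recovery
test quantifies this).

## Occupancy statistics

Each axis splits into three equal intervals → 27 regions, id =
iz·9 + iy·3 + ix + 1 with z counted bottom-up (the id ordering is a
documented convention, nothing more). Intervals are half-open [lo, hi) with
the last interval closed so boundary points — including points clamped onto
the tank faces — are always classifiable. Layer percentages are computed
from counts and rounded to 2 decimals only for display; note that a summary
computed from counts can differ from externally quoted percentages when
those were rounded or transcribed inconsistently at the source.

The heatmap encoding assigns each region a bubble at its cell center with
radius linearly proportional to its occupancy proportion (max proportion →
`max_radius_cm`, default half the smallest cell dimension) and color
linearly interpolated dark-blue → bright-green across the min–max
proportion range; a uniform grid renders mid-ramp.

## Detection evaluation

Frame scoring: confidence-filter the detections (threshold inclusive, ≥),
then match to ground-truth boxes greedily by descending IoU, one-to-one;
matched pairs with IoU ≥ 0.5 (default) are TP, leftover detections FP,
leftover truths FN, and an empty-truth/empty-detection frame one TN. Greedy
matching equals the optimal assignment whenever at most one truth box is
present — the single-animal regime this toolkit targets; the test suite
checks it against an exhaustive-assignment oracle there. For a
single always-visible animal TN (and with a strong detector FP) is 0, which
forces accuracy = recall; the metric identities test covers the general
algebra. Metrics with zero denominators are reported as absent (None),
never coerced to 0 or 1.

`ErrorStats` enforces only non-negativity and min ≤ max — deliberately not
min ≤ mean ≤ max — so externally reported summary triples can be carried
through `compare_models` verbatim even when they are internally
inconsistent. `compare_models` always computes percent changes from its
inputs at full precision, rounding only for display.

## Swim simulator

Horizontal motion is a correlated random walk: heading angle perturbed each
frame by N(0, π·(1−persistence)), speed drawn per-frame from
Gamma(16, mean/16) (coefficient of variation 25 %, always positive), walls
reflecting both position and heading. Defaults: mean speed 6 cm/s and
persistence 0.9, a plausible cruise regime for adult zebrafish; dt 0.1 s
(10 Hz sampling); 600-frame (one-minute) sessions unless asked otherwise.

Vertical motion must reproduce a prescribed long-run layer occupancy
(`layer_bias`, default upper/middle/lower = 0.577/0.177/0.246 — strongly
surface-biased). Rather than hand-tuning a drift term, the Z coordinate
follows a Metropolis chain whose stationary density is piecewise-constant
over the three layers with exactly those weights: small reflected Gaussian
steps (scale ∝ mean_speed·dt·√(1−persistence²), symmetric proposal) mixed
with occasional burst relocations (probability `burst_p`, default 0.05 per
frame) drawn from the stationary layer distribution itself — an
independence proposal whose acceptance ratio is identically 1. The mixture
keeps the stationary distribution exact while cutting the mixing time far
below session length: at 50,000 frames the empirical layer occupancy lands
within ±3 percentage points of target (measured ≤ 2.2 points across five
seeds). Bursts read as the dart-like dives/ascents real zebrafish make; no
stronger behavioral realism is claimed. At persistence 1 with bursts
disabled both noise sources vanish and the path degenerates to a straight
line with wall reflections, a useful deterministic limit for tests.

Projection places an upright body box (default 3.0 × 0.7 × 0.5 cm
length/height/width, an adult zebrafish) at each true position; near image
edges box extents shrink symmetrically rather than shifting the center, so
the projection stays exactly invertible everywhere.

Degradation models three detector failure modes: (1) per-view Bernoulli
dropout (default 0.02 — a strong detector missing the occasional blurred
fast-motion frame); (2) Gaussian jitter of the box center (default 2 px);
(3) reflection false positives — when the fish is within `wall_margin_cm`
(default 1 cm) of a wall of a view's plane, with probability `reflection_p`
(default 0.1) an extra detection mirrored across that wall's ROI edge is
appended. Confidences are a labelled synthetic stand-in for an
unpublished real detector distribution: true detections ~ Beta(20, 1)
(median ≈ 0.97), reflections ~ Beta(4, 2) (median ≈ 0.69), so the 0.7 and
0.9 thresholds used in practice separate them meaningfully. In the fully
clean limit confidences are exactly 1 and streams equal the truth boxes.
All randomness derives from the single config seed (per-view streams use
`seed`-keyed substreams); identical configs are bit-reproducible.

What the simulator does **not** emulate — real optics (refraction,
perspective, lens distortion), body articulation and orientation-dependent
box shapes, realistic burst-and-glide speed profiles, water-surface glare
structure, or multi-animal scenes. Passing tests therefore demonstrate the
pipeline's correctness and its response to dropout/noise/artifact rates,
not detector performance on real video.

## Rendering

Past points are partitioned by age at t_now: recent (age ≤ 1 s, deep blue
`#00339B`), mid (1 s < age ≤ 3 s, light blue `#7EB6FF`), old (gray
`#9E9E9E`); boundaries are inclusive on the older side of each window and
the partition of past points is exact. The color values are this package's
choices. The overlay prints cumulative distance and instantaneous velocity
taken from the kinematics module at the last sample ≤ t_now, so figures and
CSV outputs can never disagree. Output is per-snapshot PNG (Agg backend,
headless) plus an optional GIF assembly.

## Numerical choices and degenerate inputs

- Normalized coordinates tolerate 1e-6 of float dust before erroring;
  pixel points up to 2 px outside an ROI are clamped onto it, farther is an
  out-of-tank error the reconstruction records as a skipped frame.
- Confidence threshold comparisons are inclusive (≥).
- Ties in primary-detection selection break to the earlier file line.
- IoU uses corner-based arithmetic so identical boxes score exactly 1;
  degenerate (zero-area) pairs score 0.
- Empty detection files are legal missed frames; an all-empty series cannot
  be gap-filled; metrics on all-zero confusion counts are an error rather
  than a silent 0.
- Timestamps are `frame_index × dt` by definition; file mtimes are ignored;
  trajectory validation rejects non-uniform timestamps beyond 1e-6 s.

## Problem sizes

The test suite and acceptance script size their simulations to what the
statistics require: 18,490-pair sessions for conservation (matching a
full-length recording at 10 Hz), 10,000 frames for round-trip accuracy,
5 seeds × 1,200 frames per noise level for the monotonicity check, and
50,000 frames for long-run occupancy — the smallest n at which the ±3-point
band is comfortably outside Monte-Carlo noise.

## Known limitations

- Single animal only; no identity management or track linking.
- The affine camera model ignores refraction at the water/air/acrylic
  interfaces, which in a real rig biases coordinates near the tank edges;
  a physical calibration would absorb most of it into the ROI.
- Gap filling is linear; a fish turning inside a filled gap is straightened.
- Greedy IoU matching can be suboptimal with ≥ 2 overlapping truths (not a
  supported scenario).
- The simulator's confidence and reflection models are plausibility
  stand-ins, not fits to any measured detector.
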