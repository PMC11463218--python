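# fishtrack3d

A toolkit for reconstructing and analyzing the 3D swimming trajectory of a
single fish (designed around adult zebrafish, *Danio rerio*) from two
synchronized, orthogonally mounted cameras: a top camera imaging the X–Y
plane of the tank and a side camera imaging the X–Z plane. It is
**detector-agnostic**: any object detector that emits darknet/YOLO-style
bounding boxes (`class cx cy w h [conf]`, one text file per frame, or a
consolidated CSV) can feed it. A built-in synthetic swim simulator stands in
for cameras and a trained detector, so every stage is testable offline.

Intended users: behavioral neuroscience, toxicology and drug-screening labs
that track a single animal in a box-shaped tank and want physical-unit
trajectories, kinematics and spatial-preference statistics without
commercial tracking software.

## What it computes

**Reconstruction.** Each camera's box centers are mapped from pixels to
physical cm by a pure affine (proportional) transform of a per-camera
region of interest onto the matching tank face. Per frame, the two views
are joined on the shared X axis:

    x = (x_top + x_side) / 2,   y = y_top,   z = z_side,

with the per-frame disagreement |x_top − x_side| kept as a quality flag.
Frames missed in either view become gaps; interior gaps of at most
`max_gap_frames` (default 5, i.e. 0.5 s at 10 Hz) are filled by per-axis
linear interpolation between the flanking observations, marked
`interpolated`. Longer gaps and leading/trailing gaps are reported, never
extrapolated.

**Kinematics.** Step lengths are Euclidean distances
d(p, q) = √((x₂−x₁)² + (y₂−y₁)² + (z₂−z₁)²); instantaneous velocity is the
backward difference step/dt, and cumulative distance sums the included
steps (steps spanning unfilled gaps are excluded by default).

**Occupancy.** The tank is split 3×3×3 into 27 equal regions
(id = iz·9 + iy·3 + ix + 1, z bottom-up); counts, proportions, lower/middle/
upper layer summaries, and a bubble-heatmap encoding (radius ∝ proportion,
color ramp dark-blue → bright-green).

**Evaluation.** Greedy best-IoU matching of detections to ground-truth
boxes yields frame-level TP/FP/TN/FN and the standard metrics
accuracy = (TP+TN)/(TP+FP+TN+FN), precision = TP/(TP+FP),
recall = TP/(TP+FN); 3D estimates are scored against reference coordinates
by per-frame Euclidean error (n, min, max, mean) and two models are
compared by signed percent change of each statistic.

**Simulation.** A bounded correlated random walk with persistent heading,
gamma-distributed speed and reflecting walls; the vertical coordinate is a
Metropolis walk whose stationary distribution is piecewise-constant over
the three water layers, so long-run layer occupancy converges to the
configured `layer_bias` (default strongly surface-biased, as zebrafish
prefer). Detector degradation: per-view dropout, Gaussian pixel jitter of
box centers, and near-wall reflection false positives mirrored across the
nearest wall with mid-range confidence.

## Worked example

```python
import fishtrack3d as ft

geometry = ft.default_geometry()            # 43 x 8 x 14 cm tank, two 1080p cams
cfg = ft.SimConfig(seed=7, n_frames=1200)   # two minutes at 10 Hz
session = ft.simulate_dataset(cfg, geometry)

pairs = ft.pair_streams(session.top_stream, session.side_stream)
traj, diag = ft.reconstruct(pairs, geometry, conf_threshold=0.7)
print(f"points: {len(traj)} ({traj.n_observed} observed, "
      f"{traj.n_interpolated} interpolated), "
      f"{traj.n_gap_frames} frames in unfilled gaps")

stats = ft.error_stats(traj, session.truth)
print(f"error vs truth: mean {stats.mean_err_cm:.3f} cm, "
      f"min {stats.min_err_cm:.3f}, max {stats.max_err_cm:.3f}")

layers = ft.layer_summary(ft.region_histogram(traj.points, geometry.tank))
print(f"layer occupancy: lower {layers.lower_pct}%, "
      f"middle {layers.middle_pct}%, upper {layers.upper_pct}%")

profile = ft.kinematic_profile(traj)
print(f"total distance {profile[-1].cumulative_cm:.1f} cm, "
      f"final velocity {profile[-1].velocity_cm_s:.1f} cm/s")
```

Output:

```
points: 1200 (1151 observed, 49 interpolated), 0 frames in unfilled gaps
error vs truth: mean 0.083 cm, min 0.003, max 5.443
layer occupancy: lower 40.17%, middle 15.5%, upper 44.33%
total distance 1014.7 cm, final velocity 7.0 cm/s
```

Reading it: with 2% per-view dropout every one of the 1,200 frames is
recovered (49 by interpolation across short gaps). The 2 px localization
noise costs ~0.08 cm mean 3D error — about three pixels' physical extent —
while the 5.4 cm maximum marks the occasional frame where a near-wall
reflection artifact out-scored the true detection, the characteristic
failure mode the evaluation module is built to quantify (raising
`conf_threshold` to 0.9 suppresses most of them at the cost of more gaps).
A 1,200-frame session is far shorter than the simulator's vertical mixing
time, so layer occupancy is still far from its long-run surface-biased
target; at 50,000 frames it lands within ±3 percentage points.

The same pipeline as shell commands:

```bash
fishtrack3d simulate --seed 7 --n-frames 1200 --out-dir session/
fishtrack3d reconstruct --config session/geometry.yaml \
    --top session/top_stream.csv --side session/side_stream.csv \
    --conf-threshold 0.7 --out traj.csv
fishtrack3d evaluate --traj traj.csv --truth session/truth.csv --out report.json
fishtrack3d stats --traj traj.csv --config session/geometry.yaml --out-dir stats/
fishtrack3d render --traj traj.csv --times 0,20,40,60 --out-dir frames/ --gif
```

`render` draws the trajectory in tank coordinates with recency coloring
(most recent 1 s deep blue, 1–3 s light blue, older history gray) and a
cumulative-distance / velocity overlay.

## Layout

| module | contents |
| --- | --- |
| `detection_io` | YOLO txt / stream CSV parsing, confidence filtering, per-frame primary selection, two-stream synchronization |
| `geometry` | tank/camera configs, affine pixel↔cm mapping, YAML config I/O |
| `reconstruction` | two-view merge, gap filling, trajectory assembly, trajectory/truth CSV I/O |
| `kinematics` | Euclidean distances, step series, velocity / cumulative-distance profiles |
| `occupancy` | 27-region binning, layer summaries, heatmap encoding |
| `evaluation` | IoU matching, confusion metrics, error statistics, model comparison |
| `simulate` | swim simulator, view projection, detector-degradation models |
| `viz` / `cli` | recency-colored 3D rendering; the `fishtrack3d` command |

See `docs/methods.md` for the underlying models, parameter defaults and
known limitations.
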