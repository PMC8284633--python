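# cardioflow

Post-imaging analysis for hybrid cardiac microscopy of the embryonic
zebrafish heart. A slice-scanned light-sheet channel records the beating
myocardium one z plane at a time (each slice a time sequence with an
unknown cardiac phase), while a volumetric channel records sparse
blood-cell tracers. `cardioflow` turns those acquisitions into quantitative
cardiac mechanics:

1. **Retrospective gating** — estimate the cardiac period from the
   temporal autocorrelation of each slice sequence, recover relative phase
   shifts between adjacent slices by minimizing the circular pixel-wise
   Euclidean distance `D(s) = Σ_t ‖A_t − B_{(t+s) mod L}‖₂`, and merge all
   slices into a synchronized `(t, z, y, x)` cycle.
2. **Myocardial velocimetry** — classic Thirion demons deformable
   registration between consecutive frames (3-level pyramid, 100/50/25
   iterations, Gaussian field regularization), giving per-voxel wall
   velocity `v = T(x) − x / Δt` in µm/s, with circular 7-frame temporal
   smoothing, speed heatmaps and velocity gradients.
3. **Particle tracking velocimetry** — sub-voxel spot detection and
   autoregressive (constant-velocity) bipartite linking with one-frame gap
   closing, yielding per-cell trajectories and velocities.
4. **Flow geometry** — PCA principal plane of the pooled cell positions,
   per-coordinate quartic-in-θ least-squares centerline oriented AV canal →
   outflow tract, signed collective flow profile by projecting cell
   velocities on the local tangent, flow-reversal detection
   (`v < −1000 µm/s`), tube coordinates, a 4-segment partition
   (proximal/distal × left/right of the centerline) and segmental /
   relative myocardial velocities `Σ(|v|·v)/Σ|v|`,
   `rel = ⟨|v|⟩_segment / ⟨|v|⟩_global`.

Because no public raw acquisitions exist at this scale, the package ships a
first-class phantom module: an analytically contracting ellipsoidal shell
(closed-form displacement field, exact periodicity) imaged slice-by-slice
with random phase offsets, and pulsatile tracer transits along a planar
arc with a sign-changing speed profile. Every stage is tested against this
ground truth. See `docs/methods.md` for the models and their assumptions.

Intended users: labs doing 4-D cardiac imaging in small animal models who
need a scriptable, testable reimplementation of this analysis chain.

## Worked example

Run the whole pipeline on the built-in phantom (heart + tracers at SNR 10):

```bash
cardioflow -v run --out-dir out --seed 0
```

This writes the synchronized cycle (`volume4d.tif` + sidecar), the gating
report (`sync.json`), detections and tracks (CSV), the fitted centerline
(`centerline.json` + samples), the velocity field (one TIFF per
component), the segment label volume, and the statistics tables. On the
default phantom the run prints stage timings and finishes with outputs
like:

```
reversal intervals: [(27, 32), (67, 71), (107, 112), (147, 151)]

   phase    segment  relative_velocity
   systole        1           0.929
   systole        2           1.090
   systole        3           0.952
   systole        4           1.077
   diastole       1           0.908
   diastole       2           1.123
   diastole       3           0.939
   diastole       4           1.092
```

Reading: the flow profile dips below −1000 µm/s four times (once per
cardiac cycle — the regurgitation lobe built into the phantom's speed
profile), and each myocardial segment's mean velocity magnitude is within
~±12% of the whole-ventricle mean in both phases, as expected for the
phantom's nearly uniform contraction (per-segment phase offsets from the
apex–base propagation produce the small spread).

Individual stages are available as `cardioflow gate / register / track /
centerline / segments / flow-profile`, and as library functions
(`cardioflow.gating.synchronize_scan`, `cardioflow.registration.demons_register`,
`cardioflow.tracking.link_tracks`, `cardioflow.flowgeom.fit_centerline`, ...).

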