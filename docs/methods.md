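# Methods

`cardioflow` implements the post-imaging computation for hybrid cardiac
microscopy of the embryonic zebrafish heart: a slice-scanned light-sheet
channel records the beating myocardium one z plane at a time, while a
volumetric channel records sparse blood-cell tracers. The package
reconstructs a synchronized 4-D cycle from the slice scan, measures
myocardial wall velocities by deformable registration, measures blood-cell
velocities by particle tracking, and summarizes both against the geometry
of the intracardiac flow. A synthetic phantom with exhaustive ground truth
stands in for microscope data, so every stage is quantitatively testable.

## Retrospective gating

Each z slice is a time sequence `I_k(t, y, x)` covering several cardiac
cycles at a fixed frame rate, with an unknown cardiac phase at `t = 0`.
Under the assumption of a regular rhythm:

* **Period.** The frame-vectorized sequence is mean-subtracted per pixel
  and its temporal autocorrelation computed (FFT, unbiased per-lag
  normalization). The period is the lag of the first peak whose normalized
  prominence exceeds a threshold (default 0.1), refined to sub-frame
  precision by parabolic interpolation. Sequences with no variance or no
  prominent peak raise an "aperiodic" error. Per-slice estimates are pooled
  by the median, which tolerates weak-signal edge slices.
* **Shifts.** For adjacent slices the circular pixel-wise Euclidean
  distance `D(s) = sum_t ||A_t − B_{(t+s) mod L}||_2` is evaluated over one
  rounded period `L` for every integer shift, after dividing each window by
  its mean intensity (removing per-slice illumination differences). The
  minimizing shift (ties toward the smallest) aligns the pair; a flat
  profile raises an "indistinguishable phases" error naming the slices.
* **Chaining.** Adjacent-pair shifts are accumulated modulo `L` so every
  slice is aligned to slice 0's phase, then each one-period window is
  circularly rolled and stacked into a `(time, z, y, x)` volume. Shifts are
  integer frames: at 200 fps one frame is ~0.5% of a cardiac cycle, so
  sub-frame alignment would be dominated by noise. An optional canonical
  phase origin (frame of maximum total intensity) makes the output
  independent of slice ordering. Adjacent-pair chaining is preferred over
  all-pairs optimization because neighboring slices are the most similar;
  the cost is a bounded drift over the stack, and the approach presumes a
  regular rhythm — arrhythmia is reported as an error, not corrected.
* Frames of a concurrently acquired second channel are mapped to cardiac
  phase via the shared clock: phase = ((t·fps − phase_origin) mod period) /
  period.

## Deformable-registration velocimetry

Consecutive synchronized frames are registered with the classic Thirion
demons algorithm (SimpleITK), coarse-to-fine over a 3-level pyramid
(downsampling 2 per level) with 100, 50 and 25 iterations and Gaussian
regularization of the displacement field at every iteration. The smoothing
standard deviation is expressed in voxels (default 1.5) and converted to
the physical units ITK expects at each pyramid level. Volumes are first
resampled to isotropic 2 µm and background-thresholded (Otsu by default).
Frame `t` is the reference and `t+1` the moving image, so the field reads
as the motion of material at frame `t`; the last pair wraps to the first
frame to close the cycle. Velocity is displacement divided by the frame
interval, masked to the ventricle (voxels within 30 µm of the flow
centerline by default), then smoothed per voxel with a circular 7-frame
moving average over the cycle (which conserves the per-voxel cycle mean
exactly). Spatial velocity gradients use central differences in the mask
interior and one-sided differences at mask boundaries.

The registration is intensity-driven and can only constrain motion along
the local intensity gradient; motion tangential to the shell surface is
filled in by the regularizer. On the phantom this aperture effect is the
dominant error source, and the smooth Gaussian-edged wall (rather than a
binary shell) is what keeps the problem well posed.

As an independent 1-D cross-check, a kymograph sampled along a fixed line
yields wall boundary positions (threshold crossing at half maximum, linear
sub-sample interpolation) whose separation differentiated in time is a
deformation rate; the same rate is obtained from the vector field as the
difference of the two boundary velocities projected on the line. Kymograph
sampling is angle-dependent: a line tilted by `α` from the wall-motion
direction inflates the apparent rate by `1/cos α`, which the oscillating
slab phantom demonstrates exactly.

## Particle tracking velocimetry

Tracer volumes are resampled to isotropic 2 µm and Gaussian-blurred
(default σ = 1 voxel). Detection takes local maxima above a robust
per-frame floor (median + 8 MAD-derived sigma — a familywise operating
point for multi-million-voxel series; border peaks are excluded because
clipped spots cannot be localized), with non-maximum suppression at 6 µm.
Sub-voxel positions come from per-axis log-quadratic interpolation within
the 3³ neighborhood (exact for Gaussian spots, typically ≤ 0.1 voxel), with
an intensity-weighted centroid as fallback at edges.

Linking realizes an order-1 autoregressive ("constant velocity") motion
model: each track predicts its next position from its last position and
velocity (zero for new tracks), candidate links farther than
`max_displacement` from the prediction are forbidden (default 3× the
median inter-frame nearest-neighbor step measured on the detections), and
the per-frame assignment is a minimum-cost bipartite matching on squared
prediction error. Unmatched tracks coast for one missed frame
(`max_gap = 1`) before terminating. Tracks shorter than a duration
threshold (default 5 frames) are dropped. Per-step velocities are position
differences over elapsed time, stored on the earlier frame; the final
observation carries NaN.

## Flow geometry and segmental statistics

Pooled tracer positions over all cycles define the flow geometry:

* **Principal plane** by eigen-decomposition of the position covariance;
  the two leading eigenvectors span the plane through the centroid.
* **Angle θ** of each point about a center point (default: the pooled
  centroid) after projection onto the plane, with the 2π branch cut placed
  in the largest angular gap of the cloud.
* **Centerline**: each world coordinate regressed on `[1, θ, θ², θ³, θ⁴]`
  by ordinary least squares; 200 dense samples; tangents by analytic
  differentiation; orientation AV canal → outflow tract, with the AV end
  chosen by the user (default: minimum θ) or by a supplied landmark point
  (which also makes the orientation rigid-motion equivariant).
* **Flow profile**: each per-frame track velocity is projected on the unit
  tangent at the nearest centerline sample and the signed projections are
  averaged per frame (positive = toward the outflow tract); frames with no
  tracked cells are reported missing, not zero. Flow reversal intervals are
  maximal runs with projection < −1000 µm/s (configurable), the
  regurgitation criterion for early valve formation.
* **Tube coordinates**: the arc length of the point's foot on the
  (interpolated) curve, refined so the residual is orthogonal to the local
  tangent and extended linearly beyond the curve ends, plus offsets along
  two parallel-transported lateral axes (initialized from the plane
  normal), avoiding frame flips along the curve. The transform is
  well-defined for offsets smaller than the local curvature radius; beyond
  that the nearest-foot assignment is ambiguous for any tube model.
* **Segments**: ventricle voxels (within a configurable radius of the
  centerline) are split into `n/2` equal arc-length bins × left/right of
  the curve, laterality by the sign of the offset along
  `tangent × plane normal` (consistent handedness). `n` must be even;
  default 4 (proximal/distal × left/right).
* **Statistics** per frame and segment: voxel count, unweighted mean
  velocity vector, magnitude-weighted mean vector `Σ(|v|·v)/Σ|v|`, and mean
  magnitude. Both mean estimators are reported because practice varies on
  which one summarizes a segment; the magnitude-weighted vector is the
  default headline number. The global velocity is the mean magnitude over
  the whole mask, and the relative velocity of a segment is its mean
  magnitude divided by the global value. Cycle-level relative velocities
  are ratios of window means within user-declared systole/diastole frame
  windows; by default the cycle is split at the zero crossings of the mean
  projected flow, with the window containing the flow maximum labelled
  systole. That split is a convention, not a physiological segmentation,
  and should be overridden when an independent phase definition exists.

## The phantom

`make_beating_heart` renders an ellipsoidal myocardial shell (default
semi-axes 24/40/34 µm, 8 µm wall, Gaussian edge σ = 1 voxel) whose material
points move as

    x(t) = c + μ · radii · (1 + a·sin(2πt/P + k·(z_ref − z_apex)))

with contraction amplitude `a = 0.12`, period `P = 40` frames at 200 Hz
(a fast embryonic rhythm) and phase propagation `k = 0.02` rad/µm from apex
to base, emulating the apex-led contraction wave. The map is exactly
periodic and closed-form invertible, giving an analytic displacement
sampler between any two frames — the oracle for registration accuracy and
cycle closure. The shell is sized so that, like a real acquisition that
covers the whole heart, every z slice contains myocardium.

`simulate_slice_scan` re-images the periodic series slice by slice, drawing
an integer phase offset uniformly on [0, P) per slice (the distribution in
real acquisitions is unknown; uniform is the least informative choice) and
adding Gaussian noise; SNR is peak shell intensity over noise sigma
(σ = 0.1 → SNR 10).

`make_particle_flow` advects point tracers along a planar circular arc
(radius 40 µm, 160° span — the AVC→OFT sweep around the ventricle) with
plug flow: every cell moves at the profile speed

    v(t) = v_mean + v_amp·sin(2πt/P),

default mean 1200 µm/s and amplitude 2400 µm/s, giving peak forward flow
3.6 mm/s and a reversal lobe below −1000 µm/s for one third of the cycle —
scales typical of the 3 dpf ventricle. Alternatively a reversal *fraction*
`f` may be configured, which sets the amplitude through the closed form
`A = m / cos(πf)`. Cells transit the arc once each, with entries staggered
in arc length so only a few cells are concurrently present and concurrent
spots stay well separated (as in the imaged heart, where cells pass
through and are pooled over cycles); lateral offsets within a 6 µm tube
follow a golden-angle layout with a small seeded jitter. Spots are rendered
as Gaussian blobs (σ = 2 µm); positions leaving the grid are dropped from
the images but kept in the truth. The generator records exact per-frame
positions, so detection, linking, velocities, the centerline and the flow
profile are all scored against truth.

`make_oscillating_slab` is a deliberately artificial fixture: two parallel
walls breathing along y, for which the kymograph tilt inflation `1/cos α`
is an exact geometric oracle.

What the phantom does **not** emulate: optics (no point-spread function,
no light-field sensor model, no depth-dependent blur), photobleaching or
intensity drift, arrhythmia, trabeculated wall texture, deformation of the
flow path over the cycle, and cell-cell occlusion beyond simple additive
rendering. Passing tests therefore demonstrate the correctness and
accuracy of the computation under the stated motion and noise models, not
robustness to every property of real microscope data.

## Numerical choices and degenerate inputs

* All positions/vectors are µm in `(z, y, x)` order; images are
  `(t, z, y, x)`; these conventions are declared in every file sidecar.
* Randomness flows from a single integer seed per generator/config.
* Distances on the circle (shifts, phases) are compared with circular
  metrics; sequence windows are exactly one rounded period, making the
  distance profile strictly circular and swap-symmetric.
* Demons non-convergence (NaN in the field) raises an error naming the
  pyramid level; identical inputs give a zero field.
* Nearest-centerline queries use the dense 200-sample polyline instead of
  per-query quartic root finding; with ~0.5 µm sample spacing the induced
  quantization is far below the fit residuals.
* Ties in the shift search break toward the smallest shift; ties in
  bipartite matching resolve deterministically through the assignment
  solver, and detection row order does not affect the result.
* Degenerate geometry (collinear clouds, θ span < π/4, < 15 points, points
  coincident with the center) raises typed errors rather than producing
  unstable fits.
* The problem sizes used by the test-suite and the acceptance script — a
  32-slice 64×64 scan over 4 cycles for gating (20 independent seeds),
  64³ single-cycle volumes for registration, and 20 transiting tracers for
  PTV — are the package's reference phantom conditions.

## Known limitations

* Gating assumes a strictly regular rhythm; it reports aperiodicity but
  does not correct it, and integer-frame shifts bound phase accuracy to
  half a frame.
* Adjacent-pair chaining can accumulate drift over very deep stacks.
* Classic demons is not diffeomorphic and is asymmetric in its choice of
  reference frame; tangential (surface-parallel) wall motion is
  regularizer-determined, so azimuthal twist would be underestimated.
* The linker has no track merging/splitting and a one-frame memory; dense,
  fast scenes where the per-frame step exceeds the inter-particle spacing
  at track birth are ambiguous for any position-only initialization.
* The centerline is a single open quartic curve: it cannot represent
  closed loops or strongly non-planar flow paths, and the θ
  parameterization requires the cloud to subtend a well-defined angular
  arc about the center.
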