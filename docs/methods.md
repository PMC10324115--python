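# Methods

## Problem and model

Regional left-ventricular function is assessed clinically from
echocardiographic wall motion. `comflow` quantifies it by estimating a
dense optical flow field between consecutive grayscale frames, projecting
it onto per-segment radial/circumferential axes, and tracking each
segment's region of interest (ROI) through the cycle to produce
displacement curves and a clinical motion grade.

The flow estimator is a confidence-optimized multiresolution (COM)
scheme.  Two frames are represented on an exponential resolution pyramid;
estimation starts at the coarsest level (default 30% of the original
linear size) so that large systolic displacements become sub-pixel, and
the accumulated flow is upsampled, used to warp the second frame toward
the first ("image correction"), and refined level by level.  At each
level the refinement increment `(du, dv)` is multiplied pixelwise by a
confidence weight `s ∈ [0, 1]` before accumulation,

    u ← u + s·du,  v ← v + s·dv,

so that image regions carrying little information — acoustic shadows,
dropout, blur — contribute weakly to high-resolution corrections and
largely retain the flow interpolated from coarser levels.  The default
confidence map is the level-1 wavelet approximation of the level's first
frame: decompose with `db1` (Haar), zero the detail bands, reconstruct,
and min–max normalize per level.  A constant reconstruction yields
`s ≡ 1`.  The normalized gray image itself is available as an alternative
confidence source (`confidence_source="gray"`), and `use_confidence=False`
gives the plain pyramid solver (also the Brox-style warping baseline).

### Per-level solver

Each linearization minimizes the classic quadratic energy

    E(du, dv) = Σ (Ix·du + Iy·dv + It)² + α (|∇(u0+du)|² + |∇(v0+dv)|²)

where `(u0, v0)` is the accumulated flow.  Two choices matter and were
settled by the root-mean-square-error (RMSE) calibration experiment on
the reference phantom (the same experiment used to fix the relaxation
parameters of the published method):

- **Smoothness acts on the total flow**, not the increment alone.  With
  increment-only smoothing, textureless regions (the flat wall interior
  and background of a near-binary image) receive no correction at finer
  levels, and repeated warping iterations drift wherever the data term is
  weak.  Anchoring the regularizer to `u0 + du` makes the fixed point of
  the warping loop the minimizer of the level's full energy, so
  textureless areas interpolate harmonically between data-supported
  boundaries.
- **Conjugate-gradient relaxation** of the symmetric positive-definite
  normal equations replaces pointwise Jacobi/Gauss–Seidel sweeps.
  Gauss–Seidel propagates information roughly one pixel per sweep and
  cannot fill a 100-px textureless limb within any realistic iteration
  budget; CG converges in a few hundred iterations at 256², and its
  energy is monotonically non-increasing across iterations (it minimizes
  the same quadratic over a growing Krylov subspace), preserving the
  solver's descent property.

Numerical details: spatial derivatives use the fourth-order 5-point
stencil `(-1, 8, 0, -8, 1)/12` with replicated borders, averaged over the
two frames; `It = I2 − I1`.  Warping inside the solver loop uses bicubic
spline sampling (`warp_order = 3`); both refinements roughly halve the
RMSE of the phantom experiment relative to 3-point/bilinear.  The public
`warp_image` defaults to bilinear.  Flow upsampling between levels is
bilinear, with `u` and `v` scaled by the per-axis ratio of level sizes.

Defaults (calibrated once on the reference phantom experiment and fixed):
`alpha = 0.03` (images are in [0, 1]; edge gradients are then O(0.5), so
this weights smoothness comparably to squared edge contrast),
`outer_iters = 5` warp iterations per level, `inner_iters = 800` CG
iterations with `stop_tol = 1e-7` px mean update, pyramid of 6 levels
from 30% to full size.  The HS baseline is the same linear solver run
once at full resolution without warping (`alpha = 0.08`, 400 iterations);
the LK baseline solves windowed least squares (15-px box) per pixel and
zeroes/flags pixels whose structure-tensor eigenvalue falls below 1e-6.

### Wall geometry and decomposition

The wall contour (endocardium and epicardium traced base-left → apex →
base-right, with landmark indices) is supplied as JSON; the apical
two-chamber wall is divided into 6 segments of equal endocardial arc
length (three per side), and halved again into 12 for finer reporting
("upper" = basal half, "lower" = apical half).  Segment ROI masks are
built by rasterizing the endo–epi ring and assigning each wall pixel to
the segment of its nearest endocardial vertex — this guarantees the ROIs
are disjoint and tile the wall exactly.

Each segment's center is the point where the horizontal line through the
midpoint of its endocardial chord meets the endocardial polyline; for
near-horizontal spans with no such crossing the arc-length midpoint is
used instead.  The circumferential tangent at the center is the
normalized sum of the two unit chord directions toward the span
endpoints; the radial normal is the tangent rotated 90°, signed to point
toward the cavity centroid, so positive radial displacement means
contraction.  One basis per segment is applied to all its pixels; flow
decomposition is the orthonormal projection (energy-conserving and
exactly invertible).

### ROI tracking, curves and grading

For each frame pair the segment's incremental radial displacement is the
mean of `flow · normal` over its current ROI; the ROI is then advected
with the flow using the first-order inverse (sample the mask at
`y − w(y)`, bilinear, threshold 0.5 with ties included — exact for
translations; forward splatting was rejected for hole artifacts).
Cumulative curves (px, and mm via the mm-per-pixel calibration) form the
characteristic systolic arches.  The curve peak is the signed value at
the extremum of |cumulative|, so paradoxical (outward) motion keeps its
sign; grades follow the clinical table `>5 mm → 0`, `(2, 5] → 1`,
`[0, 2] → 2`, `< 0 → 3` (half-open intervals chosen at the overlapping
endpoints).

Segment axes are fixed at their frame-1 values by default.  An optional
refresh (`axis_update_interval = n`) re-derives them every n frame pairs
from advected ROI centroids, but centroid-derived axes are a coarser
basis than the contour-derived ones and switching bases mid-cycle injects
up to ~1 px of spurious cumulative displacement on a cycle whose
ground-truth curves must close; for the near-translational segment
motion simulated here, fixed axes are exact, so 0 is the default.

## Phantom simulator

The generator emulates the simulation study design: a U-shaped,
near-binary ventricular wall (two vertical limbs joined by a
half-annulus) on black background, 256×256 px with a 20-px wall and
64-px cavity by default, optionally Gaussian-smoothed (σ = 1 px default)
and textured with seeded multiplicative speckle.  The prescribed motion
translates the left limb +2 px (rightward), the right limb −2 px, and
the whole wall +1 px down; the horizontal component blends linearly with
column across the cavity/base so the field is continuous where the two
limb motions meet.  Frames are synthesized by backward bilinear sampling
with the first-order inverse of the displacement field (exact in the
piecewise-constant limbs; O(slope²) error in the gently varying blend),
so sub-pixel schedules are well defined.  A cycle follows a half-sine
cumulative schedule `c_k = sin(πk/(n−1))` (contraction to peak
mid-cycle, return to baseline); with only two frames the cycle
degenerates to a single full-peak step.

Acoustic shadows are elliptical attenuation regions (default semi-axes
50×15 px over the right limb, attenuation 0.8) in two flavors:

- **co-moving** — the shadow is stamped onto the wall image before the
  motion is applied (the shadow-then-warp construction used for the
  quantitative accuracy experiment); brightness constancy holds, and the
  difficulty is the 5× contrast loss inside the shadow;
- **static** — the shadow darkens both frames at a fixed location while
  the wall moves beneath it, like a rib shadow during acquisition;
  brightness constancy is violated at the shadow border, which anchors
  naive estimates toward zero motion there.  This is the harder, more
  physical corruption and the setting in which confidence weighting is
  measured (endpoint error inside the shadow, confidence on vs. off).

What the phantom does **not** emulate: speckle decorrelation, scan-line
/ sector geometry, point-spread anisotropy, reverberation, or
out-of-plane motion.  Passing tests therefore demonstrate correctness of
the estimator and tracking machinery under controlled violations
(contrast loss, static occlusion, large motion), not clinical-grade
performance on real echocardiograms.

## Problem sizes and numerical tolerances

The reference experiments run at the phantom's native 256×256 size; the
cycle experiment uses 12 frames (one cardiac cycle at typical acquisition
rates spans 9–13 frames).  Because inter-frame motion along the cycle is
sub-pixel, cycle tracking uses a shallower 3-level pyramid with a lighter
solver (3 warps, 500 CG iterations) — measured peak recovery is within
5% of ground truth.  Flow-error metrics are evaluated over the frame-1
wall mask eroded by 1 px (configurable) to exclude interpolation-boundary
pixels.  Peak-recovery statements are made for segments whose
ground-truth peak exceeds 0.5 px: the apex segments have near-zero
prescribed radial motion under this phantom's displacement field, so a
relative error there is not meaningful (their displacement is dominated
by the global downward shift, which is tangential-to-outward at the
apex — the same low-reference-value caveat applies clinically).

## Known limitations

- Quadratic (non-robust) penalties: motion discontinuities are smoothed;
  occlusion/disocclusion is not modeled.
- One tangent/normal pair per segment; per-pixel bases are out of scope.
- Contours are manual inputs; no automatic segmentation.
- The angular error uses the homogeneous (+1) space-time convention so
  zero-flow comparisons are defined; very small flows therefore produce
  small angles by construction.
- The confidence mechanism reduces, but does not remove, the bias a
  strong static occluder edge exerts on the flow inside a shadow.
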