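# Methods

## Background and scope

Cine DENSE (displacement encoding with stimulated echoes) CMR stores, in the
phase of each pixel, the in-plane displacement of the tissue at that pixel
since an end-diastolic reference encoding.  Converting a cine stack of
wrapped phase images into circumferential/radial/longitudinal strain and
left-ventricular torsion requires a chain of post-processing steps:
myocardial masking from contours, spatial phase unwrapping, conversion of
phase to millimetres, inversion of the Eulerian sampling to deform a
reference mesh, temporal smoothing, and Green–Lagrange strain evaluation.
`cinedense` implements that chain, the three-contour workflow simplification
(draw only the end-diastolic endo/epi pair and the end-systolic endocardium,
then propagate), and the statistics used to quantify agreement between the
full and simplified analyses.  MRI acquisition, DICOM conversion, and
automatic segmentation of magnitude images are out of scope.

## The processing model, stage by stage

**Masking.** Contours are closed simple polygons in pixel coordinates
(x = column, y = row, pixel centers at integer coordinates), normalized to
counter-clockwise order.  The per-frame myocardial mask is the set of pixel
centers inside the epicardial polygon and not inside the endocardial one;
boundary points count as inside the polygon they lie on, so an
endocardial-boundary pixel belongs to the cavity.  In DENSE the contours
only gate which pixels contribute displacement data — they never enter the
strain computation directly — which is precisely why the three-contour
simplification can work.

**Simplified contour generation.** The end-diastolic epicardium is copied
to every frame (it bounds the outermost extent of the wall over the cycle)
and the end-systolic endocardium, the frame with the smallest endocardial
area, is copied to every frame except the reference.  The resulting mask is
a superset of the true myocardium on intermediate frames; the extra pixels
contain only phase noise and are removed again by the quality gate below.
End systole is detected per slice as the smallest endocardial polygon area
(earliest frame on ties); an explicit `--es-frame` override is available
because a study-level choice from true volumes may differ.

**Phase unwrapping.** Each frame and each encoding direction is unwrapped
independently by a quality-guided priority flood: starting from seed pixels,
the masked region is grown in descending quality order, each new pixel
receiving its neighbour's value plus the wrapped difference of the wrapped
inputs.  Quality is the negative variance of wrapped phase differences in a
3×3 window; ties are broken in row-major order, making the flood fully
deterministic.  Seeds keep their wrapped value, i.e. they assert "this
pixel's true phase lies in (−π, π)".

Automatic seeding must honour that assertion.  A pixel with a *small
wrapped* phase is not necessarily safe: at k_e = 1.0 cycles/mm a
displacement near 1 mm produces a true phase near 2π that wraps back to
zero.  The seed planner therefore tracks the set of pixels that are masked
on every frame, accumulates their phase through time with a running 1D wrap
correction (valid because frame-to-frame displacement increments are well
under half an encoding period), and picks, per frame, the highest-quality
pixel whose accumulated phase is safely inside (−π, π).  The 2D unwrapping
of each frame remains strictly independent; only the choice of where to
plant the seed uses temporal continuity, playing the role of the operator
who marks "pixels known to be unwrapped".  Explicit seeds can be supplied
through the analysis configuration instead.

**Displacement and trajectories.** Unwrapped phase converts to displacement
as u = φ / (2π·k_e) per direction.  Before interpolation, samples whose
3×3 wrapped-difference variance exceeds 1 rad² in either direction are
discarded as noise: tissue at the modelled noise level has variance
≈ 2·(0.05)² ≈ 0.005 rad², uniform noise ≈ 6.6 rad², so the gate separates
the two populations by three orders of magnitude rather than sitting on a
tuned boundary.  This is what actually removes the blood-pool and
outside-wall pixels that the simplified contours admit.

Each surviving sample lives at its deformed position p and implies a
reference position X = p − u.  Displacement at arbitrary resting points
(the mesh nodes) is obtained by scattered interpolation over (X → u) pairs
with a thin-plate-spline kernel, linear polynomial tail, and a 64-neighbour
local stencil: exact on affine fields, exact at the samples when noise-free.
Queries outside the convex hull of the samples take the nearest sample's
value and are flagged in the diagnostics (on an annulus this affects only
the epicardial node ring, whose nodes sit marginally outside the outermost
pixel centers).

Node trajectories are smoothed per coordinate with a least-squares
polynomial of order 10 in normalized time, the degree clamped to
n_frames − 2 for conditioning at low frame counts.  The fit uses a
zero-intercept basis on the displacement from rest, pinning every
trajectory exactly to its resting position at frame 0, which is what
"reference configuration" means physically.

**Mesh and strain.** The resting mesh resamples both reference contours to
128 arc-length-uniform vertices starting at the anterior RV-insertion ray
and places 6 node rings linearly between them (5 radial × 128
circumferential elements by default).  Per element, the deformation
gradient F is the least-squares fit mapping centroid-relative rest corners
to deformed corners; E = ½(FᵀF − I) is rotation-invariant, so rigid motion
produces zero strain to machine precision.  Normal components are taken in
rest-frame local directions (outward radial; circumferential 90° CCW from
it) and reported as percentages.  Short-axis slices report E_cc and E_rr.
Long-axis slices run the identical code path on their (closed) contour
pair and report the wall-tangent component as E_ll; an open two-limb strip
mesh was considered and rejected because the artifact's contour schema and
phantom define closed polygons only.

**Segments, peaks, twist, torsion.** Elements are grouped into equal
circumferential sectors from the RV insertion (6 short-axis / 4 long-axis
by default; 128 columns over 6 sectors gives two sectors of 22 columns and
four of 21, assigned deterministically, remainder first).  Segment curves
are plain means over member elements across all transmural layers; peaks
are signed extrema (most negative for Ecc/Ell, most positive for Err).
Twist is the unweighted mean rotation of all mesh nodes about the LV
center, CCW-positive in image coordinates; torsion is the per-frame OLS
slope of twist versus slice location in deg/cm (curves on different frame
grids are aligned by linear interpolation in time), with the signed
extremum of the slope magnitude reported as the peak.

**Agreement statistics.** For paired analyses: modified coefficient of
variation CoV = Σᵢ StDev(x_o[i], x_s[i]) / |Σᵢ (x_o[i]+x_s[i])/2| × 100
with the pairwise two-sample SD |a−b|/√2 (N−1 convention, the standard in
reproducibility work); curve RMSE = √(Σ(x_o−x_s)²/N); Bland–Altman bias =
mean(x_s − x_o) with 95% limits of agreement ±1.96·SD(d) (1.96, not 2,
matching the 95% normal quantile).  CoV and RMSE are symmetric in the two
arms; bias is antisymmetric; all three scale correctly under common
rescaling of both arms.

## The synthetic phantom

The phantom is an incompressible annulus (resting radii R_endo = 8 mm,
R_epi = 12 mm by default) on a 128×128 grid at 0.25 mm pixel spacing with
k_e = 1.0 cycles/mm — the mouse-like acquisition geometry; a human-like
phantom uses 2.6 mm pixels and k_e = 0.1.  Deformation is a closed-form
in-plane map: the endocardial radius contracts to (1−c)·R_endo at peak
systole (c = 0.2 by default), the rest of the wall follows the
area-preserving map r(R) = √(R² − R_endo² + r_endo²), and the slice rotates
rigidly by a·twist_peak (4° default).  The temporal amplitude a(f) is a
pair of sin² half-waves: 0 at frame 0, 1 at the peak frame
(round(0.45·(n−1)), frame 9 of 20), 0 again at the last frame — smooth,
C¹-continuous, and documented so every downstream quantity has a closed
form.  Ground-truth stretches are λ_c = r(R)/R and λ_r = 1/λ_c, giving
exact Ecc/Err at any resting radius; multi-slice studies impose a linear
twist gradient so torsion truth is the requested slope.

Encoding follows the DENSE model exactly: in-myocardium pixels carry
wrap(2π·k_e·u_d + ε) with ε ~ N(0, 0.05 rad) per direction, out-of-wall
pixels carry uniform phase in [−π, π), magnitude is high inside and low
outside, and everything is a deterministic function of the seed.

What the phantom does *not* model: partial-volume averaging at the wall
boundary, through-plane motion, T1 recovery and stimulated-echo amplitude
decay, papillary muscles, trabeculation, breathing/gating artifacts, and
anatomically realistic (non-circular, translating) ventricles.  Passing the
recovery tests therefore demonstrates correctness of the numerical chain
under the stated motion and noise model, not clinical performance; the
simplified-vs-full comparisons on the phantom mirror the logic of the
validation, at desk scale, not its population statistics.

## Numerical choices and degenerate inputs

- Wrap convention: wrap(x) = ((x+π) mod 2π) − π, range [−π, π); shared by
  the phantom encoder and the unwrapper.  A displacement of exactly half an
  encoding period lands on −π.
- Priority-queue and ES-detection ties break deterministically (row-major
  pixel order; earliest frame).
- Polynomial smoothing runs in normalized time t ∈ [0, 1]; order-10 fits in
  raw milliseconds would be severely ill-conditioned at 13–28 frames.
- Disconnected mask components without a seed stay unvisited (NaN) and are
  excluded from samples rather than guessed.
- Degenerate geometry (self-intersecting contours, zero-area elements,
  collinear samples, < 3 samples, < 2 slices for torsion, empty masks) is
  rejected with typed errors; pipeline failures are tagged with their stage
  name.
- Determinism: given a seed, rendered containers are bit-identical on disk
  (HDF5 timestamp tracking is disabled), and the analysis chain is
  deterministic given its inputs.

## Problem sizes used in the shipped checks

The test suite runs most unit checks on a 64×64 miniature phantom
(R_endo/R_epi = 4/6 mm, 12 frames) and the end-to-end acceptance checks at
the standard conditions (128×128, 20 frames, c = 0.2, noise 0.05 rad;
a 3-slice study at 0/1/2 cm with a 1.5 deg/cm twist gradient).  The
radial-strain noise floor is checked at the standard size: with an 8-pixel
wall, radial elements span only 2–3 pixels and radial noise roughly doubles
— the same resolution sensitivity of radial strain that motivates
transmural averaging in practice.

## Known limitations

- Radial strain is the least robust output at coarse resolution, inherent
  to 2–3 samples across the wall rather than to the simplification.
- The seed planner assumes some pixels stay within the wall across the
  whole cycle; a pathologically thin or fast-moving wall could defeat it,
  in which case explicit seeds should be provided.
- Long-axis support treats the contour pair as a closed section; true
  open-contour long-axis geometries from clinical tools would need a
  conversion step.
- The reference (resting) configuration must be frame 0 of the stack,
  matching the DENSE encoding convention.
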