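# Methods

## The registration model

`rootletreg` registers a subject's cervical spinal cord T2-weighted image to a
straightened template space using the dorsal nerve rootlets as landmarks.
Spinal levels — defined neuroanatomically by where rootlets enter the cord —
do not correspond one-to-one with vertebral levels defined by the
intervertebral discs, and the correspondence varies across individuals and
with neck position. Aligning rootlets directly therefore places spinal levels
more consistently in template space than the traditional disc-based
alignment, which this package also implements as a baseline.

The transformation is built in stages, each producing a displacement field,
all of which are concatenated at the end:

1. **Level landmarks.** The unweighted center of mass of each labelled
   rootlet level (codes 2–8 for C2–C8) is computed in subject and template
   space.
2. **Straightening.** The cord centerline is fit as a pair of cubic smoothing
   splines x(z), y(z) through the per-slice centers of mass of the binary
   cord mask, and the image is resampled on planes orthogonal to the
   centerline tangent. The output vertical axis is the arc length along the
   curve, so distances along the cord are preserved by construction.
   In-plane frames are parallel-transported along the curve to avoid
   spurious axial rotation. The curve model is a smoothing spline rather
   than a NURBS: both are C1 curve fits through the same centers, and the
   spline's single smoothing weight (`smoothing`, target mean squared
   residual in mm² per slice, default 1.0) is easier to reason about.
3. **Level alignment.** A 1D monotone mapping along z sends each subject
   level to its template position: shape-preserving piecewise-cubic (PCHIP)
   interpolation between landmarks, constant shift beyond the outermost
   ones. Monotone interpolation guarantees no fold-over; the constant-shift
   extension avoids runaway deformation above C2 and below C8. A missing
   intermediate level is interpolated across (with a warning); crossing
   landmarks are an error.
4. **Rostro-caudal refinement.** Both images are masked by their rootlet
   segmentations dilated by 3 voxels (6-connected, i.e. an L1 ball on the
   lattice) and registered along z only: the displacement profile dz(z) is a
   cubic B-spline (control spacing 10 mm) shared in-plane, optimized by
   gradient ascent with an accept-only-improvement line search on normalized
   cross-correlation over a 3-level smoothing pyramid (z-smoothing sigmas of
   2, 1, 0 voxels), displacement capped at 10 mm. Sharing the profile
   in-plane loses nothing because the next stage averages slice-wise anyway.
   The emitted field is non-zero only inside the template mask support.
5. **Symmetrization.** The z displacement of each axial slice is replaced by
   the mean of its non-zero values (|dz| > 1e-9 mm) and broadcast across the
   whole slice, making the field exactly left–right symmetric. The mean uses
   sorted summation with a constant-slice short-circuit so the operation is
   bit-exactly idempotent and flip-invariant.
6. **In-plane scaling.** Per template slice, an isotropic scale
   s(z) = sqrt(area_template / area_subject) about the template cord center,
   median-filtered along z (5 slices) and clamped to [0.25, 4]. This is the
   minimal transform that matches cord size; it deliberately does not
   deform gray/white matter shape. The stage can be disabled
   (`no_xy_scaling`) to preserve native morphology for morphometric
   analyses.
7. **Concatenation.** All fields are composed into a single forward field on
   the template grid (pull-back convention: the value at a template point is
   the offset to the subject-space sample position) and inverted onto the
   subject grid for the backward transform.

### Displacement-field conventions

Fields are stored as 4D NIfTI (last axis = x, y, z components in world mm)
with a JSON sidecar recording direction (`forward` = defined on the template
grid, pointing into subject space) and reference grid. Composition is
positional: `compose(outer, inner)(p) = outer(p) + inner(p + outer(p))`.
Direction flags are descriptive metadata, not enforced during composition —
a field must be composable with its own inverse. Off-grid field samples are
edge-clamped (images are zero-filled): zero-extending a displacement field
creates a boundary discontinuity that breaks fixed-point inversion.
Inversion is a damped fixed-point iteration (relaxation 0.5, tolerance
0.05 mm, up to 50–100 iterations); non-convergence signals a folded field
and is an error. Labels are always resampled nearest-neighbour, images
trilinearly.

### The disc-based baseline

The baseline runs the identical machinery with intervertebral disc point
labels as landmarks in stages 1 and 3. The rostro-caudal refinement is
skipped in disc mode by default (`RegistrationOptions.refine`): that stage's
mask is the rootlet segmentation, which the traditional disc-based method
does not consume, and letting the baseline see rootlet information would
bias the head-to-head comparison the baseline exists for.

## Validation metrics

**Rostro-caudal overlap.** For each spinal level, the set of axial slices
containing that level is computed for the warped subject and the template;
the reported percentage is 100 · |intersection| / |template slices|, so 100%
means the subject exactly covers the template extent. A 1D Dice variant,
200 · overlap / (len_template + len_subject), is reported alongside.
Cross-level and cross-subject aggregation uses population SD (divide by n).

**CSA morphometry.** Cross-sectional area per axial slice is voxel count ×
in-plane voxel area. Profiles are normalized by their mean over a 20-slice
window centered at the C2–C3 disc, then smoothed by a centered moving
average of round(22.5 mm / slice thickness) slices (forced odd, reflected
boundaries); smoothing is applied to the normalized profile. The cervical
enlargement is the argmax of the smoothed curve, ties broken toward the
more rostral slice.

## The synthetic phantom

The generator emulates the pipeline's inputs at 0.8 mm isotropic resolution
on a 48 × 48 × 176 grid: a cord tube (baseline radius 4 mm) along a possibly
curved centerline, with a Gaussian radius bulge (amplitude 1.3 mm, sigma
12 mm, centered between C5 and C6) for the cervical enlargement; paired
dorsal rootlet blobs per level (C2–C8 at ~13 mm spacing, odd/even levels at
different lateral offsets so adjacent levels can interleave in z as real
rootlet levels do); single-voxel disc labels on the vertebral side; and a
T2-like intensity image (bright CSF ring, intermediate cord, darker
rootlets) with seeded Gaussian noise (SD 5).

Neck position is modelled as a smooth sagittal bow (±6 mm, opposite signs
for flexion and extension) combined with a ±3 mm slide of the cord — and
everything attached to it — along the canal relative to the discs. The
slide is what decouples spinal from vertebral levels across positions; pure
curvature without slide would leave both landmark systems equally stable.

Cohorts add per-level rootlet jitter (SD scaled linearly from 1× at C2 to 2×
at C8, mirroring the larger caudal variability of spinal levels) and a
per-subject disc offset that decouples the two landmark systems. Draws
producing non-monotone or colliding levels are resampled up to 10 times;
this truncation shrinks the realized caudal jitter SD somewhat below
nominal, which the validation tolerances absorb. The subject's enlargement
position follows the mean C5/C6 jitter, since the enlargement is anatomy of
the spinal levels, not of the vertebrae.

What the phantom does **not** model: MR physics (bias fields, ghosting, CSF
pulsation), anatomically branching rootlets and their partial-volume
appearance, cord compression, and segmentation errors — inputs here are
perfect label volumes. Passing tests therefore demonstrate correctness of
the registration and metric machinery under known ground truth, not
robustness to segmentation quality on clinical data.

## Problem sizes and numerical choices

Validation runs use the phantom's native 48 × 48 × 176 grid at 0.8 mm; a
full registration takes a few seconds, which keeps the cohort (10 subjects ×
2 landmark modes × 2 scaling variants) and the neck-position series
comfortably reproducible on one CPU. The warp-recovery study uses 20 seeded
smooth profiles of amplitude ≤ 3 mm, the amplitude regime of the landmark
residuals the refinement stage actually sees. Ground-truth warped images in
tests are produced by an independent brute-force per-slice interpolation,
never by the code path under test. All randomness is routed through seeded
`numpy.random.default_rng` generators; registrations themselves are
deterministic.

## Known limitations

- The z refinement is a greedy unidirectional B-spline fit, not a
  bidirectional symmetric-normalization scheme; after slice-wise
  symmetrization the expressive power is the same for this z-only pipeline,
  but the optimizer can stall in a local optimum for misalignments well
  beyond the ~5 mm capture range of the smoothing pyramid.
- The in-plane scaling is isotropic per slice; it matches cord area, not
  shape.
- Straightening assumes the centerline is a graph over z (no horizontal
  loops), which holds for any realistic neck curvature.
- The disc labels are single voxels; their centers are transported
  analytically through the straightening warp rather than volume-resampled,
  so sub-voxel landmark accuracy survives, but a disc label placed outside
  the straightening field's support would degrade the baseline.
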