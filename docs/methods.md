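# Methods

`dsabox` re-creates, end to end, a frameless workflow for transferring a
target contour drawn on a pair of planar subtraction-angiography views
onto a treatment-planning CT:

1. **Match initialization** — per-view 2D-2D alignment of the native
   X-ray against a DRR of the CT, including the divergent-beam zoom
   factor;
2. **2D-3D auto-matching** — optimization of the CT's rigid pose so that
   dynamically rendered DRRs match the native X-ray pair;
3. **Visual match verification** — blend/split/checkerboard composites
   and a residual similarity score;
4. **2D drawing** — closed target contours on the frontal and sagittal
   DSA views;
5. **Backprojection** — intersection of the two back-projected contour
   cones into a volumetric "box" structure on the CT grid.

The package also contains the evaluation machinery around the workflow: a
phantom factory, a center-of-mass accuracy analysis, and an observer-study
harness for registration-mismatch detection.

## Coordinate conventions

* Patient frame: DICOM **LPS** (x left, y posterior, z superior), in
  millimetres, origin at the imaging isocenter.
* Rigid poses `(tx, ty, tz, rx, ry, rz)` rotate about the isocenter with
  fixed axes applied x → y → z (`R = Rz·Ry·Rx`), angles in degrees.  The
  pose is the transform *applied to the CT* ("the volume moves, the rays
  stay").
* Canonical **frontal** view: beam along +y; detector axes u = +x,
  v = −z.  Canonical **sagittal** view: beam along +x; u = −y, v = −z
  (axes chosen right-handed with u × v along the beam).
* Detector coordinates are millimetres relative to the center of pixel
  (0, 0), so field-of-view crops never shift contour coordinates.
* Couch-frame vocabulary maps to the patient frame as: roll = rotation
  about the longitudinal axis (z), pitch = about the lateral axis (x),
  yaw = about the vertical axis (y), couch shift = translation along x.

## Projection geometry

Each view is a point source plus a planar detector: SAD (source–isocenter
distance) 1000 mm and SID (source–detector distance) 1500 mm by default —
typical C-arm angiography values.  The zoom factor of an object at depth `d` from
the source is `SID / d` (1.5 at the isocenter).  Rotated acquisitions
(roll/pitch) rotate source and detector rigidly about the isocenter, which
preserves SAD, SID and detector orthonormality exactly.

## DRR rendering

A DRR pixel is the line integral of linear attenuation along the ray from
the source through the pixel center.  HU converts to attenuation as
`mu = mu_water (1 + HU/1000)` clamped at zero, with `mu_water = 0.0205/mm`
(≈70 keV effective).  Integration is fixed-step ray marching (default step
= half the smallest voxel pitch) with trilinear interpolation and zero
attenuation outside the volume; the marcher is a small numba kernel.
Against the analytic sphere-chord oracle `2·sqrt(R²−d²)·mu` the integrals
agree to well under 1 % away from the grazing rim (where voxelization of
the sphere itself dominates).  Images are raw integrals; `exp(−I)` is
offered for display only.  No spectra, scatter or detector response are
modeled.

## Registration

The auto-matcher maximizes the mean per-view similarity between each
acquired image and the DRR rendered at a candidate pose, over all six pose
parameters, with Powell's derivative-free method on a detector pyramid
(block-averaging factors 4, 2, 1; ray-march step is coarsened with the
level).  Default metric is normalized cross-correlation — appropriate
because simulated X-rays and DRRs share a modality; gradient-NCC and
histogram mutual information are available for less idealized data.
Tolerance is 0.01 mm/0.01° per parameter, with a budget of 800 function
evaluations per level (the small-FOV configuration legitimately needs
~550 at one level).  The documented capture range is about ±10 mm/±10°
around the initial pose.  If the optimized pose scores below the initial
pose at full resolution, the initial pose is returned and the match is
flagged unconverged.

Initialization converts per-view 2D-2D adjustments into a 6-DOF pose:
in-plane shifts divide by the view magnification; a zoom factor `z` maps
to a depth translation `SAD(1/z − 1)` along the view's beam; per-view
in-plane rotations combine as rotation vectors about the beam axes.
Adjustments left at their neutral value are treated as "not adjusted" and
excluded from the least-squares solve, so a deliberate adjustment in one
view is not diluted by the other view's silence.  An automatic variant
aligns per-view intensity centroids; it assumes the object is fully inside
both fields of view.

## Backprojection

A closed contour on a view, swept toward the source, bounds a generalized
cone; the box structure is the set of grid points whose projections lie
inside the drawn polygon on *both* views.  Membership uses the even-odd
rule with the boundary counted as inside, evaluated at voxel centers; a
`supersample` factor evaluates on a grid refined by that factor instead
(the accuracy experiments use 2×, giving sub-voxel COM resolution at
8× the membership tests).  No smoothing is applied to the box.  Per-slice
boundary polygons are extracted as 0.5-level iso-contours and re-rasterize
to the mask within one voxel.

## Phantoms and simulated acquisitions

* **Cubic phantom**: 120 mm water-equivalent cube in air with a 2 mm
  metal ball (3000 HU) at the exact volume center; 1 mm CT grid.
* **Head phantom**: ellipsoidal bone shell (semi-axes 72/88/92 mm,
  6 mm thick, 1200 HU) around soft tissue (30 HU), with a 60 mm cubic air
  cavity holding three 3 mm metal markers at fixed non-collinear offsets
  (−18,−12,−15), (22,6,2), (−2,14,18) mm — chosen once so the three
  markers stay well separated in every evaluated projection, and part of
  the stated world of the experiments.

Spheres are painted with 3³ sub-voxel antialiasing so partial-volume
fractions are respected at any grid pitch.

Native X-rays are DRRs of the full phantom plus seeded Gaussian noise
(default SD = 1 % of the image maximum).  DSA images render only the
target component — metal markers standing in for contrast-filled vessels —
from an explicitly painted markers-on-air volume, and share the native
image's geometry object (subtraction imaging is intrinsically registered).
The cubic phantom, being solid, cannot receive contrast; its "DSA" is a
copy of the native image, as one must do with a solid physical
phantom.  Simulated
X-rays are rendered at *twice* the step resolution the registration uses,
partially breaking the inverse crime; they remain renders of the same
volume, so a green accuracy test establishes correctness of the geometry
and algorithms, not robustness to real radiographic physics.

Eleven named acquisition configurations vary FOV (central 50 % crop),
lateral couch shift (±5, ±10 cm), detector roll 45°, pitch 30°, and
phantom yaw 30° ("about 30°" is fixed at exactly 30°).  For couch-shift
cases the frontal detector is re-centred in-plane on the projected
phantom, as a technologist keeps the skull in view; the sagittal shift is
along that view's beam, so only its zoom factor changes — which is
exactly the robustness the configuration probes.

## Accuracy experiments

For each configuration: simulate the posed phantom and image pairs;
initialize the registration from the true pose perturbed by a seeded
uniform offset within ±5 mm/±5° (the stand-in for the operator's manual
2D-2D pre-match); auto-match; auto-contour each marker on both DSA views;
backproject; and compare the box COM against the marker's known center.
Results are reported in centimetres as signed per-axis differences and
`r_3D = sqrt(dx²+dy²+dz²)`.  COMs are unweighted means of member
voxel-center coordinates (reference structures are binary, and whether
the clinical systems weight by intensity is unknown).

Automatic contouring thresholds the target-only view with Otsu's method,
labels blobs, picks the blob nearest the predicted marker projection, and
draws a circle centered on the blob's intensity-weighted centroid,
circumscribing its pixel footprint.  A convex hull of the binary
footprint is also available, but at the evaluated detector pitch a 3 mm
marker covers only ~2 pixels and the hull can sit half a pixel off the
true projection center — a bias of ~1 mm object-side that would dominate
the error budget; the weighted centroid is sub-pixel accurate, which is
why the circle is the default.

For the solid cubic phantom the match is driven by the ball blob alone
(an ROI mask around its predicted projection restricts the similarity),
mirroring the physical procedure; rotations are then weakly constrained,
but the ball sits at the isocenter, so the box COM is insensitive to
them.

## Mismatch observer-study harness

Per subject: 24 unchanged reference registrations plus 12 error specs
({translation, rotation} × {±0.5, ±1, ±2} mm/°) × 3 replicates = 60
cases, shuffled with a seeded permutation; 180 cases for three subjects.
Whether such errors are best introduced in 2D (on the detector) or in
3D, and along which axis, is an open design choice; here they are applied
to the 3D pose along/about a single configurable axis (default: lateral),
composing the error with the reference pose.  Ratings are accept/decline records in a
flat CSV; the analysis is a group-by over (subject, error type, signed
magnitude) yielding correct/wrong counts and fractions.  Human observer
modeling is explicitly out of scope; a threshold-on-residual-NCC
simulated rater exists only to exercise the harness and reproduces the
expected qualitative shape (wrong fraction non-increasing with error
magnitude).

## Numerical and scale choices

* Experiment scale is chosen so the full pipeline runs in minutes on one
  CPU: cubic case 1 mm CT / 256² detector at 1 mm; head cases 2 mm CT /
  128² detector at 2.25 mm.  These are stated-world values chosen once,
  not quantities fitted to any outcome.
* Ties in the optimizer resolve deterministically (fixed evaluation
  order, single seeded restart sequence when restarts are enabled).
* Degenerate inputs fail loudly: empty cone intersections, empty
  structures, non-projectable points, near-parallel view pairs,
  non-positive distances and spacings all raise typed errors.
* All randomness (noise, perturbations, shuffles) flows from explicit
  integer seeds; identical seeds give bitwise-identical outputs.

## File formats

Volumes and structure masks: uncompressed MetaImage (.mha) via a built-in
codec (exact float32 round trip) or NIfTI via nibabel (axis-aligned
affines only, converted RAS→LPS).  Planar images: 16-bit PNG + JSON
geometry sidecar (lossless to the declared 16-bit quantization); images
without a sidecar are rejected.  Contours, slice polygons and case
manifests: JSON (mm, LPS).  Ratings: CSV.  DICOM adapters (CT series,
XA headers, RT-Struct export) are not included because no DICOM toolkit
is available in the supported environment.

## Known limitations

* Inverse-crime optimism: simulated X-rays derive from the same CT that
  is registered, so accuracy numbers bound geometric/algorithmic error
  only, not robustness to spectra, scatter or soft-tissue mismatch.
* The optimizer is local; initialization must be inside the capture
  range (the experiments' ±5 mm/±5° perturbations are).
* Axis-aligned volumes only (no oblique direction matrices).
* The head phantom is parametric, not anatomical; the marker layout is a
  design choice, stated above.
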