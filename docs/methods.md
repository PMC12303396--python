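# Methods

`capmorph` estimates participant-specific scalp morphology from a colored
3D surface scan of a head wearing a photogrammetric cap, and evaluates the
estimate against ground truth through geodesically constructed EEG
montages. This note documents the model, the algorithmic choices, the
synthetic phantoms used for validation, and the limits of what those
phantoms can show.

## The estimation model

The cap carries rigid modules. Each module exposes a bright-red 3-4-5
right-triangle fiducial on top (vertical leg 20 mm, horizontal leg 15 mm)
and stands on four thin feet that comb through the hair and rest on the
scalp, 25 mm below the fiducial plane. The scanner sees hair, skin, dark
module bodies and the red fiducials; it never sees the scalp. The
estimation chain inverts this:

1. **Color filter.** A scan vertex is kept when its normalized red channel
   is at least `red_min` (0.5), its HSV saturation at least `sat_min`
   (0.7), and its hue within `hue_max` (0.1) of the hue origin on the
   [0, 1) circle. Red straddles the origin, so the hue test accepts both
   `h <= hue_max` and `h >= 1 - hue_max`; without the wrap side, slightly
   blue-shifted reds under uneven lighting would lose half the fiducial.
   "Normalized color" is read as the red channel in [0, 1] (not
   chromaticity); the conversion lives in one routine (`rgb_to_hsv`) so
   the interpretation can be swapped.

2. **Clustering.** Filtered vertices are partitioned into `k` clusters
   (default 17, one per module) by k-means with seeded k-means++
   initialization. A solution is accepted only if every cluster has at
   least 3 members and a maximum pairwise diameter of at most 50 mm (the
   physical spacing of modules on the cap); violations trigger a restart
   (budget 10), then an error. k-means itself does not enforce the
   diameter bound, so enforcement is by rejection.

3. **Pose recovery.** Per cluster: PCA gives the fiducial plane; the
   third principal axis is signed toward the head center (estimated as the
   mean of all cluster centroids — the modules cover the upper scalp, so
   the mean lies safely inside the head and only the sign is needed). The
   triangle corners are the maximum-area triple of the convex hull of the
   plane-projected cluster. The hypotenuse is the longest side; the
   right-angle corner is opposite it; the 20-vs-15 mm leg asymmetry
   assigns the remaining two corners, resolving the 180-degree in-plane
   ambiguity (this is why the fiducial is a 3-4-5 triangle and not an
   equilateral one). A three-point Procrustes fit of the model triangle
   onto the matched corners gives the rigid pose; fits are rejected when
   the observed leg ratio is within 10% of 1 (ambiguous) or the corner
   residual RMS exceeds 2 mm. Failed modules are skipped with a warning;
   the run fails below 6 posed modules.

4. **Foot projection.** The module feet (four corners of a 14 x 14 mm
   square centered under the triangle centroid, at z = -25 mm in the
   module frame; configurable for other hardware) are mapped through each
   pose. The pooled foot points are the sparse scalp sample. By
   construction the perpendicular distance from each fitted fiducial plane
   to its projected feet is exactly the module height.

5. **Template fit.** A template head surface (in practice an atlas scalp;
   any watertight scalp mesh works) is fit to the sparse sample by scaled
   iterative closest-surface-point: each iteration pairs every sample
   point with its closest point on the transformed template and
   re-estimates rotation, translation and (optionally isotropic or
   per-axis) scale. The anisotropic transform is factorized as
   `R @ diag(s)` — scale in template axes, then rotate; the order is fixed
   so parameters are identifiable. Two candidate updates are computed per
   iteration: a closed-form/alternating point-to-point solve, which
   provably never increases the objective, and a damped Gauss-Newton
   point-to-plane step, which lets sample points slide along the surface
   and converges far faster on smooth heads (point-to-point alone needs
   >1000 iterations to pin down rotation because rotating a near-ellipsoid
   slides points along, not off, the surface). The better candidate is
   accepted, so the mean squared point-to-surface distance is
   non-increasing; convergence is an improvement below `tol` (1e-4 mm^2),
   with a 300-iteration cap. The fit assumes the scan and template share a
   rough anatomical frame (or an explicit `init` transform, e.g. from
   landmark correspondences); it is a local optimizer, not a global one.

## Montages

10-20 and modified 10-5 positions are built from the four cranial
landmarks (nasion, inion, left/right preauricular) with plane-slice
geodesics: the "geodesic" between two surface points is the intersection
curve of the mesh with the plane through the two points and a reference
point, restricted to the arc passing nearest the reference. On a sphere
this is the great-circle arc; it is deterministic and cheap, and matches
closed-form spherical arcs to well under 1 mm at the phantom mesh
resolution (tested).

Cz is found by alternating: slice the sagittal nasion-inion curve through
the current Cz, take its arc-length midpoint, slice the coronal LPA-RPA
curve through that, take its midpoint; stop when successive midpoints
coincide within 0.5 mm (20-iteration cap; converges in a handful of
iterations on ellipsoids with axis ratios 0.7-1.3). The initial Cz is the
nasion-inion midpoint pushed to the surface along the anatomical up
direction `(RPA - LPA) x (nasion - inion)` — a sign-unambiguous choice
(a nearest-surface-point projection from inside the head can land on
either side).

The full grid: midline points at 5% fractions of the sagittal curve
(latitudes 0.10 ... 0.90); a circumferential "ring" sliced through Fpz, Oz
and the coronal 10%/90% points T7/T8 (least-squares plane through the
four; exact on symmetric heads); per side, ring stations at half-arc
fractions equal to the latitude, pinned so T7/T8 sit at 0.5; and 17
transverse rows connecting same-latitude ring stations through the
midline point, subdivided into 16 arc intervals pinned at the midline.
That yields 17 x 17 = 289 positions on or above the ring — the above-ear
modified 10-5 montage. **The 289-label membership is this package's
definition**: the canonical above-ear subset is not uniquely standardized,
so the registry is generated once and frozen as a text resource
(`capmorph/data/ten5_above_ears_labels.txt`). Naming follows 10-10
conventions (left odd / right even, `z` midline, `h` for 5%
intermediates), with canonical Fp1/Fp2, T7/T8, O1/O2 at the ring and the
front/back rows numbering their interiors one step further out to avoid
collisions. The 21 10-20 labels are read off the same grid, so the two
montages nest exactly by construction.

## Registration and error metrics

* Rigid label-matched registration is the Kabsch least-squares solution
  (no scale; singular values of the recovered linear part are 1 to 1e-9).
  It aligns estimated and reference montages via their shared 10-20 labels
  before any error is measured, and also serves as the unscaled atlas
  placement.
* The "basic 4" registration is the unique affine interpolating four
  landmark correspondences (nasion, inion, left/right tragus; preauricular
  points stand in for the tragus on phantoms). Near-coplanar sources raise
  an error carrying the source tetrahedron volume.
* Errors are per-label Euclidean distances over the 289 above-ear 10-5
  positions. Per-participant summaries report mean / min / max / standard
  deviation; deviations and variances are population statistics (divide by
  n) — the convention is fixed here for reproducibility. Grand means
  average each column across participants; because "grand min/max" can be
  read as either the mean of per-participant extremes or global extremes,
  both are computed (the global ones under `extra`). Per-position
  statistics give across-participant mean and variance per label.

## Synthetic phantoms

`make_head` builds an analytic radial head: an ellipsoid (default
semi-axes 90/110/95 mm: x left-right, y front-back, z up) plus a smooth
seeded bump field of 3 mm amplitude. The bump field is masked to vanish at
the four landmark directions so landmark placement stays analytic (e.g.
the nasion-inion separation equals the ellipsoid pole distance exactly).
Landmarks: nasion/inion at the y poles; preauricular points at the lateral
extremes, 20 mm below the equator — real ears sit below the nasion-inion
line, and a non-coplanar landmark tetrahedron is what makes a four-point
affine well-posed at all. Meshes are subdivided icospheres warped by the
radial function; the default 4 mm target edge length keeps discretization
error (chord sagitta ~0.02 mm) far below the quantities tested.

`make_cap_scan` assembles what the scanner sees: the hair envelope (scalp
offset outward by a hair-thickness field: mean 8 mm under the cap, with a
smooth seeded +-60% spatial variation — hair is not a uniform shell), dark
module bodies, and pure-red triangulated fiducial patches (45 vertices
each) at known poses, with Gaussian vertex noise (sigma 0.3 mm, the scale
of consumer structured-light scanners). Modules are placed along a
spherical-Fibonacci layout above ear level and settled so the four rigid
feet straddle the curved scalp; true foot contacts are the radial
projections onto the analytic surface (within 0.1 mm of the scalp mesh).
Skin and hair colors are drawn from ranges that can never pass the color
filter, which isolates filter testing from rendering realism.

Two degraded control variants mirror the study's comparison:

* **without cap** — the cap-less scan is the hair envelope alone, with the
  uncompressed thickness (1.75x the under-cap value: the cap flattens
  hair) and landmarks pushed onto it. Its montage is computed directly on
  that envelope.
* **without legs** — the module height is split into a body and thin
  10 mm legs; this variant projects feet only to the body bottom, so the
  sparse sample floats ~10 mm above the scalp and the fitted template
  over-scales accordingly. (Projecting to the fiducial plane itself —
  ignoring the full 25 mm — would make this variant far worse than the
  cap-less one, inverting the orderings the study reports; the leg split
  is the physically coherent reading.)

### The evaluation cohort

`participant_spec` derives per-seed participants from the base
conditions with three sources of anatomical variation, chosen once:

* per-axis semi-axis scaling, uniform within +-6% — so each participant is
  a known anisotropic scaling of the atlas (head circumference spread of
  roughly the adult range), and that generating transform provides the
  gold-standard "volumetric" registration;
* preauricular drop 20 +- 8 mm — ear height relative to the skull varies
  across individuals and is *not* an affine function of head shape; this
  is precisely the variation that makes a four-point affine pinned to a
  flat landmark tetrahedron extrapolate badly toward the vertex;
* 2.5 mm tangential jitter of each landmark on the surface (anatomical
  variation plus manual-picking error).

`evaluate_methods` computes, per participant, the above-ear 10-5 error
(after rigid 10-20 alignment) of six estimates: the cap-based estimation,
the known generating transform (gold standard), basic-4, the unscaled
rigid atlas, without-cap and without-legs. `compare_cohort` aggregates 10
seeded participants into grand means and per-position statistics — the
problem size used throughout the tests (about half a minute on one CPU).

### What the phantoms do and do not show

Passing phantoms demonstrates the pipeline's geometry: exact filter
semantics, correct clustering under the diameter constraint, sub-degree /
sub-millimeter pose recovery, montage construction matching closed forms,
transform estimation to numerical precision, and the qualitative method
ordering (gold <= with-cap < without-legs < without-cap; with-cap <
basic-4) under hair. They do not emulate: real scanner artifacts
(holes, specular dropouts, non-Gaussian noise), lighting-dependent
fiducial color shifts (the saturation threshold may need per-participant
adjustment on real scans), hair that occludes fiducials, cloth deformation
of the cap, the face/neck geometry of real scalp meshes, or the non-affine
gap between any atlas and a real head beyond smooth bumps. Absolute error
magnitudes on phantoms are therefore smaller than on human data; only the
relative ordering and the robustness trends carry over.

## Numerical choices and degenerate inputs

* Closest-point-on-surface queries use a KD-tree over face centroids with
  exact point-triangle distances on 24 candidates — no external spatial
  index dependency.
* PLY files are written binary-little-endian with float64 coordinates, so
  write-read round-trips are bit-exact; colors are 8-bit (exact at 0.0 and
  1.0, else within 1/255).
* `surface_from_binary_mask` treats foreground voxels as filled cells
  (nearest x4 upsampling, marching cubes at 0.5, volume-preserving
  Laplacian smoothing): a single voxel meshes to ~0.92 mm^3 and a
  radius-20 spherical mask to vertex radii within ~0.5 mm of 20. The
  "normalized thresholding" path scales intensities by the 99.9th
  percentile and thresholds at 0.1 by default — the step's parameters are
  not standardized, so they are configuration.
* Degenerate inputs raise typed errors rather than returning garbage:
  collinear clusters, equilateral (ambiguous) fiducials, coplanar basic-4
  sources (with the tetrahedron volume), planes through the head center,
  label mismatches (with the symmetric difference), empty or full masks.
* All randomness (k-means restarts, phantom generation, cohort seeds)
  flows from explicit integer seeds through `numpy` generators; identical
  seeds give bit-identical phantoms and identical pipeline outputs.

## Known limitations

* The template fit is local; grossly misaligned scans need a landmark
  initialization. Coherent point drift and globally initialized variants
  are out of scope, as is nonlinear/deformable registration.
* Plane-slice curves are not exact shortest geodesics; on strongly
  non-convex heads the slice may deviate from the true geodesic.
* The montage requires the slicing planes to cut the mesh in closed
  loops; meshes cropped at the neck work for above-ear positions, but
  open surfaces through the slicing region raise errors.
* The 289-label registry is a package definition of the above-ear 10-5
  subset; other implementations may enumerate a different membership with
  the same cardinality.
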