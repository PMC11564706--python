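# Methods

`breastmorph` computes surgical-planning morphometry from 3D multi-tissue
breast MRI label maps: nipple localization, breast-box construction,
axis-aligned tumor dimensions and volumes, tumor-to-landmark distances,
breast-quadrant localization, and convex excision hulls at a chosen
surgical margin, together with the evaluation statistics used to validate
such pipelines (Dice, Hausdorff distance, reader concordance, Gwet's AC1,
exact binomial bounds). This note records the model, its assumptions, the
defaults, and the numerical choices.

## Coordinate model

All volumes live on an axis-aligned lattice in an LPS-like frame: axis
`i` runs patient-right→left, `j` anterior→posterior, `k`
inferior→superior. Voxel `(i,j,k)` occupies the half-open box
`[i·si,(i+1)·si) × …` plus the map origin, so voxel corners form an exact
lattice. This makes the vertex-set operations (corner distances, hull
containment) exact rather than approximate. NIfTI inputs are reconciled
to this frame by nearest-axis codes; oblique affines are rejected rather
than resampled, because every downstream metric definition assumes an
axis-aligned lattice. Bilateral volumes are split at the mid-sagittal
grid plane (`i = Ni/2` by default, configurable) — clinical bilateral
acquisitions center the sternum, but no universal convention exists, so
the midline is an explicit parameter.

## Tissue model

Seven semantic classes (air, skin, adipose, fibroglandular, vessel,
chest, tumor) map to arbitrary distinct integer labels through a
user-supplied schema. "Breast tissue" throughout means skin + adipose +
fibroglandular + vessel + tumor; this same set defines breast volume,
breast-box containment and the quadrant balance, so the tumor-to-breast
ratio is always ≤ 1 and internal tissue composition never affects
balance-plane symmetry.

## Nipple localization

Candidates are voxels whose centers lie within 8 mm (Euclidean,
center-to-center; parameter `neighborhood_radius_mm`) of at least one
voxel each of air, skin and fibroglandular tissue; the unweighted center
of mass of the candidate centers is offset 6 mm posteriorly
(`posterior_offset_mm`). Both defaults are the published heuristic
values. An empty candidate set raises an error — never a silent default.
The heuristic's premise is anatomical: the retroareolar ducts are the one
place where fibroglandular tissue approaches the skin/air interface; in
breasts with little subcutaneous fat the candidate set widens and the
estimate drifts posteriorly, which is why the accompanying phantom
reproduces a ductal stalk (below).

## Breast box

Five skin-anchored key points seed an axis-aligned box: (1) breast-tissue
center of mass; (2) most anterior skin-surface voxel on the side's
central sagittal plane (ties → smallest k, then i); (3) a reference point
6 mm posterior to (2), medial-laterally aligned with (1); (4a/4b)
skin-surface voxels nearest the reference in the transverse (2D, mm)
projection on each side of it → medial/lateral extents; (5a/5b) the same
in the sagittal projection → inferior/superior extents; anterior face =
most anterior skin-surface voxel; posterior face = most anterior chest
voxel within the box footprint. "Skin surface" means skin voxels with a
face-neighbor of air, excluding buried shell. A corrective pass then
pushes any face that still excludes breast tissue outward one voxel at a
time until nothing is excluded; the defining point is re-snapped to the
skin surface for reporting. The pass is implemented as direct face
expansion — equivalent in effect to walking the defining point along the
skin boundary, but free of local minima of the surface adjacency graph.
The box therefore always contains 100 % of the side's breast-tissue
voxels (asserted exactly in the tests), with a flagged tight-bounding-box
fallback for degenerate inputs.

## Tumor metrics

Axis extents are outer-edge spans, `(max_idx − min_idx + 1)·spacing`, so
the longest dimension is the max of the three extents and the bounding
box volume is exactly their product; the alternative reading of
"longest in-plane dimension" as oblique diameters would break that
product identity, so the per-axis reading is used. Components use
face (6) connectivity by default (edge/corner configurable), with
deterministic ids in raster order and ties for the dominant mass broken
toward the first component. Distances are vertex-set distances: the
minimum Euclidean distance between deduplicated voxel-corner sets (or a
corner set and a point), computed with a KD-tree and tested for exact
equality against an all-pairs brute force. No sub-voxel surface
interpolation is attempted; reports round to 0.1 mm.

## Quadrants

Two planes through the nipple partition the breast: the transverse plane
(superior/inferior) and a near-sagittal plane containing the
superior-inferior axis, rotated about it until breast-tissue voxel counts
inside the breast box balance to < 0.5 % of the total. The rotation is
solved by bisection of the signed imbalance over ±45°; if the imbalance
does not change sign over that range, the minimizer on a 0.5° grid is
returned and flagged. Voxel centers exactly on the plane count as medial;
a tumor center of mass exactly on a plane is named upper and/or outer and
flagged. "Outer" means lateral for the given side, so mirroring a case
left↔right preserves quadrant names and negates the angle.

## Margin hulls

Per tumor component: (1) a corner-shifted mask is built whose voxel
centers are the corners of the original tumor voxels (grid grows by one
per axis, origin shifts by −half a voxel); (2) a watertight marching-cubes
surface is extracted after one-voxel zero padding; (3) surface vertices
are displaced outward along their normals by the margin (0–20 mm);
(4) the convex hull of the displaced vertices is kept. Multicentric mode
does this per connected component, tests overlap by vertex-in-hull
half-space membership (1e-9 mm slack), merges overlapping groups
transitively, rebuilds merged hulls from the union of the member
components' displaced surface vertex sets, and repeats to a fixed point.

Two numerical choices matter here:

* **Iso-level.** On the corner-shifted grid the occupied lattice points
  *are* boundary samples of the tumor, so the iso-surface should
  interpolate them; the pipeline uses level 0.99, placing vertices a
  hundredth of a voxel outside the corners. This keeps corner containment
  strict while avoiding the half-voxel inflation that the conventional
  0.5 level would add to every hull (a single 1 mm voxel would otherwise
  yield a ~1.4 mm³ hull instead of ~1.06 mm³). For ordinary masks, whose
  voxel centers straddle the true boundary, `extract_surface` defaults to
  the conventional level 0.5.
* **Support directions.** Averaged vertex normals are sparse at sharp
  corners (three directions at a cube corner), which would undercut the
  hull boundary by up to `m(1−cos 27°)` ≈ 2 mm at a 20 mm margin. For
  positive margins the hull point set therefore also includes per-face
  displaced vertex copies, restoring intermediate support directions.
  With both choices the hull of a voxelized r = 10 mm sphere at a 10 mm
  margin lands within 7 % of the analytic offset sphere, and the minimum
  corner-to-boundary distance stays within one voxel diagonal of the
  margin on spheres and cuboids.

Known limitation: voxelizing a margin-0 hull back onto the grid
re-covers ≥ 99 % of the original voxels, but for small spheres
(r ≲ 8 mm at 1 mm spacing) the convex cover of the blocky corner lattice
adds a sub-voxel shell that holds the round-trip Dice near 0.88; compact
cuboids and larger spheres exceed 0.9.

## Evaluation statistics

Dice is `2TP/(2TP+FP+FN)`; two empty masks give 1.0 with a warning
(identity of empties made explicit rather than NaN). Hausdorff distance
is the symmetric max-min over boundary-voxel centers in mm, with
"boundary" meaning a face neighbor outside the mask and the image border
counting as outside. Reader agreement uses the two-rater, two-category
Gwet AC1 with `pe = 2π(1−π)`, `π = (2a+b+c)/2n` — chosen over Cohen's
kappa because approval prevalence in vetting studies is highly skewed and
AC1 remains stable there; it depends on the discordant total `b+c` only.
The Clopper–Pearson one-sided lower bound uses the beta-quantile form
`Beta(α; x, n−x+1)` (0 when x = 0) and is cross-checked against direct
bisection of the binomial tail.

## Synthetic phantom

The phantom emulates a bilateral breast DCE-MRI label map with analytic
ground truth: a posterior chest slab; hemispherical breasts on its
anterior face with a 2 mm skin shell; a paraboloidal nipple bump
(r = 5 mm, h = 2 mm) at each apex; a deep fibroglandular core (ellipsoid)
with a retroareolar stalk (capsule, r = 4 mm) reaching to 4 mm beneath
the apex — the geometric stand-in for the converging ducts that make the
nipple heuristic work; capsule-shaped vessels; and axis-aligned
ellipsoidal tumor foci. Stamping order air < chest < adipose <
fibroglandular < vessel < skin < tumor resolves overlaps, so every voxel
carries exactly one label. Tumors are validated to lie strictly inside a
breast and clear of the chest.

Ground truth comes from the continuous geometry, never the voxel grid:
ellipsoid volumes and extents in closed form; tumor-to-chest distance
from the slab plane; tumor-to-skin from the farthest ellipsoid point to
the breast center against the inner skin sphere; tumor-to-nipple from
the nearest ellipsoid point to the nipple reference (apex offset 6 mm
posteriorly). Point-to-ellipsoid extremal distances have no closed form
for true ellipsoids and are computed by coarse spherical-parameter search
plus Nelder–Mead refinement (error ≪ 0.01 mm); spheres use closed forms.
Per-tissue voxel counts are the one grid-derived truth field (a count has
no continuous analog). Optional seeded Gaussian-smoothed boundary jitter
(default 0) supports robustness tests; with jitter the analytic truths
are only approximate.

Default geometry (presets at 1 mm isotropic spacing, 160×80×96 grid
unless noted): breast radius 35 mm centered at x = 40/120 mm, chest slab
14 mm, fibroglandular core 13×12×13 mm behind a 16 mm subcutaneous
clearance — large enough that the only air-skin-fibroglandular
convergence is retroareolar, as in moderately fatty breasts. The six
presets span the presentation spectrum: `unifocal_small` (spherical
r = 10 mm tumor, upper-outer left), `unifocal_large` (14×12×10 mm
ellipsoid), `multifocal_near` (two r = 8 mm foci, 6 mm surface gap, so a
5 mm margin forces a hull merge), `multifocal_far` (r = 42 mm breasts on
a 184×84×96 grid; two r = 6 mm foci 42 mm apart — more than twice the
20 mm maximum margin, so hulls never merge), `bilateral` (mirror-image
r = 9 mm tumors), and `dense_fibroglandular` (17×14×17 mm core).

What the phantom does *not* emulate: MRI intensities and contrast
kinetics, ductal/lobular micro-anatomy, realistic skin-thickness
variation, pectoral muscle boundaries, and irregular (non-ellipsoidal)
tumor margins. Passing the phantom suite therefore demonstrates the
correctness of the geometry pipeline against known truth, not
segmentation-model performance on clinical images; the published
cohort-level numbers (median Dice 75.6 %, median Hausdorff 15.1 mm
against radiologist-approved annotations) require the clinical cohort and
trained segmentation model and are outside this package's scope.

## Problem sizes and determinism

Phantom presets are ~1.2–1.5 M voxels and generate in under a second;
the full per-side pipeline (landmarks, metrics, quadrants, hulls) runs in
a few seconds. Convergence checks run the compact test configuration at
2/1/0.5 mm. The analysis path contains no randomness; the only seed in
the package drives phantom boundary jitter, so identical inputs always
produce identical reports (reports embed no timestamps).
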