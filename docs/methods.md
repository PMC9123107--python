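# Methods

## Problem and model

The package restores the distal fibula of one leg (the "ipsilateral" side)
from the mirrored healthy contralateral leg. The underlying assumption is
approximate bilateral symmetry of the lower leg: after mirroring, the
contralateral tibia+fibula differ from the ipsilateral pair only by a rigid
motion plus small shape/size asymmetry. A rigid registration of a chosen
bone segment then transfers the contralateral distal fibula into the
ipsilateral anatomy; the residual pose error of that transferred fragment is
the quantity of interest.

All geometry is represented as triangular surface meshes in mm with outward
normals (positive divergence-theorem volume). Registration operates on
area-uniform surface samples, not on mesh vertices, so results are
independent of triangulation density.

## Anatomical frame

* Origin: center of the tibial oriented bounding box (OBB).
* y: first OBB axis (anatomical tibial axis). The OBB axes are the
  eigenvectors of the exact area-weighted second moment of the surface
  (per-triangle closed-form integrals — centroid point masses are biased
  for coarse meshes). Distal/proximal disambiguation: the end slice
  (10% of the length) with the larger 2-D convex-hull cross-section is
  proximal — the tibial plateau is the largest cross-section of the bone.
  This rule is rigid-motion invariant, so the frame never flips under
  repositioning.
* z: component of (fibula surface centroid − tibia surface centroid)
  orthogonal to y, normalised; undefined (error) if the fibula centroid is
  within 1 mm of the tibial axis.
* x = y × z (right-handed).

Eigenvector signs elsewhere in the OBB are fixed deterministically:
each axis is oriented so the area-weighted skewness of surface projections
is non-negative, falling back to making the largest-magnitude component
positive; the third axis is then flipped if needed for right-handedness.
OBB construction is PCA-based, not the exact minimum-volume box: for
long-bone shafts the principal extents are strongly separated and PCA is
deterministic and stable; an exact minimum-volume OBB could shift measured
lengths by well under 1%.

## Segments and sampling

Segment cut planes sit at `fraction × (bone extent along frame y)` from the
stated end. The extent along y — rather than the OBB length, which is
measured along the bone's own first principal axis — is used as the cut
basis so that the proximal-75% and distal-25% fibula regions partition the
fibula samples exactly. For the tibia the two coincide by construction.
Surface sampling is area-weighted uniform with fixed per-bone substreams of
the run seed, so segment point sets nest (tibia25 ⊆ tibia50) and runs are
deterministic.

Default sampling density: **100 points/cm²**. Correspondences in ICP are
sample-to-sample, so the mean nearest-neighbour spacing sets a noise floor
on the registration; at 100/cm² the perfect-symmetry null registers below
0.05 mm / 0.05° for every segment, while much sparser sampling leaves the
axial twist of near-cylindrical segments badly constrained (degrees of
slop). Density is configurable per study.

## Registration

Point-to-point trimmed ICP: exact nearest neighbours (k-d tree, ties to the
lowest index), the worst `trim_fraction` (default 0.1) of correspondences
dropped each iteration, weighted Kabsch/SVD solve with determinant
correction (never a reflection). With a fixed trim count the RMS residual
over kept pairs is provably non-increasing; iteration stops when the RMS
change falls below `rms_tolerance` (default 1e-4 mm) or at `max_iter`
(default 100, returned with `converged=False`, not an exception).
Initialisation aligns the mirrored-contralateral anatomical frame onto the
ipsilateral one — mirrored bones start near their target, so this coarse
alignment suffices for every segment. Scale is never estimated: side-to-side
size asymmetry is part of the measured error, not corrected.

## Error decomposition

The zero-error reference pose registers the mirrored contralateral distal
fibula directly onto the ipsilateral one — closed-form Kabsch when exact
vertex correspondence is available (synthetic pairs), trimmed ICP otherwise.
The error transform is `T_err = T_segment ∘ T_reference⁻¹`, i.e. the map
from the truly-placed to the segment-restored fragment in *ipsilateral*
coordinates; expressed at the ipsilateral distal-fibula centroid so that a
pure rotation of the fragment contributes nothing to the translation
metrics. This ordering (rather than composing in mirrored-contralateral
coordinates) is what makes all four metrics invariant under a common rigid
motion of the ipsilateral pair.

* Translation error `−(d·ŷ)`: positive = distal displacement = lengthening.
* Rotation error: signed swing–twist angle of `R_err` about ŷ (quaternion
  projection, canonical hemisphere), positive = external rotation in the
  pooled right-leg convention. Left-leg pairs are mirrored into the
  right-leg convention at load time so signs pool across sides.
* Euclidean distance `‖d‖`; Euler's angle = geodesic rotation angle of
  `R_err`. By construction Euclidean ≥ |translation| and Euler ≥ |twist|;
  both inequalities are asserted on every report.

"Euclidean distance" is interpreted as the displacement norm of the
distal-fibula centroid between restored and reference pose, and "Euler's
angle" as the single axis–angle rotation magnitude (not a per-axis Euler
sequence component); these are stated interpretations of the summary
quantities, chosen because they reduce to the translation norm and total
angular deviation of the fragment.

## Synthetic cohort

The generator emulates paired CT-derived lower legs. Bones are lofted tubes
(rings of 40 vertices every 3 mm) with analytic displacement fields for the
landmarks that anchor contralateral registration: tibial plateau flare
(largest cross-section → frame orientation), distal tibial flare with
medial-malleolus bump, fibular-notch groove and anterior tubercle; fibular
head flare and distal lateral-malleolus bulge. Both shafts carry a ridged
(triangular) cross-section — real tibiae and fibulae are not surfaces of
revolution, and without the ridges the proximal fibular shaft would carry
almost no axial-rotation information for registration. Defaults: tibia
360 mm, fibula 350 mm, fibula offset 16 mm laterally / 5 mm posteriorly,
its tip 8 mm below the tibial plafond.

The contralateral side is built on the same parametric grid (exact
vertex-wise correspondence) and then mirrored, with asymmetry applied
first: per-bone isotropic scale ~ N(1, `scale_sigma`), band-limited radial
shape noise (axial modes ≤ 2, circumferential modes ≤ 3) of RMS amplitude
`shape_noise_mm`, and length jitter ~ N(0, `length_jitter_mm`). Defaults
(scale σ = 0.01, noise 0.6 mm, jitter 2 mm) put the median side-to-side
tibial length difference in the low-millimetre range, the scale reported
for real paired legs; they are order-of-magnitude choices, since published
side differences are summarised only as median absolute differences.
`fibula_shaft_noise_mm` (default 0) adds noise confined to the fibular
shaft, for cohorts whose asymmetry is deliberately concentrated there.

Deformity injection displaces the contralateral distal-quarter fibula by a
known rigid motion: `translation_y` along the shaft axis and `rotation_y`
about it through the fragment centroid, specified in the pooled right-leg
report convention (the applied angle is mirror/side-conjugated internally,
because a mirror flips the sense of rotations about an in-plane axis). A
10 mm cosine blend sits *proximal* of the cut, so the evaluation region
itself moves rigidly and ground truth there is exact; the blend tail is
what lets a strong deformity leak into an untrimmed proximal-fibula
registration.

What the generator does **not** model: cortical/trabecular interior, CT
noise and segmentation artefacts, non-rigid articular congruence, bowing or
torsion differences between sides beyond the low-frequency noise field, and
demographic covariates. Passing tests therefore demonstrate correctness of
the pipeline's geometry and statistics under controlled asymmetry, not
clinical performance on real CT cohorts.

## Statistics

Medians and ranges per segment × metric, plus medians of absolute errors.
Between-segment comparison uses the classical Friedman statistic
(within-subject mid-ranks, no tie correction), df = k−1, upper-tail χ² p.
When Friedman p < 0.05 for a metric, all six pairwise Wilcoxon signed-rank
tests are run (exact null distribution up to 25 non-zero differences,
normal approximation with tie and continuity corrections above) and
Bonferroni-adjusted with m = 6. Zero differences are dropped
(Wilcoxon's rule); fewer than five non-zero differences is an error, and a
fully degenerate pair within a significant metric is reported as NaN rather
than aborting the table.

## Numerical choices and degenerate inputs

* Vertices closer than 1e-6 mm are welded on read (STL duplicates vertices
  per facet); faces degenerated by welding are dropped.
* Meshes are written as ASCII STL, ASCII PLY with `double` vertex
  properties, or OBJ — single-precision binary formats lose ~1e-5 mm at
  bone-scale coordinates, breaking the 1e-6 mm round-trip guarantee.
* Rigid transforms are validated (RᵀR = I, det = +1) on construction;
  reflections are rejected.
* Collinear point sets (Kabsch), coplanar vertex sets (OBB), zero-area
  meshes (centroid/sampling), empty segment selections, and a fibula
  centroid on the tibial axis (frame) all raise typed errors.
* A failed registration excludes that pair from the cohort table with a
  logged reason; it never aborts the study.

## Problem sizes

Default study: 20 simulated pairs (sides alternating), 4 segments each,
100 points/cm² sampling — about a minute on one CPU. The cohort size and
density are configurable; `n` up to 96 mimics a full cadaveric study.

## Known limitations

* Cut fractions are measured along the anatomical y-axis; if a study
  measured them along a scanner axis instead, segment contents differ
  slightly near the cut.
* The PCA OBB is not the minimum-volume box (see above).
* Sample-to-sample ICP accuracy is density-limited; point-to-surface
  correspondence would remove that floor at higher cost.
* The synthetic cohort's asymmetry model is parametric and low-frequency;
  it cannot produce localised real-world variants (osteophytes, previous
  trauma remodelling).
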