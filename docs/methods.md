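# Methods

This note records the models, conventions and numerical choices behind
`dsmkit`, in the order the pipeline applies them.

## Coordinate frame and data model

All geometry is in DICOM patient coordinates for a head-first-supine
patient: +x patient-left, +y posterior, +z superior, lengths in mm, doses in
Gy. A structure is a `ContourStack` (one simple closed polygon per axial
plane, sorted ascending in z); dose is a `DoseGrid` (axis-aligned scalar
field with origin/spacing); a treatment course is one planning
`FractionRecord` plus N daily records, each carrying rectum and PTV
contours, the isocentre, and a full-course-rescaled 3D dose.

Conventions inherited from RT practice and fixed here:

* contours with multiple polygons on one plane keep the largest-area
  polygon with a warning (the rectum is a single lumen);
* dose lookups outside the grid raise an error rather than returning zero —
  silent zero-fill would corrupt map edges;
* dose interpolation is trilinear; nearest-neighbour would quantise
  dose-difference maps.

## Dose-surface maps

**Central path.** An interpolating cubic spline is fit through the
per-slice polygon centroids (parameterised by cumulative chord length) and
resampled by arc length in exact 3 mm steps starting at the inferior end.
When the path length is not a multiple of 3 mm the superior remainder
(< 3 mm) is dropped; for tubes whose extent is a multiple of 3 mm the final
point coincides with the superior centroid. A 99 mm organ therefore yields
⌊99/3⌋ + 1 = 34 rows.

**Slicing planes and the intersection correction.** The contour surface is
the ruled surface between consecutive slice polygons, each resampled to 90
arc-length-uniform points with a consistent start (the boundary point hit
by the posterior ray from the centroid) and orientation (posterior toward
patient-left). At every path point a plane orthogonal to the path tangent
cuts this surface; the cut is found per longitudinal polyline by sign
change of the plane distance (linear interpolation within the crossing
segment, nearest crossing to the path point if several). Planes that run
off the inferior/superior end face are clamped to the end ring; a plane
missing the surface in the interior is an error.

In curved or irregular organs, adjacent orthogonal planes can intersect
inside the lumen, double-sampling tissue. Following the usual
plane-reorientation idea for rectal maps, the correction here is iterative
tangent blending: while any adjacent pair of planes intersects within the
maximum ring radius of the stack, each offending tangent is replaced by the
normalised average of tangents in a window around it; the window widens
every 5 iterations so persistent high-curvature segments are smoothed over
longer stretches, with failure declared after 50 iterations. The exact
correction rule used by earlier DSM software is not published in
algorithmic detail; this implementation is a documented interpretation and
is validated on zig-zag phantoms whose naive planes provably collide.

**Angular sampling.** 45 equiangular rays (8° apart) emanate from the path
point in the cut plane. θ = 0 is the in-plane projection of patient
posterior (+y); θ increases toward patient-left. Each surface point is the
ray–ring intersection; for rings that are not star-shaped about the path
point the farthest intersection is taken with a warning. Column 0 is
therefore the posterior wall and, when the map is displayed, the posterior
cut forms both lateral edges; the anterior midline (180°) falls midway
between columns 22 (176°) and 23 (184°), so anterior-wall values are the
mean of those two columns. With 45 points on a 90-vertex circular polygon
the sampled radius is accurate to ~0.1%.

## Accumulation and dose-difference maps

Daily contours differ in length, so maps are aligned at row 0 (the inferior
border, the most stable landmark) and truncated to the shortest map before
any pointwise arithmetic; the same rule produces cohort averages on the
common inferior region. Each daily dose grid is a full-course
recalculation, so the per-fraction dose is the daily map divided by the
number of fractions and the accumulated full-course map equals the mean of
daily full-course maps; both `sum_per_fraction` and `mean_full_course`
modes are provided and coincide under that scaling. DDMs are fixed as
planned − delivered (positive = colder than planned); the cohort-average
DDM is the mean of patient DDMs on the common grid, which equals the
difference of cohort-average maps after common truncation.

## DVHs

Voxel membership is by centre-point inclusion against the contour polygon
nearest in z within half the contour slice spacing — i.e. the structure
solid is the union of 3 mm slabs centred on the contour planes, without
partial-volume weighting. The cumulative curve uses 0.1 Gy bins by default;
values at arbitrary doses (the 5 Gy test points, VX% metrics at X% of
prescription) are read off by linear interpolation, making them effectively
bin-independent. Relative volume uses each day's own total rectal volume as
denominator, so daily volume change directly rescales daily DVH values —
the mechanism by which smaller rectums yield hotter relative DVHs.
Curves are padded with zero volume up to prescription + 5 Gy so metrics at
the prescription level are defined even when the organ maximum falls short.

## Permutation inference

The test statistic is the mean difference (two-sided throughout). The null
is generated by sign flips of the per-subject differences: for n ≤ 12
subjects all 2^n patterns are enumerated and p = #{|T⁎| ≥ |T|}/2^n is
exact; otherwise p = (1 + #extreme)/(1 + n_perm) from seeded draws, never
exactly zero. Paired tests reduce to sign flips of within-pair differences.

* **DVH run rule** — tests at 5, 10, … Gy up to the prescription (36.25 Gy
  → last point 35); one shared set of sign-flip draws across points;
  significant only when ≥ 3 consecutive points have p ≤ 0.05 (boundary
  value counts).
* **DSM cluster rule** — per-pixel p-values with one shared draw sequence
  across all pixels (preserving the spatial correlation of the null maps);
  significant only when a cluster of ≥ 5 contiguous p ≤ 0.05 pixels exists.
  Contiguity is 4-neighbour by default (8-neighbour selectable) and wraps
  across the lateral map edges, which are spatially adjacent at the
  posterior cut. A max-statistic familywise variant is available behind a
  flag; the contiguity rule is the default. The mask marks exactly the
  pixels of qualifying clusters.

With 5 fractions, one-sample exact enumeration has a two-sided p floor of
1/16 per pixel/point — short-course patient-level tests are structurally
unable to reach p ≤ 0.05. This is a property of the procedure at that
sample size, not a defect, and it is why cohort-level paired tests (n = 20
patients) carry the inference for 5-fraction courses.

Wilcoxon signed-rank (zeros dropped with a 1e-9 tolerance; exact null for
n ≤ 25 without ties, otherwise normal approximation with tie correction)
and Pearson correlation are delegated to scipy and cross-checked in the
tests against an independent enumeration oracle. Correlations pool
fraction-level deviations (motion metric vs same-fraction dose metric)
across patients; no multiple-testing correction is applied across the 5
DVH metrics and 6 DSM probe points, matching how such correlations are
conventionally reported. DSM probes sit 18/36/54 mm above the inferior
border (rows 6/12/18) on the anterior and posterior walls.

## Motion metrics

* volume: trapezoidal integration of polygon areas along z (note this is
  the contoured-extent volume; the DVH slab convention differs by half a
  slice at each end, each convention documented);
* wall positions: y-coordinates of DSM column 0 (posterior) and the
  column-22/23 mean (anterior) relative to the isocentre, compared per row
  on the rows common to the planning and daily maps;
* PTV position: the displacement vector from the inferior rectal slice
  centroid to the isocentre (which is fixed to the planned dose and proxies
  the PTV under soft-tissue matching), daily minus planning, reported as
  (LR, AP, SI) with positive = patient-left / posterior / superior — so a
  positive SI component is a superior shift of the target and dose wash
  relative to the rectum.

Per-patient Wilcoxon tests use per-fraction deviations; the cohort test
uses per-patient means as the paired sample. The split is a documented
convention.

## Synthetic cohorts

The generator emulates the study conditions: a straight circular-tube
rectum (radius 12 mm, length 99 mm, slices every 3 mm; an optional
circular-arc sagittal curvature exercises the path code) abutting an
ellipsoidal PTV (semiaxes 30 × 25 × 35 mm, a prostate plus 5 mm margin;
32 × 27 × 37 mm for the 7 mm-margin long-course cohort) centred 37 mm
anterior of the rectal axis at 54 mm height, so the anterior rectal wall
touches the prescription isodose and the probe rows at 18/36/54 mm sit
below / at the inferior margin of / behind the PTV. Dose is an analytic
wash: prescription inside the ellipsoid, exponential decay with a 10 mm
falloff length outside (distance to the surface via the first-order normal
approximation, exact along the principal axes) — the spatial structure of
a dose wash without a beam model. Prescriptions follow the two regimens:
36.25 Gy in 5 fractions and 60 Gy in 20.

Per fraction, four motion factors are drawn independently from normal
distributions and recorded as ground truth: volume scale (slice radius ×
√scale so volume is linear in the scale; default 1.0 ± 0.15), AP wall
translation (default 2.0 ± 3.0 mm posterior), SI translation of the dose
field and isocentre relative to the rectum (default 2.1 ± 4.2 mm superior,
the reported long-course SI shift level), and contour length jitter (± 6
mm). Draws are clipped to physical plausibility (scale 0.2–4, shifts within
the guaranteed grid coverage); voxelwise Gaussian dose noise (0.5 Gy sd,
clipped at 0) models delivery/recalculation noise. All randomness derives
from one seed with per-patient substreams, so cohorts are exactly
reproducible. These default levels are conventions of the same order as
interfraction motion reported for prostate cohorts, not estimates fit to
any dataset.

What the generator does **not** emulate: realistic VMAT fluence, lumen
deformation beyond affine scaling/translation, wall thickness, bowel gas,
intrafraction motion, or contouring variability. Passing tests therefore
demonstrate the correctness of the map construction, accumulation and
inference machinery under known ground truth — not clinical performance on
real anatomy.

For statistical calibration, `map_level_replicate` generates null cohorts
directly at the DSM/DVH-test-point level: with zero motion the geometry of
every fraction equals planning, so a cohort reduces to per-patient base
maps plus symmetric per-fraction perturbations. Sign-flip tests are exact
under any symmetric null regardless of spatial correlation, so this
light-weight representation calibrates the run- and cluster-rule procedures
faithfully while making hundreds of replicates affordable; it does not
exercise the geometry code, which has its own oracles.

## Problem sizes and numerical choices

Dose grids default to 2.5 mm isotropic spacing (3 mm for the 20-fraction
cohort in the acceptance script); surface resampling uses 90 longitudes;
DVH bins are 0.1 Gy; permutation tests default to n_perm = 2000 with a
mandatory seed in the CLI. Calibration uses 500 replicates of 20-patient
cohorts on 20 × 45 maps at n_perm = 500; recovery checks use 20 patients ×
5 fractions. Comparisons of p-values against thresholds use a 1e-12
tolerance so exact boundary values (p = 0.05) count as significant, per the
"≤" rules.

## Known limitations

* The plane-correction rule is an interpretation; fidelity to any specific
  earlier implementation is not claimed.
* The ruled-surface/ray-sampling approach assumes roughly tubular anatomy;
  strongly non-star-shaped cuts fall back to the farthest intersection with
  a warning rather than a geodesic treatment.
* Exact enumeration caps at n = 12 subjects (4096 patterns); beyond that
  Monte-Carlo p-values carry O(1/√n_perm) noise.
* DICOM support targets the generic standard attributes only, not
  vendor-specific export dialects.
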