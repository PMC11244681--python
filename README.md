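# dsmkit

Spatial analysis of dose-delivery accuracy for the rectum in prostate
radiotherapy: dose-surface maps (DSMs), daily dose accumulation,
dose-difference maps, DVH comparison, permutation-based significance testing
with contiguity criteria, and interfraction-motion quantification.

## The problem

Image-guided prostate radiotherapy keeps the target dose accurate, but the
rectum — a hollow, mobile organ pressed against the target — routinely
receives a different dose each day than the plan intended. The standard tool
for checking delivery accuracy, the cumulative dose-volume histogram (DVH),
discards all spatial information: two very different dose distributions can
produce identical DVHs, and regional hot/cold changes can cancel in the
curve. A dose-surface map keeps the geometry: the dose on the rectal surface
is unwrapped into a 2D array whose rows follow the organ's central axis and
whose columns follow its circumference, so planned and delivered doses can
be compared pixel by pixel and significant *regions* of change can be
located on the rectal wall.

`dsmkit` implements the full analysis chain for this comparison:

1. **DSM generation** — slices of the rectal contour are taken orthogonal to
   its central-axis path in 3 mm increments (re-tilting slicing planes that
   would intersect inside the lumen), 45 equiangular points are placed
   around each cut starting at the posterior wall, dose is sampled at those
   points by trilinear interpolation, and the surface is unwrapped at the
   posterior midline into a rows × 45 array (posterior wall at the lateral
   edges, anterior wall at the centre).
2. **Accumulation** — daily DSMs are aligned at their inferior borders,
   truncated to the shortest daily contour, and combined; the accumulated
   full-course map is the mean of daily full-course maps. Dose-difference
   maps (DDMs) are planned − accumulated, so positive pixels are colder than
   planned.
3. **DVH analysis** — cumulative DVHs recomputed from contour + dose grid,
   average-delivered DVHs with standard uncertainty of the mean, and VX%
   metrics by interpolation.
4. **Statistics** — two-sided sign-flip permutation tests on the mean
   difference (exact enumeration of all 2^n sign patterns for n ≤ 12
   subjects, seeded Monte Carlo otherwise). DVHs are tested in 5 Gy steps
   across the prescription range and flagged only when ≥ 3 consecutive
   points have p ≤ 0.05 (a continuous 10 Gy range); DSMs are tested per
   pixel with shared permutation draws and flagged only when ≥ 5 contiguous
   pixels (4-neighbour, wrapping across the posterior cut) have p ≤ 0.05.
   Wilcoxon signed-rank tests and Pearson correlations relate dose changes
   to motion.
5. **Motion metrics** — rectal volume change (planned − delivered, % of
   planned), anterior/posterior wall positions vs the isocentre read off the
   DSM sampling points, and PTV-vs-rectum displacement via the vector from
   the inferior rectal slice centroid to the isocentre.

Because clinical planned/delivered datasets cannot be redistributed, the
package ships a **synthetic cohort generator**: a tubular rectum abutting an
ellipsoidal PTV dose wash with per-fraction volume change, AP wall
translation, SI dose-field shifts and length jitter, all drawn from seeded
distributions whose true values are stored as ground truth next to every
record. Every downstream stage is validated against that ground truth and
against closed-form oracles.

## Worked example

```python
from dsmkit import AnatomyParams, MotionParams, generate_cohort
from dsmkit.pipeline import RunConfig, analyze_cohort

cohort = generate_cohort(AnatomyParams(), MotionParams(), n_patients=5, seed=11)
res = analyze_cohort(cohort, RunConfig(cohort_path="", n_perm=1000, seed=1))
print("patients flagged by DVH:", res.n_flagged_dvh)
print("patients flagged by DSM:", res.n_flagged_dsm)
print(res.motion["cohort"].set_index("metric")[["mean", "sd", "wilcoxon_p"]].round(3))
```

prints

```
patients flagged by DVH: 0
patients flagged by DSM: 0
                          mean     sd  wilcoxon_p
metric
anterior_wall_shift_mm   1.190  1.821       0.312
posterior_wall_shift_mm  1.475  1.485       0.125
ptv_ap_mm               -1.333  1.587       0.188
ptv_lr_mm                0.000  0.000       1.000
ptv_si_mm                2.761  2.087       0.125
volume_change_pct       -3.641  9.315       0.625
```

Five patients at 36.25 Gy in 5 fractions: no individual patient reaches
significance (with 5 fractions the exact sign-flip test has a two-sided
p-value floor of 1/16, so patient-level flags require longer courses), and
the recovered cohort motion means sit near the generator's injected
distribution means (AP wall 2.0 mm, SI 2.1 mm, volume scale 1.0 ± 0.15 —
note a −3.6% mean volume change over only 25 fractions is within the spread
of that draw). The per-patient maps, tests and correlation tables are in
`res.patients` and `res.motion`.

The same pipeline runs from the shell on a fixture directory:

```
dsmkit simulate --config cohort.yaml --seed 7 --out cohort/
dsmkit compare --cohort cohort/ --nperm 2000 --seed 3 --out results/
dsmkit motion  --cohort cohort/ --out motion.csv
```

Standard DICOM-RT Structure Set / Dose files are read with
`dsmkit.rt_io.read_rtstruct` / `read_rtdose` (or `dsmkit dsm --struct
rtss.dcm --dose dose.dcm --out map.csv`).

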