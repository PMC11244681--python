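"""Synthetic prostate-radiotherapy cohorts with known interfraction motion.

Real planned/delivered rectal dose data cannot be redistributed, so every
downstream stage of the package is exercised on a parametric stand-in: a
tubular rectum abutting an ellipsoidal PTV dose wash.  Interfraction motion
is injected per fraction as

* a rectal volume scale (lumen filling),
* an anterior-posterior translation of the whole rectal wall,
* a superior-inferior translation of the dose distribution (and isocentre)
  relative to the rectum, and
* jitter of the contoured rectal length,

each drawn from a normal distribution whose parameters are recorded next to
the generated record, so estimates of the motion can be checked against the
injected truth.

Default anatomy and motion levels are conventions chosen to be of the same
order as interfraction motion reported for prostate cohorts (posterior-wall
excursions of a few mm, SI target shifts of ~2 mm with ~4 mm spread, volume
changes of tens of percent); they are documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CohortData, ContourStack, DoseGrid, FractionRecord, Patient

_CIRCLE_VERTS = 90
SLICE_STEP_MM = 3.0


@dataclass
class AnatomyParams:
    """Geometry of the synthetic pelvis, mm / Gy."""

    rectum_radius_mm: float = 12.0
    rectum_length_mm: float = 99.0
    ptv_semiaxes_mm: tuple[float, float, float] = (30.0, 25.0, 35.0)
    #: PTV centre relative to the rectum axis origin (inferior end, on axis);
    #: anterior of the rectum, centred over its mid-superior portion
    ptv_centre_offset_mm: tuple[float, float, float] = (0.0, -37.0, 54.0)
    prescription_gy: float = 36.25
    n_fractions: int = 5
    dose_falloff_mm: float = 10.0
    #: optional sagittal curvature of the rectal axis (circular arc radius);
    #: None = straight tube
    curvature_radius_mm: float | None = None

    def __post_init__(self) -> None:
        if min(
            self.rectum_radius_mm,
            self.rectum_length_mm,
            self.dose_falloff_mm,
            *self.ptv_semiaxes_mm,
        ) <= 0:
            raise ValueError("anatomy lengths must be positive")
        if self.prescription_gy <= 0 or self.n_fractions < 1:
            raise ValueError("invalid prescription")


@dataclass
class MotionParams:
    """Per-fraction motion distributions (normal; sd = 0 freezes a factor)."""

    volume_scale_mean: float = 1.0
    volume_scale_sd: float = 0.15
    ap_wall_shift_mean_mm: float = 2.0  # positive = posterior
    ap_wall_shift_sd_mm: float = 3.0
    si_dose_shift_mean_mm: float = 2.1  # positive = superior
    si_dose_shift_sd_mm: float = 4.2
    length_jitter_sd_mm: float = 6.0
    noise_sd_gy: float = 0.5

    def __post_init__(self) -> None:
        sds = (
            self.volume_scale_sd,
            self.ap_wall_shift_sd_mm,
            self.si_dose_shift_sd_mm,
            self.length_jitter_sd_mm,
            self.noise_sd_gy,
        )
        if any(sd < 0 for sd in sds):
            raise ValueError("standard deviations must be >= 0")
        if self.volume_scale_mean <= 0:
            raise ValueError("volume_scale_mean must be positive")


ZERO_MOTION = MotionParams(
    volume_scale_mean=1.0,
    volume_scale_sd=0.0,
    ap_wall_shift_mean_mm=0.0,
    ap_wall_shift_sd_mm=0.0,
    si_dose_shift_mean_mm=0.0,
    si_dose_shift_sd_mm=0.0,
    length_jitter_sd_mm=0.0,
    noise_sd_gy=0.0,
)


def _axis_y_offset(z: np.ndarray, radius: float | None) -> np.ndarray:
    """Sagittal bowing of the rectal axis: y(z) on a circular arc, 0 if straight."""
    if radius is None:
        return np.zeros_like(z)
    if radius <= np.max(np.abs(z)):
        raise ValueError("curvature radius must exceed the rectum z-extent")
    return radius - np.sqrt(radius**2 - z**2)


def make_rectum(
    p: AnatomyParams,
    scale: float = 1.0,
    ap_shift_mm: float = 0.0,
    length_mm: float | None = None,
) -> ContourStack:
    """Tube of circular cross-sections along z, slices every 3 mm.

    The slice radius is ``rectum_radius_mm * sqrt(scale)`` so the enclosed
    volume scales linearly with ``scale``; the whole tube is translated by
    ``ap_shift_mm`` along +y (posterior).
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    length = p.rectum_length_mm if length_mm is None else float(length_mm)
    zs = np.arange(0.0, length + 1e-9, SLICE_STEP_MM)
    if len(zs) < 3:
        raise ValueError("rectum length yields fewer than 3 slices")
    r = p.rectum_radius_mm * np.sqrt(scale)
    ang = 2 * np.pi * np.arange(_CIRCLE_VERTS) / _CIRCLE_VERTS
    circle = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
    y_axis = _axis_y_offset(zs, p.curvature_radius_mm)
    slices = [
        (float(z), circle + np.array([0.0, ap_shift_mm + y0]))
        for z, y0 in zip(zs, y_axis)
    ]
    return ContourStack("Rectum", slices)


def make_ptv(p: AnatomyParams, si_shift_mm: float = 0.0) -> ContourStack:
    """Ellipsoidal PTV contour stack; moves with the dose (SI shift applied)."""
    a, b, c = p.ptv_semiaxes_mm
    cx, cy, cz = p.ptv_centre_offset_mm
    cz = cz + si_shift_mm
    zs = np.arange(cz - c, cz + c + 1e-9, SLICE_STEP_MM)
    ang = 2 * np.pi * np.arange(_CIRCLE_VERTS) / _CIRCLE_VERTS
    slices = []
    for z in zs:
        f2 = 1.0 - ((z - cz) / c) ** 2
        if f2 <= 1e-4:
            continue
        f = np.sqrt(f2)
        ring = np.column_stack(
            [cx + a * f * np.cos(ang), cy + b * f * np.sin(ang)]
        )
        slices.append((float(z), ring))
    return ContourStack("PTV", slices)


def ellipsoid_dose(
    points: np.ndarray, p: AnatomyParams, si_shift_mm: float = 0.0
) -> np.ndarray:
    """Analytic dose wash at (n, 3) points.

    Prescription dose inside the PTV ellipsoid; outside, exponential decay
    ``prescription * exp(-d / dose_falloff_mm)`` with d the distance to the
    ellipsoid surface (first-order normal approximation, exact along the
    principal axes).  ``si_shift_mm`` translates the whole field superiorly.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float)).copy()
    centre = np.array(p.ptv_centre_offset_mm) + np.array([0.0, 0.0, si_shift_mm])
    rel = pts - centre
    ax = np.asarray(p.ptv_semiaxes_mm)
    q = rel / ax
    rho = np.linalg.norm(q, axis=1)
    grad = np.linalg.norm(q / ax, axis=1)
    dose = np.full(len(pts), p.prescription_gy)
    outside = rho > 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(grad > 0, (rho - 1.0) * rho / np.maximum(grad, 1e-12), 0.0)
    dose[outside] = p.prescription_gy * np.exp(-d[outside] / p.dose_falloff_mm)
    return dose


def make_dose_field(
    p: AnatomyParams,
    si_shift_mm: float = 0.0,
    grid_spacing_mm: float = 2.5,
    margin_mm: float | None = None,
) -> DoseGrid:
    """Dose grid covering rectum + PTV with margin >= 3 x falloff."""
    margin = 3.0 * p.dose_falloff_mm if margin_mm is None else margin_mm
    if margin < 3.0 * p.dose_falloff_mm:
        raise ValueError("grid margin must be at least 3 x dose_falloff_mm")
    a, b, c = p.ptv_semiaxes_mm
    cx, cy, cz = p.ptv_centre_offset_mm
    # generous rectum envelope: radius * 2 covers volume scales up to 4 and
    # AP wall shifts of a radius; length slack covers length jitter
    r_env = 2.0 * p.rectum_radius_mm + 8.0
    lo = np.minimum(
        [cx - a, cy - b, cz - c - abs(si_shift_mm)],
        [-r_env, -r_env, 0.0],
    ) - margin
    hi = np.maximum(
        [cx + a, cy + b, cz + c + abs(si_shift_mm)],
        [r_env, r_env, p.rectum_length_mm + 24.0],
    ) + margin
    shape = np.ceil((hi - lo) / grid_spacing_mm).astype(int) + 1
    coords = [lo[i] + grid_spacing_mm * np.arange(shape[i]) for i in range(3)]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    values = ellipsoid_dose(pts, p, si_shift_mm).reshape(shape)
    return DoseGrid(
        origin_mm=lo, spacing_mm=np.full(3, float(grid_spacing_mm)), values=values
    )


def generate_cohort(
    a: AnatomyParams,
    m: MotionParams,
    n_patients: int,
    seed: int,
    grid_spacing_mm: float = 2.5,
) -> CohortData:
    """Planning + per-fraction records for ``n_patients`` synthetic patients.

    The planning record has scale 1, zero shifts and noiseless dose.  Every
    fraction draws its motion from ``m`` (scale truncated > 0.2, length
    truncated to >= 5 slices), adds voxelwise zero-mean Gaussian dose noise,
    and stores the drawn values in ``FractionRecord.truth``.  All randomness
    derives from one seeded stream with per-patient substreams.
    """
    if n_patients < 1:
        raise ValueError("need at least one patient")
    streams = np.random.SeedSequence(seed).spawn(n_patients)
    iso_plan = np.array(a.ptv_centre_offset_mm)
    patients: list[Patient] = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        planning = FractionRecord(
            rectum=make_rectum(a),
            ptv=make_ptv(a),
            isocentre_mm=iso_plan,
            dose=make_dose_field(a, 0.0, grid_spacing_mm),
            fraction_index=0,
            truth={"scale": 1.0, "ap_shift_mm": 0.0, "si_shift_mm": 0.0,
                   "length_mm": a.rectum_length_mm},
        )
        fractions: list[FractionRecord] = []
        for k in range(1, a.n_fractions + 1):
            # draws clipped to physically plausible ranges so the dose grid
            # always covers the anatomy
            scale = float(
                np.clip(rng.normal(m.volume_scale_mean, m.volume_scale_sd), 0.2, 4.0)
            )
            ap = float(
                np.clip(rng.normal(m.ap_wall_shift_mean_mm, m.ap_wall_shift_sd_mm),
                        -25.0, 25.0)
            )
            si = float(
                np.clip(rng.normal(m.si_dose_shift_mean_mm, m.si_dose_shift_sd_mm),
                        -20.0, 20.0)
            )
            min_len = 4 * SLICE_STEP_MM  # 5 slices
            length = float(
                np.clip(rng.normal(a.rectum_length_mm, m.length_jitter_sd_mm),
                        min_len, a.rectum_length_mm + 24.0)
            )
            dose = make_dose_field(a, si, grid_spacing_mm)
            if m.noise_sd_gy > 0:
                noisy = dose.values + rng.normal(0.0, m.noise_sd_gy, dose.values.shape)
                dose = DoseGrid(dose.origin_mm, dose.spacing_mm,
                                np.clip(noisy, 0.0, None))
            fractions.append(
                FractionRecord(
                    rectum=make_rectum(a, scale, ap, length),
                    ptv=make_ptv(a, si),
                    isocentre_mm=iso_plan + np.array([0.0, 0.0, si]),
                    dose=dose,
                    fraction_index=k,
                    truth={"scale": scale, "ap_shift_mm": ap, "si_shift_mm": si,
                           "length_mm": length},
                )
            )
        patients.append(Patient(f"P{i + 1:03d}", planning, fractions))
    return CohortData(patients, a.prescription_gy, a.n_fractions)


# ---------------------------------------------------------------------------
# Map/DVH-level null and effect replicates for statistical calibration
# ---------------------------------------------------------------------------

@dataclass
class MapLevelCohort:
    """A cohort represented directly at the DSM / DVH-test-point level.

    With zero injected motion the geometry of every fraction is identical to
    planning, so a cohort is fully described by each patient's planned map
    plus per-fraction dose noise sampled at the (fixed) surface points, and
    by the planned DVH values at the 5 Gy test points plus per-fraction
    perturbations.  This lightweight representation makes large numbers of
    calibration replicates affordable; it exercises the statistical
    machinery, not the map-construction geometry.
    """

    planned_maps: np.ndarray  # (n_patients, rows, cols) full-course Gy
    daily_maps: np.ndarray  # (n_patients, n_fractions, rows, cols)
    planned_dvh_points: np.ndarray  # (n_patients, n_points) % volume
    daily_dvh_points: np.ndarray  # (n_patients, n_fractions, n_points)
    test_points_gy: np.ndarray


def map_level_replicate(
    rng: np.random.Generator,
    n_patients: int = 20,
    n_fractions: int = 5,
    map_shape: tuple[int, int] = (20, 45),
    prescription_gy: float = 36.25,
    noise_sd_gy: float = 1.0,
    dvh_noise_sd_pct: float = 3.0,
    effect_map_gy: np.ndarray | None = None,
) -> MapLevelCohort:
    """One map-level cohort: planned base maps + symmetric daily perturbations.

    ``effect_map_gy`` (rows x cols), if given, is added to every daily map —
    an injected systematic delivered-minus-planned dose effect.  With the
    default ``None`` the cohort is an exact null: daily maps differ from
    planning by zero-mean noise only.
    """
    rows, cols = map_shape
    n_points = int(prescription_gy // 5)
    pts = 5.0 * (1 + np.arange(n_points))
    # smooth patient-specific base maps: inferior-superior dose ramp plus an
    # angular modulation, kept away from 0 so noise cannot clip
    r = np.linspace(0.2, 1.0, rows)[:, None]
    c = 0.5 + 0.5 * np.cos(2 * np.pi * np.arange(cols) / cols)[None, :]
    base_scale = prescription_gy * rng.uniform(0.5, 0.9, n_patients)
    planned = base_scale[:, None, None] * (0.3 + 0.5 * r * (0.4 + 0.6 * c))
    daily = planned[:, None] + rng.normal(
        0.0, noise_sd_gy, (n_patients, n_fractions, rows, cols)
    )
    if effect_map_gy is not None:
        daily = daily + np.asarray(effect_map_gy)[None, None]
    # DVH test-point values: decreasing planned curve per patient, daily =
    # planned + smooth correlated perturbation (one scalar per fraction times
    # a loading) + independent jitter; all interior to (0, 100)
    loading = np.linspace(1.0, 0.4, n_points)
    planned_v = 80.0 - 50.0 * (pts / prescription_gy)[None, :] * rng.uniform(
        0.8, 1.0, (n_patients, 1)
    )
    shared = rng.normal(0.0, dvh_noise_sd_pct, (n_patients, n_fractions, 1))
    jitter = rng.normal(
        0.0, 0.3 * dvh_noise_sd_pct, (n_patients, n_fractions, n_points)
    )
    daily_v = planned_v[:, None] + shared * loading[None, None, :] + jitter
    return MapLevelCohort(planned, daily, planned_v, daily_v, pts)
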