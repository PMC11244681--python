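"""Core domain types for dose-surface-map analysis.

Geometry lives in the DICOM patient coordinate frame for a head-first-supine
patient: +x is patient-left, +y is posterior, +z is superior, all lengths in
millimetres, all doses in Gy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from shapely.geometry import Polygon


class DsmkitError(Exception):
    """Base class for all package errors."""


class GeometryError(DsmkitError):
    pass


class DoseLookupError(DsmkitError):
    """A requested position falls outside the dose grid."""


@dataclass
class ContourStack:
    """A contoured structure: one closed planar polygon per axial level.

    ``slices`` is an ordered list of ``(z_mm, vertices)`` pairs with vertices
    an ``(n, 2)`` array of (x, y) in mm.  Slices are sorted by ascending z;
    every polygon must be simple, have at least 3 vertices and nonzero area.
    """

    structure_name: str
    slices: list[tuple[float, np.ndarray]]

    def __post_init__(self) -> None:
        if not self.slices:
            raise GeometryError(f"{self.structure_name}: contour stack has no slices")
        cleaned: list[tuple[float, np.ndarray]] = []
        for z, verts in self.slices:
            verts = np.asarray(verts, dtype=float)
            if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
                raise GeometryError(
                    f"{self.structure_name}: polygon at z={z} needs >=3 (x, y) vertices"
                )
            poly = Polygon(verts)
            if poly.area <= 0:
                raise GeometryError(f"{self.structure_name}: zero-area polygon at z={z}")
            if not poly.is_simple:
                raise GeometryError(
                    f"{self.structure_name}: self-intersecting polygon at z={z}"
                )
            cleaned.append((float(z), verts))
        zs = np.array([z for z, _ in cleaned])
        if np.any(np.diff(np.sort(zs)) == 0):
            raise GeometryError(f"{self.structure_name}: duplicate contour z planes")
        order = np.argsort(zs)
        self.slices = [cleaned[i] for i in order]

    @property
    def z_values(self) -> np.ndarray:
        return np.array([z for z, _ in self.slices])

    def polygon(self, i: int) -> Polygon:
        return Polygon(self.slices[i][1])

    def centroids(self) -> np.ndarray:
        """(n, 3) array of per-slice polygon centroids."""
        out = np.empty((len(self.slices), 3))
        for i, (z, verts) in enumerate(self.slices):
            c = Polygon(verts).centroid
            out[i] = (c.x, c.y, z)
        return out

    def translated(self, offset: Sequence[float]) -> "ContourStack":
        dx, dy, dz = (float(v) for v in offset)
        return ContourStack(
            self.structure_name,
            [(z + dz, verts + np.array([dx, dy])) for z, verts in self.slices],
        )


@dataclass
class DoseGrid:
    """Axis-aligned 3D absorbed-dose grid.

    ``values[ix, iy, iz]`` is the dose in Gy at
    ``origin_mm + spacing_mm * (ix, iy, iz)``.
    """

    origin_mm: np.ndarray
    spacing_mm: np.ndarray
    values: np.ndarray
    axes: str = "HFS"

    def __post_init__(self) -> None:
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise ValueError("dose grid must be 3D with >=2 samples per axis")
        if np.any(self.spacing_mm <= 0):
            raise ValueError("dose grid spacing must be strictly positive")
        if np.any(self.values < 0):
            raise ValueError("dose grid contains negative dose")

    @property
    def axis_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin_mm[a] + self.spacing_mm[a] * np.arange(self.values.shape[a])
            for a in range(3)
        )

    def interpolator(self) -> RegularGridInterpolator:
        return RegularGridInterpolator(
            self.axis_coords, self.values, method="linear", bounds_error=True
        )

    def sample(self, points_mm: np.ndarray) -> np.ndarray:
        """Trilinear dose lookup at (n, 3) points; outside the grid is an error."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        try:
            return self.interpolator()(pts)
        except ValueError as exc:
            raise DoseLookupError(f"dose lookup outside grid: {exc}") from None


@dataclass
class FractionRecord:
    """One fraction's anatomy and full-course-scaled dose.

    ``fraction_index`` 0 denotes the planning record.  ``truth`` optionally
    carries the generating parameters of a synthetic fraction (ground truth).
    """

    rectum: ContourStack
    ptv: ContourStack
    isocentre_mm: np.ndarray
    dose: DoseGrid
    fraction_index: int
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.isocentre_mm = np.asarray(self.isocentre_mm, dtype=float)
        zmin = self.origin_z
        zmax = zmin + self.dose.spacing_mm[2] * (self.dose.values.shape[2] - 1)
        for s in (self.rectum, self.ptv):
            z = s.z_values
            if z.max() < zmin or z.min() > zmax:
                raise GeometryError(
                    f"{s.structure_name} z-range does not overlap the dose grid"
                )

    @property
    def origin_z(self) -> float:
        return float(self.dose.origin_mm[2])


@dataclass
class Patient:
    patient_id: str
    planning: FractionRecord
    fractions: list[FractionRecord]

    def __post_init__(self) -> None:
        if not self.fractions:
            raise ValueError(f"patient {self.patient_id} has no treatment fractions")


@dataclass
class CohortData:
    patients: list[Patient]
    prescription_gy: float
    n_fractions: int

    def __post_init__(self) -> None:
        if self.prescription_gy <= 0:
            raise ValueError("prescription must be positive")
        if not self.patients:
            raise ValueError("cohort has no patients")


@dataclass
class DSM:
    """A dose-surface map.

    Rows run from the inferior border superiorly at ``row_spacing_mm``
    intervals; the 45 columns unwrap the circumference starting at the
    posterior wall (column 0) and proceeding toward patient-left, so the
    posterior cut forms both lateral edges of the visualised map.  ``points``
    stores the sampled 3D surface positions, shape ``dose.shape + (3,)``.
    """

    dose: np.ndarray
    points: np.ndarray
    row_spacing_mm: float = 3.0
    angular_count: int = 45
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        self.points = np.asarray(self.points, dtype=float)
        if self.dose.ndim != 2 or self.dose.shape[1] != self.angular_count:
            raise ValueError(f"DSM must be rows x {self.angular_count}")
        if self.points.shape != self.dose.shape + (3,):
            raise ValueError("DSM points array must match dose shape")
        if np.any(self.dose < 0):
            raise ValueError("DSM contains negative dose")

    @property
    def n_rows(self) -> int:
        return self.dose.shape[0]

    def scaled(self, factor: float) -> "DSM":
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        return DSM(
            self.dose * factor,
            self.points.copy(),
            self.row_spacing_mm,
            self.angular_count,
            dict(self.metadata),
        )


@dataclass
class DDM:
    """Signed dose-difference map on the common truncated DSM grid."""

    values: np.ndarray
    row_spacing_mm: float = 3.0
    angular_count: int = 45
    convention: str = "planned_minus_delivered"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != self.angular_count:
            raise ValueError(f"DDM must be rows x {self.angular_count}")


@dataclass
class DVH:
    """Cumulative dose-volume histogram: % of volume receiving >= each edge dose."""

    dose_edges_gy: np.ndarray
    rel_volume_pct: np.ndarray
    sem_pct: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dose_edges_gy = np.asarray(self.dose_edges_gy, dtype=float)
        self.rel_volume_pct = np.asarray(self.rel_volume_pct, dtype=float)
        if self.dose_edges_gy.shape != self.rel_volume_pct.shape:
            raise ValueError("DVH edges and volumes must have identical shape")
        if np.any(np.diff(self.dose_edges_gy) <= 0):
            raise ValueError("DVH dose edges must be strictly ascending")
        if np.any(np.diff(self.rel_volume_pct) > 1e-9):
            raise ValueError("cumulative DVH must be non-increasing")
        if (
            self.rel_volume_pct.min() < -1e-9
            or self.rel_volume_pct.max() > 100 + 1e-9
        ):
            raise ValueError("relative volume must lie in [0, 100]")


def warn_geometry(message: str) -> None:
    warnings.warn(message, RuntimeWarning, stacklevel=3)
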