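"""Cumulative dose-volume histograms and DVH metrics.

DVHs are recomputed from contour + dose grid: a voxel belongs to the
structure when its centre lies inside the contour polygon nearest in z
(within half the contour slice spacing); the cumulative curve is the
volume-weighted fraction of member voxels at or above each dose edge.
Relative volume always uses that day's own total structure volume as the
denominator, so daily volume change directly rescales daily DVH values.
Metrics VX% are read off the curve by linear interpolation at
X% of the prescription.
"""

from __future__ import annotations

import numpy as np
import shapely
from shapely.geometry import Polygon

from .core import ContourStack, DoseGrid, DVH

DEFAULT_BIN_GY = 0.1


def structure_doses(dose: DoseGrid, structure: ContourStack) -> np.ndarray:
    """Doses of all grid voxels whose centres fall inside the structure."""
    xs, ys, zs = dose.axis_coords
    slice_z = structure.z_values
    spacing = float(np.median(np.diff(slice_z))) if len(slice_z) > 1 else np.inf
    half = spacing / 2.0
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    flat_x, flat_y = xx.ravel(), yy.ravel()
    member: list[np.ndarray] = []
    for iz, z in enumerate(zs):
        j = int(np.argmin(np.abs(slice_z - z)))
        if abs(slice_z[j] - z) > half + 1e-9:
            continue
        poly = Polygon(structure.slices[j][1])
        inside = shapely.contains_xy(poly, flat_x, flat_y)
        if inside.any():
            member.append(dose.values[:, :, iz].ravel()[inside])
    if not member:
        raise ValueError(
            f"no dose-grid voxel centres inside structure {structure.structure_name}"
        )
    return np.concatenate(member)


def compute_dvh(
    dose: DoseGrid, structure: ContourStack, bin_gy: float = DEFAULT_BIN_GY
) -> DVH:
    """Cumulative DVH with edges 0, bin, 2*bin, ... covering the member doses."""
    if bin_gy <= 0:
        raise ValueError("bin width must be positive")
    doses = np.sort(structure_doses(dose, structure))
    n = doses.size
    top = doses[-1] + bin_gy
    edges = np.arange(0.0, top + bin_gy / 2, bin_gy)
    # fraction of voxels with dose >= edge (voxels are uniform -> counts)
    idx = np.searchsorted(doses, edges - 1e-12, side="left")
    rel = 100.0 * (n - idx) / n
    return DVH(edges, rel)


def average_dvh(dvhs: list[DVH]) -> DVH:
    """Pointwise mean of DVHs on identical edges, with sd/sqrt(n) uncertainty."""
    if not dvhs:
        raise ValueError("no DVHs to average")
    edges = dvhs[0].dose_edges_gy
    for d in dvhs[1:]:
        if d.dose_edges_gy.shape != edges.shape or not np.allclose(
            d.dose_edges_gy, edges
        ):
            raise ValueError("DVHs have mismatched dose edges")
    stack = np.stack([d.rel_volume_pct for d in dvhs])
    mean = stack.mean(axis=0)
    if len(dvhs) > 1:
        sem = stack.std(axis=0, ddof=1) / np.sqrt(len(dvhs))
    else:
        sem = np.zeros_like(mean)
    return DVH(edges, mean, sem_pct=sem)


def rel_volume_at(dvh: DVH, dose_gy: float) -> float:
    """Linear interpolation of the cumulative curve at an arbitrary dose."""
    edges = dvh.dose_edges_gy
    if dose_gy < edges[0] - 1e-9 or dose_gy > edges[-1] + 1e-9:
        raise ValueError(
            f"dose {dose_gy} Gy outside DVH range [{edges[0]}, {edges[-1]}]"
        )
    return float(np.interp(dose_gy, edges, dvh.rel_volume_pct))


def v_metrics(
    dvh: DVH, prescription_gy: float, at_pct: list[float]
) -> dict[float, float]:
    """VX% metrics: % volume receiving >= X% of prescription, per requested X."""
    if prescription_gy <= 0:
        raise ValueError("prescription must be positive")
    return {
        float(p): rel_volume_at(dvh, prescription_gy * p / 100.0) for p in at_pct
    }


def pad_dvh_to(dvh: DVH, top_gy: float, bin_gy: float = DEFAULT_BIN_GY) -> DVH:
    """Extend a DVH's dose axis to ``top_gy`` with zero volume (for averaging)."""
    edges = dvh.dose_edges_gy
    if edges[-1] >= top_gy:
        return dvh
    extra = np.arange(edges[-1] + bin_gy, top_gy + bin_gy, bin_gy)
    return DVH(
        np.r_[edges, extra],
        np.r_[dvh.rel_volume_pct, np.zeros(extra.size)],
        sem_pct=None if dvh.sem_pct is None else np.r_[dvh.sem_pct, np.zeros(extra.size)],
    )
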