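"""Dose-surface-map construction.

A DSM unfolds the dose on the surface of a tubular organ (here the rectum)
into a 2D array.  The construction follows the standard recipe for rectal
dose-surface mapping:

1. fit a central path through the per-slice contour centroids and resample it
   by arc length in 3 mm steps;
2. cut the contour surface with a plane orthogonal to the path at every step,
   re-tilting planes that would intersect each other inside the lumen;
3. place 45 equiangular points around each cut, starting at the posterior
   wall and proceeding toward patient-left;
4. sample the 3D dose at those surface points and stack the cuts into a
   rows x 45 array, row 0 at the inferior border, column 0 posterior.

Because the circumference is cut at the posterior midline, the posterior wall
maps to the lateral edges of the array and the anterior wall to its centre
(columns 22/23).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from shapely.geometry import Polygon

from .core import ContourStack, DoseGrid, DSM, GeometryError, warn_geometry

PATH_STEP_MM = 3.0
ANGULAR_COUNT = 45
#: anterior midline (180 deg) falls between these two columns; the anterior
#: wall value is taken as their mean
ANTERIOR_COLUMNS = (22, 23)
_SURFACE_RESAMPLE = 90  # longitudinal polylines used to represent the surface


@dataclass
class CentralPath:
    """Arc-length parameterised organ axis: points 3 mm apart with unit tangents."""

    points: np.ndarray  # (n, 3)
    tangents: np.ndarray  # (n, 3), unit norm

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.tangents = np.asarray(self.tangents, dtype=float)
        if len(self.points) < 2:
            raise GeometryError("central path needs at least 2 points")


@dataclass
class Ring:
    """A single planar cut through the contour surface.

    ``points`` is a closed polyline (first vertex not repeated) lying in the
    plane through ``centre`` with unit normal ``normal``.
    """

    points: np.ndarray  # (m, 3)
    centre: np.ndarray  # (3,)
    normal: np.ndarray  # (3,)


def _polygon_angles_resample(verts: np.ndarray, m: int) -> np.ndarray:
    """Resample a closed 2D polygon to m points by arc length.

    The start point is the polygon's boundary intersection with the ray from
    its centroid along +y (posterior) and traversal proceeds from posterior
    toward patient-left (+x), giving every slice a consistent parameterisation
    so that corresponding indices line up across slices.
    """
    poly = Polygon(verts)
    c = np.array([poly.centroid.x, poly.centroid.y])
    # orient clockwise in (x, y): +y -> +x -> -y -> -x
    area = 0.5 * np.sum(
        verts[:, 0] * np.roll(verts[:, 1], -1) - np.roll(verts[:, 0], -1) * verts[:, 1]
    )
    if area > 0:
        verts = verts[::-1]
    # find the boundary point hit by the posterior ray and rotate the vertex
    # list so the polygon starts there
    rel = verts - c
    nxt = np.roll(rel, -1, axis=0)
    # edge p1->p2 intersected with ray t*(0, 1), t > 0
    denom = nxt[:, 0] - rel[:, 0]
    hits: list[tuple[int, float, float]] = []  # (edge index, s along edge, t)
    for i in range(len(rel)):
        p1, p2 = rel[i], nxt[i]
        dx = p2[0] - p1[0]
        if abs(dx) < 1e-12:
            if abs(p1[0]) < 1e-12:
                for s, y in ((0.0, p1[1]), (1.0, p2[1])):
                    if y > 0:
                        hits.append((i, s, y))
            continue
        s = -p1[0] / dx
        if -1e-12 <= s <= 1 + 1e-12:
            y = p1[1] + s * (p2[1] - p1[1])
            if y > 0:
                hits.append((i, float(np.clip(s, 0.0, 1.0)), y))
    del denom
    if not hits:
        raise GeometryError("polygon centroid posterior ray misses the boundary")
    i0, s0, _ = max(hits, key=lambda h: h[2])
    start = rel[i0] + s0 * (nxt[i0] - rel[i0])
    ring = np.vstack([start, rel[i0 + 1 :], rel[: i0 + 1]])
    # drop consecutive duplicates (start may coincide with a vertex)
    keep = np.r_[True, np.linalg.norm(np.diff(ring, axis=0), axis=1) > 1e-9]
    ring = ring[keep]
    closed = np.vstack([ring, ring[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.r_[0.0, np.cumsum(seg)]
    targets = np.linspace(0.0, s[-1], m, endpoint=False)
    x = np.interp(targets, s, closed[:, 0])
    y = np.interp(targets, s, closed[:, 1])
    return np.column_stack([x, y]) + c


def _surface_longitudes(rectum: ContourStack, m: int = _SURFACE_RESAMPLE) -> np.ndarray:
    """(n_slices, m, 3) consistent resampling of every slice polygon.

    Linear interpolation between corresponding points of adjacent slices
    defines the ruled contour surface used for plane cuts.
    """
    out = np.empty((len(rectum.slices), m, 3))
    for i, (z, verts) in enumerate(rectum.slices):
        xy = _polygon_angles_resample(verts, m)
        out[i, :, :2] = xy
        out[i, :, 2] = z
    return out


def central_path(rectum: ContourStack) -> CentralPath:
    """Cubic-spline path through slice centroids, resampled at 3 mm arc length."""
    if len(rectum.slices) < 3:
        raise GeometryError("central path requires at least 3 contour slices")
    cents = rectum.centroids()
    chord = np.linalg.norm(np.diff(cents, axis=0), axis=1)
    if np.any(chord <= 0):
        raise GeometryError("coincident adjacent slice centroids")
    t = np.r_[0.0, np.cumsum(chord)]
    spline = CubicSpline(t, cents, axis=0)
    # dense arc-length table
    td = np.linspace(0.0, t[-1], max(20 * len(t), 400))
    pd = spline(td)
    seg = np.linalg.norm(np.diff(pd, axis=0), axis=1)
    s = np.r_[0.0, np.cumsum(seg)]
    total = s[-1]
    n = int(np.floor(total / PATH_STEP_MM + 1e-9)) + 1
    if n < 2:
        raise GeometryError("organ shorter than two 3 mm path steps")
    s_targets = PATH_STEP_MM * np.arange(n)
    t_targets = np.interp(s_targets, s, td)
    points = spline(t_targets)
    tangents = spline(t_targets, 1)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    return CentralPath(points, tangents)


def _plane_pair_clearance(p1, n1, p2, n2) -> float:
    """Distance from p1/p2 to the intersection line of the two planes.

    Returns +inf for (near-)parallel planes, which cannot intersect inside
    the lumen.
    """
    d = np.cross(n1, n2)
    nd = np.linalg.norm(d)
    if nd < 1e-9:
        return np.inf
    # point on the line: least squares of the two plane equations
    a = np.vstack([n1, n2])
    b = np.array([np.dot(n1, p1), np.dot(n2, p2)])
    x0, *_ = np.linalg.lstsq(a, b, rcond=None)
    d /= nd
    def dist(p):
        v = p - x0
        return float(np.linalg.norm(v - np.dot(v, d) * d))
    return min(dist(p1), dist(p2))


def _corrected_tangents(path: CentralPath, r_max: float, max_iter: int = 50) -> np.ndarray:
    """Re-tilt slicing planes that intersect within the maximum ring radius.

    Offending tangents are replaced by the normalised average of themselves
    and their neighbours until no adjacent pair of planes intersects closer
    to the path than ``r_max``.
    """
    tang = path.tangents.copy()
    pts = path.points
    n = len(pts)
    for it in range(max_iter):
        offending = np.zeros(n, dtype=bool)
        for i in range(n - 1):
            if _plane_pair_clearance(pts[i], tang[i], pts[i + 1], tang[i + 1]) < r_max:
                offending[i] = offending[i + 1] = True
        if not offending.any():
            return tang
        # averaging window widens as iterations progress, so persistent
        # high-curvature segments are smoothed over ever longer stretches
        w = 1 + it // 5
        new = tang.copy()
        for i in np.nonzero(offending)[0]:
            lo, hi = max(0, i - w), min(n, i + w + 1)
            v = tang[lo:hi].sum(axis=0)
            nv = np.linalg.norm(v)
            if nv < 1e-9:
                raise GeometryError("tangent correction degenerate (opposing tangents)")
            new[i] = v / nv
        tang = new
    raise GeometryError("slicing-plane correction failed to converge in 50 iterations")


def slice_rings(rectum: ContourStack, path: CentralPath) -> list[Ring]:
    """Cut the ruled contour surface with a plane at every path point."""
    surf = _surface_longitudes(rectum)
    n_slices, m, _ = surf.shape
    r_max = float(
        max(
            np.max(np.linalg.norm(surf[i, :, :2] - rectum.centroids()[i, :2], axis=1))
            for i in range(n_slices)
        )
    )
    tangents = _corrected_tangents(path, r_max)
    half_step = 0.5 * PATH_STEP_MM
    rings: list[Ring] = []
    for q, t in zip(path.points, tangents):
        d = (surf - q) @ t  # (n_slices, m) signed plane distances
        pts = np.empty((m, 3))
        for j in range(m):
            dj = d[:, j]
            prod = dj[:-1] * dj[1:]
            crossings = np.nonzero(prod <= 0)[0]
            if crossings.size == 0:
                # no transversal crossing: clamp to the tube end when the
                # plane runs off the inferior/superior face (tilted end
                # planes); an interior miss is a genuine geometry error
                k = int(np.argmin(np.abs(dj)))
                if k in (0, len(dj) - 1) or abs(dj[k]) <= half_step:
                    pts[j] = surf[k, j]
                    continue
                raise GeometryError(
                    f"slicing plane at path point {q} misses the contour surface"
                )
            best = None
            for k in crossings:
                denom = dj[k] - dj[k + 1]
                frac = 0.0 if abs(denom) < 1e-12 else dj[k] / denom
                p = surf[k, j] + frac * (surf[k + 1, j] - surf[k, j])
                dist = np.linalg.norm(p - q)
                if best is None or dist < best[0]:
                    best = (dist, p)
            pts[j] = best[1]
        rings.append(Ring(points=pts, centre=np.asarray(q), normal=np.asarray(t)))
    return rings


def _ring_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """In-plane basis: u = projected posterior (+y), v = u x n (toward patient-left)."""
    n = normal / np.linalg.norm(normal)
    yhat = np.array([0.0, 1.0, 0.0])
    u = yhat - np.dot(yhat, n) * n
    nu = np.linalg.norm(u)
    if nu < 1e-9:
        raise GeometryError("slicing plane normal is parallel to posterior axis")
    u /= nu
    v = np.cross(u, n)
    return u, v


def sample_ring(ring: Ring, centre: np.ndarray | None = None) -> np.ndarray:
    """45 equiangular ray-boundary intersections of a ring.

    Point k lies along the in-plane direction k * 8 degrees from the
    projected posterior direction, proceeding toward patient-left.  For a
    ring that is not star-shaped about its centre the farthest intersection
    is taken (with a warning).  Returns an (45, 3) array.
    """
    c = np.asarray(ring.centre if centre is None else centre, dtype=float)
    u, v = _ring_basis(ring.normal)
    rel = ring.points - c
    a = rel @ u
    b = rel @ v
    p1 = np.column_stack([a, b])
    p2 = np.roll(p1, -1, axis=0)
    e = p2 - p1  # (m, 2) edges
    theta = np.deg2rad(360.0 / ANGULAR_COUNT * np.arange(ANGULAR_COUNT))
    dirs = np.column_stack([np.cos(theta), np.sin(theta)])  # (45, 2)
    # solve p1 + s*e = t*dir per (ray, edge)
    cross = lambda w, z: w[..., 0] * z[..., 1] - w[..., 1] * z[..., 0]
    denom = cross(dirs[:, None, :], e[None, :, :])  # (45, m)
    # solving t*dir = p1 + s*e by Cramer's rule
    with np.errstate(divide="ignore", invalid="ignore"):
        s = cross(p1[None, :, :], dirs[:, None, :]) / denom
        tt = cross(p1[None, :, :], e[None, :, :]) / denom
    valid = (np.abs(denom) > 1e-12) & (s >= -1e-9) & (s <= 1 + 1e-9) & (tt > 1e-9)
    out = np.empty((ANGULAR_COUNT, 3))
    for k in range(ANGULAR_COUNT):
        tk = tt[k][valid[k]]
        if tk.size == 0:
            raise GeometryError(f"sampling ray {k} has no boundary intersection")
        # count distinct crossings (shared edge endpoints produce duplicates)
        distinct = np.unique(np.round(tk, 6))
        if distinct.size > 1:
            warn_geometry(
                f"ring not star-shaped about its centre at ray {k}; "
                "taking the farthest boundary intersection"
            )
        r = float(tk.max())
        out[k] = c + r * (dirs[k, 0] * u + dirs[k, 1] * v)
    return out


def compute_dsm(
    rectum: ContourStack, dose: DoseGrid, metadata: dict | None = None
) -> DSM:
    """Full DSM pipeline: path -> corrected cuts -> 45-point sampling -> dose."""
    path = central_path(rectum)
    rings = slice_rings(rectum, path)
    points = np.stack([sample_ring(r) for r in rings])  # (rows, 45, 3)
    doses = dose.sample(points.reshape(-1, 3)).reshape(points.shape[:2])
    return DSM(
        dose=doses,
        points=points,
        row_spacing_mm=PATH_STEP_MM,
        angular_count=ANGULAR_COUNT,
        metadata=metadata or {},
    )
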