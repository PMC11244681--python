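"""Geometry of the dose-surface-map construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dsmkit.core import ContourStack, GeometryError
from dsmkit.dsm_generation import (
    ANGULAR_COUNT,
    PATH_STEP_MM,
    Ring,
    _plane_pair_clearance,
    central_path,
    compute_dsm,
    sample_ring,
    slice_rings,
)
from dsmkit.synthetic_cohort import AnatomyParams, make_rectum

from conftest import circle_polygon, cylinder_stack, linear_z_dose_grid, uniform_dose_grid


class TestCentralPath:
    def test_straight_cylinder_path_on_axis(self):
        path = central_path(cylinder_stack())
        assert len(path.points) == 34
        assert np.abs(path.points[:, :2]).max() < 0.1
        assert np.allclose(path.tangents, [0.0, 0.0, 1.0], atol=1e-6)
        # endpoints coincide with the terminal slice centroids
        assert np.linalg.norm(path.points[0] - [0, 0, 0]) < 1.0
        assert np.linalg.norm(path.points[-1] - [0, 0, 99.0]) < 1.0

    def test_translation_equivariance(self):
        base = central_path(cylinder_stack())
        moved = central_path(cylinder_stack(centre=(10.0, 5.0)))
        assert np.allclose(moved.points, base.points + [10.0, 5.0, 0.0], atol=1e-6)

    def test_spacing_is_3mm(self):
        path = central_path(cylinder_stack(length=90.0))
        steps = np.linalg.norm(np.diff(path.points, axis=0), axis=1)
        assert np.allclose(steps, PATH_STEP_MM, rtol=0.01)

    def test_curved_tube_follows_generating_arc(self):
        r_arc = 300.0
        rect = make_rectum(AnatomyParams(curvature_radius_mm=r_arc))
        path = central_path(rect)
        # generating axis: x = 0, y = R - sqrt(R^2 - z^2)
        z = path.points[:, 2]
        y_expected = r_arc - np.sqrt(r_arc**2 - z**2)
        err = np.hypot(path.points[:, 0], path.points[:, 1] - y_expected)
        assert err.max() < 0.5

    def test_too_few_slices_rejected(self):
        stack = ContourStack(
            "Rectum", [(0.0, circle_polygon(10)), (3.0, circle_polygon(10))]
        )
        with pytest.raises(GeometryError):
            central_path(stack)


class TestSliceRings:
    def test_cylinder_rings_are_circles(self):
        rect = cylinder_stack(radius=12.0)
        path = central_path(rect)
        rings = slice_rings(rect, path)
        assert len(rings) == len(path.points)
        for ring in rings[::7]:
            radii = np.linalg.norm(ring.points - ring.centre, axis=1)
            assert np.allclose(radii, 12.0, rtol=0.01)

    def test_zigzag_centroids_trigger_plane_correction(self):
        # alternating +-3 mm AP centroid offsets at 3 mm z-steps give the
        # naive spline tangents so much tilt that adjacent planes cross
        # inside the lumen; the corrected rings must not
        zs = np.arange(0.0, 45.1, 3.0)
        slices = [
            (float(z), circle_polygon(10.0, centre=(0.0, 3.0 * (-1) ** i)))
            for i, z in enumerate(zs)
        ]
        stack = ContourStack("Rectum", slices)
        path = central_path(stack)
        naive_clearance = min(
            _plane_pair_clearance(
                path.points[i], path.tangents[i], path.points[i + 1], path.tangents[i + 1]
            )
            for i in range(len(path.points) - 1)
        )
        assert naive_clearance < 10.0  # the naive planes do collide in the lumen
        rings = slice_rings(stack, path)
        for a, b in zip(rings[:-1], rings[1:]):
            clearance = _plane_pair_clearance(a.centre, a.normal, b.centre, b.normal)
            assert clearance >= 10.0 * 0.999

    def test_ring_count_matches_path(self):
        rect = cylinder_stack(length=60.0)
        path = central_path(rect)
        assert len(slice_rings(rect, path)) == len(path.points)


def _planar_ring(points_xy: np.ndarray) -> Ring:
    pts = np.column_stack([points_xy, np.zeros(len(points_xy))])
    return Ring(points=pts, centre=np.zeros(3), normal=np.array([0.0, 0.0, 1.0]))


class TestSampleRing:
    def test_circle_distances_and_orientation(self):
        ring = _planar_ring(circle_polygon(10.0, n=720))
        pts = sample_ring(ring)
        assert pts.shape == (ANGULAR_COUNT, 3)
        radii = np.linalg.norm(pts, axis=1)
        assert np.allclose(radii, 10.0, atol=1e-3)
        # k = 0 points posterior (+y) and k = 1 leans toward patient-left (+x)
        assert pts[0, 1] == pytest.approx(10.0, abs=1e-3)
        assert pts[0, 1] == max(pts[:, 1])
        assert pts[1, 0] > 0

    def test_ellipse_matches_closed_form(self):
        a, b = 10.0, 5.0
        ang = np.linspace(0, 2 * np.pi, 2000, endpoint=False)
        # r(theta) measured from posterior: semiaxis a along +y, b along +x
        xy = np.column_stack([b * np.sin(ang), a * np.cos(ang)])
        pts = sample_ring(_planar_ring(xy))
        theta = np.deg2rad(360.0 / ANGULAR_COUNT * np.arange(ANGULAR_COUNT))
        expected = a * b / np.sqrt(b**2 * np.cos(theta) ** 2 + a**2 * np.sin(theta) ** 2)
        assert np.abs(np.linalg.norm(pts, axis=1) - expected).max() < 0.1

    def test_non_star_shaped_takes_farthest_intersection(self):
        # disc of radius 10 with a slot (y in [4, 6], x in [-2, 10]) cut in
        # from the right: the posterior ray crosses the boundary 3 times
        ang = np.linspace(0, 2 * np.pi, 721)[:-1]
        disc = [(10 * np.cos(a), 10 * np.sin(a)) for a in ang if not (
            0.35 < np.sin(a) < 0.65 and np.cos(a) > 0)]
        # walking counter-clockwise from (10, 0), insert the slot vertices in
        # traversal order where the boundary arc was removed
        poly = []
        inserted = False
        for x, y in disc:
            if y > 6 and x > 0 and not inserted:
                poly.extend([(np.sqrt(100 - 16), 4.0), (-2.0, 4.0),
                             (-2.0, 6.0), (np.sqrt(100 - 36), 6.0)])
                inserted = True
            poly.append((x, y))
        ring = _planar_ring(np.array(poly))
        with pytest.warns(RuntimeWarning, match="star-shaped"):
            pts = sample_ring(ring)
        # posterior ray k=0 must land on the outer circle, not the slot
        assert np.linalg.norm(pts[0]) == pytest.approx(10.0, abs=0.05)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_star_shaped_rings_match_generating_radius(self, seed):
        """Brute-force oracle: boundary generated from a known r(theta)."""
        rng = np.random.default_rng(seed)
        k = np.arange(1, 5)
        amp = rng.uniform(-0.8, 0.8, 4)
        phase = rng.uniform(0, 2 * np.pi, 4)

        def radius(theta):
            return 10.0 + sum(a * np.cos(j * theta + p) for a, j, p in zip(amp, k, phase))

        # theta measured from +y toward +x as in the sampling convention
        dense = np.linspace(0, 2 * np.pi, 4000, endpoint=False)
        r = radius(dense)
        xy = np.column_stack([r * np.sin(dense), r * np.cos(dense)])
        pts = sample_ring(_planar_ring(xy))
        theta_k = np.deg2rad(360.0 / ANGULAR_COUNT * np.arange(ANGULAR_COUNT))
        assert np.abs(np.linalg.norm(pts, axis=1) - radius(theta_k)).max() < 0.1


class TestComputeDsm:
    def test_linear_axial_field_oracle(self):
        rect = cylinder_stack(radius=12.0, length=99.0)
        dsm = compute_dsm(rect, linear_z_dose_grid(0.1))
        assert dsm.dose.shape == (34, ANGULAR_COUNT)
        expected = 0.3 * np.arange(34)[:, None]
        assert np.abs(dsm.dose - expected).max() < 0.05

    def test_uniform_field(self):
        rect = cylinder_stack(length=60.0)
        dsm = compute_dsm(rect, uniform_dose_grid(10.0, half=80.0))
        assert np.allclose(dsm.dose, 10.0, atol=1e-9)

    def test_dose_bounded_by_grid(self):
        rect = cylinder_stack(length=60.0)
        grid = linear_z_dose_grid(0.2)
        dsm = compute_dsm(rect, grid)
        assert dsm.dose.min() >= grid.values.min() - 1e-9
        assert dsm.dose.max() <= grid.values.max() + 1e-9

    def test_translation_equivariance(self):
        shift = np.array([7.0, -4.0, 12.0])
        rect = cylinder_stack(length=60.0)
        grid = linear_z_dose_grid(0.1)
        base = compute_dsm(rect, grid)
        moved_grid = type(grid)(grid.origin_mm + shift, grid.spacing_mm, grid.values)
        moved = compute_dsm(rect.translated(shift), moved_grid)
        assert np.abs(moved.dose - base.dose).max() < 1e-6
        assert np.allclose(moved.points - base.points, shift, atol=1e-6)

    def test_rotation_permutes_columns(self):
        # rotating a cylindrical phantom and its dose field about the tube
        # axis by one angular step cyclically permutes DSM columns
        rect = cylinder_stack(radius=12.0, length=30.0)
        half, spacing = 25.0, 1.0
        n = int(2 * half / spacing) + 1
        coord = -half + spacing * np.arange(n)
        zs = np.arange(0, 36.0, 3.0)

        def grid_from(fxy):
            xx, yy = np.meshgrid(coord, coord, indexing="ij")
            plane = fxy(xx, yy)
            vals = np.repeat(plane[:, :, None], len(zs), axis=2)
            from dsmkit.core import DoseGrid

            return DoseGrid(np.array([-half, -half, 0.0]),
                            np.array([spacing, spacing, 3.0]), vals)

        base_field = lambda x, y: 20.0 + 0.5 * x
        phi = np.deg2rad(8.0)  # rotate from posterior toward patient-left
        rot_field = lambda x, y: 20.0 + 0.5 * (np.cos(phi) * x - np.sin(phi) * y)
        base = compute_dsm(rect, grid_from(base_field))
        rotated = compute_dsm(rect, grid_from(rot_field))
        shifts = [
            np.abs(rotated.dose - np.roll(base.dose, s, axis=1)).max() for s in (-1, 1)
        ]
        assert min(shifts) < 0.05

    def test_point_outside_grid_is_an_error(self):
        from dsmkit.core import DoseLookupError

        rect = cylinder_stack(length=99.0)
        small = linear_z_dose_grid(0.1, z_max=60.0)
        with pytest.raises(DoseLookupError):
            compute_dsm(rect, small)

    def test_short_tube_rejected(self):
        stack = ContourStack(
            "Rectum",
            [(0.0, circle_polygon(10)), (1.0, circle_polygon(10)), (2.0, circle_polygon(10))],
        )
        with pytest.raises(GeometryError):
            compute_dsm(stack, uniform_dose_grid())
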