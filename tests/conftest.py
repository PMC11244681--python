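import numpy as np
import pytest

from dsmkit.core import ContourStack, DoseGrid
from dsmkit.synthetic_cohort import AnatomyParams, MotionParams, ZERO_MOTION


def circle_polygon(radius: float, centre=(0.0, 0.0), n: int = 90) -> np.ndarray:
    ang = 2 * np.pi * np.arange(n) / n
    return np.column_stack(
        [centre[0] + radius * np.cos(ang), centre[1] + radius * np.sin(ang)]
    )


def cylinder_stack(
    radius: float = 12.0,
    length: float = 99.0,
    centre=(0.0, 0.0),
    step: float = 3.0,
    name: str = "Rectum",
) -> ContourStack:
    zs = np.arange(0.0, length + 1e-9, step)
    return ContourStack(name, [(float(z), circle_polygon(radius, centre)) for z in zs])


def linear_z_dose_grid(
    slope_gy_per_mm: float = 0.1,
    xy_half: float = 25.0,
    z_max: float = 105.0,
    spacing: float = 2.0,
) -> DoseGrid:
    """Analytic field D = slope * z (z >= 0), trilinear-exact for interpolation."""
    nx = int(2 * xy_half / spacing) + 1
    nz = int(z_max / spacing) + 1
    zs = spacing * np.arange(nz)
    values = np.broadcast_to(
        slope_gy_per_mm * zs[None, None, :], (nx, nx, nz)
    ).copy()
    return DoseGrid(
        origin_mm=np.array([-xy_half, -xy_half, 0.0]),
        spacing_mm=np.full(3, spacing),
        values=values,
    )


def uniform_dose_grid(dose_gy: float = 10.0, half: float = 60.0, spacing: float = 4.0):
    n = int(2 * half / spacing) + 1
    return DoseGrid(
        origin_mm=np.array([-half, -half, -half]),
        spacing_mm=np.full(3, spacing),
        values=np.full((n, n, n), dose_gy),
    )


@pytest.fixture
def anatomy():
    return AnatomyParams()


@pytest.fixture
def small_anatomy():
    """Shorter rectum / coarser dose grid for fast end-to-end tests."""
    return AnatomyParams(rectum_length_mm=60.0)


@pytest.fixture
def zero_motion():
    return ZERO_MOTION


@pytest.fixture
def mild_motion():
    return MotionParams()
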