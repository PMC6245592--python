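"""Shared fixtures: case-study parameter objects and small flow fields."""

import numpy as np
import pytest

import psfcav as p

OT_CASE = 8.0 * np.log(2.0)


@pytest.fixture(scope="session")
def wu_rates():
    return p.WU_MERCHUK


@pytest.fixture(scope="session")
def reparam():
    """Rounded case-study q-set (q2 = 0.3, q4 = 0.5)."""
    return p.CASE_STUDY_REPARAM


@pytest.fixture(scope="session")
def case_light():
    """Bottom-lit Beer-Lambert field with u_av = 1 and Ot = 8 ln 2."""
    return p.LightField.from_average(1.0, OT_CASE, 0.02)


@pytest.fixture
def small_grid():
    return p.Grid2D(16, 16, 0.02)


def zero_field(grid):
    z = np.zeros((grid.nz, grid.nx))
    return p.VelocityField2D(grid=grid, vx=z.copy(), vz=z.copy())


@pytest.fixture
def still_field(small_grid):
    return zero_field(small_grid)


@pytest.fixture(scope="session")
def cavity_re100():
    """One shared Re = 100 cavity solve on a 64^2 grid (a few seconds)."""
    return p.solve_cavity(100.0, p.Grid2D(64, 64, 0.02), tol=1e-7)
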