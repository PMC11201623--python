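"""Shared fixtures: analytic digital shapes and a seeded phantom cohort."""

import numpy as np
import pytest

from mbrisk.containers import Volume
from mbrisk.synthetic_data import PhantomParams, generate_cohort, make_sphere_mask


@pytest.fixture(scope="session")
def sphere_r10():
    """Digital ball of radius 10 mm at 1 mm spacing."""
    return make_sphere_mask(10.0, (16, 16, 16), (32, 32, 32))


@pytest.fixture(scope="session")
def cylinder_r5():
    """Digital cylinder, radius 5, long axis along x."""
    cyl = np.zeros((40, 24, 24), dtype=bool)
    ii = np.indices((40, 24, 24))
    cyl[((ii[1] - 12) ** 2 + (ii[2] - 12) ** 2 <= 25)
        & (ii[0] >= 4) & (ii[0] < 36)] = True
    return cyl


@pytest.fixture(scope="session")
def unit_volume_32():
    return Volume(np.ones((32, 32, 32)))


@pytest.fixture(scope="session")
def default_cohort():
    """The default 70-subject, three-site phantom cohort (seeded)."""
    return generate_cohort(PhantomParams(seed=7))


@pytest.fixture(scope="session")
def small_cohort():
    """A small two-site cohort for fast pipeline tests."""
    params = PhantomParams(
        seed=3,
        site_composition={"siteA": {"G4": 6, "SHH": 0},
                          "siteB": {"G4": 6, "SHH": 0}},
        grid_shape=(40, 40, 40),
    )
    return generate_cohort(params)
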