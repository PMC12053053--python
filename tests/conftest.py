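import time

import pytest

from acoustolev.device import (ParticleSpec, model_A_config, model_B_config)
from acoustolev.gorkov import gorkov_potential, radiation_force
from acoustolev.helmholtz import solve_pressure

#: default production resolution (dx, dy, dz) in meters
DEFAULT_RES = (100e-6, 100e-6, 50e-6)
COARSE_RES = (150e-6, 150e-6, 60e-6)


@pytest.fixture(scope="session")
def spheroid_150um():
    """The reference particle: 150 um diameter, 1099 kg/m^3, tissue-like."""
    return ParticleSpec(radius=75e-6)


@pytest.fixture(scope="session")
def field_A():
    """Model A chamber field at production resolution (timed)."""
    chamber, tmap = model_A_config()
    t0 = time.perf_counter()
    field = solve_pressure(chamber, tmap, resolution=DEFAULT_RES)
    field.solve_seconds = time.perf_counter() - t0
    return field


@pytest.fixture(scope="session")
def field_B():
    chamber, tmap = model_B_config()
    return solve_pressure(chamber, tmap, resolution=DEFAULT_RES)


@pytest.fixture(scope="session")
def field_A_coarse():
    chamber, tmap = model_A_config()
    return solve_pressure(chamber, tmap, resolution=COARSE_RES)


@pytest.fixture(scope="session")
def force_A_coarse(field_A_coarse, spheroid_150um):
    return radiation_force(gorkov_potential(field_A_coarse, spheroid_150um))


@pytest.fixture(scope="session")
def force_A(field_A, spheroid_150um):
    return radiation_force(gorkov_potential(field_A, spheroid_150um))
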