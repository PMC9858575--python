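import numpy as np
import pytest
from hypothesis import settings

from kerma_rbf import grid, physics

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def tables():
    return physics.load_attenuation_tables()


@pytest.fixture(scope="session")
def reference_dataset(tables):
    """Full 1375-position x 6-voltage dataset; built once per session."""
    return grid.reference_dataset(tables=tables)


@pytest.fixture(scope="session")
def coarse_dataset(tables):
    """Small 3 x 5 x 7 grid x 3 voltages (315 samples) for fast model tests."""
    g = grid.build_detector_grid(
        radii_mm=(25.0, 75.0, 125.0),
        theta_max_deg=20.0, theta_step_deg=5.0,
        phi_max_deg=360.0, phi_step_deg=60.0,
    )
    return grid.build_dataset(g, (40.0, 80.0, 140.0), tables=tables)


@pytest.fixture()
def toy_table():
    """3-knot table with easy hand-computable log-log interpolation."""
    return physics.AttenuationTable(
        material="toy",
        energies=np.array([10.0, 40.0, 160.0]),
        mu_over_rho=np.array([8.0, 1.0, 0.125]),
    )
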