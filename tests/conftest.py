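import pytest

from lfnc import RigGeometry, WaveformSpec, enumerate_grid, generate_dataset

DEFAULT_FLOWS = [0.1, 0.3, 0.5, 1.0]


@pytest.fixture(scope="session")
def table_grid():
    """The full bench scenario grid (Table-1 defaults)."""
    return enumerate_grid()


@pytest.fixture(scope="session")
def grid_dataset(table_grid):
    """Noise-free simulated dataset over the full grid and all four flows.

    One deterministic value per scenario x flow (replicates=1); shared
    across tests because the 400 steady-state simulations dominate runtime.
    """
    return generate_dataset(
        table_grid, DEFAULT_FLOWS, noise_sd_pp=0.0, replicates=1
    )


@pytest.fixture(scope="session")
def oracle_geometry():
    """Reservoir-free rig: the closed-form (Benaron-Benitz) regime."""
    return RigGeometry(dead_space_ml=0.0)


@pytest.fixture(scope="session")
def square_wave():
    return WaveformSpec("square")
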