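import numpy as np
import pytest

from scwhydro import ScwParams, generate_shape_series, surface_velocity_series


@pytest.fixture(scope="session")
def scw_params_small() -> ScwParams:
    """Default stated-world wave sampled at a coarser frame interval."""
    return ScwParams(n_frames=36, frame_interval=12.0)


@pytest.fixture(scope="session")
def scw_shapes_small(scw_params_small):
    return generate_shape_series(scw_params_small)


@pytest.fixture(scope="session")
def scw_velocities_small(scw_params_small, scw_shapes_small):
    return surface_velocity_series(scw_shapes_small,
                                   scw_params_small.frame_interval)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def fd_oracle():
    """Finite-difference Stokes oracle on the 90 um cell, factorised once."""
    from fd_stokes import FDStokesOracle

    return FDStokesOracle(radius=90.0, n_r=200, n_theta=200)
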