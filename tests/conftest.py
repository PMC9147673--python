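import pytest

from otrisk.hbm import get_study
from otrisk.pbpk import build_model
from otrisk.reconstruct import ExposureReconstruction, ReconstructionConfig


@pytest.fixture(scope="session")
def default_model():
    """One shared PBPK model handle with published defaults."""
    return build_model()


@pytest.fixture(scope="session")
def worker_forward_map():
    """Shared per-unit-intake forward map for the occupational scenario.

    Building it runs a grid of PBPK simulations, so it is constructed once
    per session and reused by every reconstruction test.
    """
    model = ExposureReconstruction.from_study(
        get_study("labat"), "mean", config=ReconstructionConfig(seed=0))
    return model.forward_map()


@pytest.fixture(scope="session")
def steady_state_forward_map():
    """Forward map for the steady-state sampling plan of the fast generator."""
    model = ExposureReconstruction(
        100.0, "post_shift_spot", plan="steady_state_spot",
        config=ReconstructionConfig(seed=0))
    return model.forward_map()


@pytest.fixture()
def fast_config():
    """Small but functional sampler configuration for unit tests."""
    return ReconstructionConfig(n_iterations=2000, burn_in=500, n_chains=2, seed=42)
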