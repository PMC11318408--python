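import numpy as np
import pytest

from sliceox import SdScenarioParams, SliceModelParams


@pytest.fixture(scope="session")
def slice_params() -> SliceModelParams:
    """Standard slice model: 150 mmHg supply, 160-um core, default constants."""
    return SliceModelParams(surface_po2=150.0, domain_depth=160.0)


@pytest.fixture(scope="session")
def three_depths() -> np.ndarray:
    return np.array([40.0, 100.0, 160.0])


@pytest.fixture(scope="session")
def noiseless_scenario() -> SdScenarioParams:
    return SdScenarioParams(
        noise_sd_po2=0.0, noise_sd_dc=0.0, noise_sd_k_voltage=0.0, seed=7
    )


@pytest.fixture(scope="session")
def noiseless_episode(noiseless_scenario, slice_params):
    """One noiseless synthetic SD episode, shared across tests (generation
    involves thousands of steady-state solves)."""
    from sliceox import generate_sd_episode

    return generate_sd_episode(noiseless_scenario, slice_params)
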