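import numpy as np
import pytest

from sersquant import (
    SUDAN_DILUTION_LEVELS_M,
    PreprocessConfig,
    SimulationConfig,
    default_library,
    preprocess_matrix,
    simulate_dilution_series,
)


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def noiseless_config():
    return SimulationConfig(
        additive_noise_sd=0.0,
        multiplicative_noise_sd=0.0,
        drift_amplitude=0.0,
        replicates=3,
        seed=0,
    )


@pytest.fixture(scope="session")
def noiseless_series(library, noiseless_config):
    """Noiseless 7-level Sudan I dilution series in triplicate."""
    return simulate_dilution_series(
        "sudan_i", SUDAN_DILUTION_LEVELS_M, library, noiseless_config
    )


@pytest.fixture(scope="session")
def noisy_series(library):
    """Dilution series with 1%-of-apex additive noise plus replicate
    variability and drift — the default study conditions."""
    config = SimulationConfig(seed=11)
    return simulate_dilution_series(
        "sudan_i", SUDAN_DILUTION_LEVELS_M, library, config
    )


@pytest.fixture(scope="session")
def snv_noisy(noisy_series):
    Z = preprocess_matrix(noisy_series.intensities, PreprocessConfig(chain="snv_chain"))
    y = noisy_series.concentrations()["sudan_i"].to_numpy()
    return Z, y, noisy_series.sample_ids


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
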