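import warnings

import pytest

from lncregnet.synthetic import SimulationConfig, simulate_dataset

warnings.filterwarnings("ignore", message="dropping .* constant expression rows")


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic dataset (log-normal noise, sigma 0.2)."""
    return simulate_dataset(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def zero_noise_dataset():
    """Noise-free dataset: planted effects are exact."""
    return simulate_dataset(SimulationConfig(seed=5, noise_sigma=0.0))
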