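import numpy as np
import pytest

from crysmech import PullConfig, generate_dataset, preset


@pytest.fixture(scope="session")
def dimer():
    return preset("dimer")


@pytest.fixture(scope="session")
def tetramer():
    return preset("crys_i27_tetramer")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def dimer_batch():
    """Sixty noisy dimer traces at the standard pulling condition with the
    anomalous pathway sampled at 15 %; shared across tests for speed."""
    return generate_dataset([{"construct": "dimer", "n": 60, "seed": 9,
                              "config": {"swap_probability": 0.15, "seed": 9}}])


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free protocol without unfolding intermediates."""
    return PullConfig(seed=1, force_noise_sd=0.0, intermediate_probability=0.0)
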