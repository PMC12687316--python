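import numpy as np
import pytest
from hypothesis import settings

from venomglyco.sequons import ProteinRecord
from venomglyco.simulate import SimulationConfig, simulate, zero_noise_config

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def zero_noise_bundle():
    """Noise-free bundle: occupancy 1, detection 1, exactly 3 compositions/site."""
    return simulate(zero_noise_config(k=3, seed=11))


@pytest.fixture(scope="session")
def default_bundle():
    """Bundle under the generator's default (noisy) study conditions."""
    return simulate(SimulationConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_protein():
    # sites: N at 3 (NGT) and N at 12 (NAS); K/R cleavage points between
    return ProteinRecord("P1", "AANGTKPEPTCNASRGGWDER", toxin_class="SVSP")
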