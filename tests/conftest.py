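import numpy as np
import pytest

from exoarch import synthetic_data as sd


@pytest.fixture(scope="session")
def small_cohort():
    """24-gene synthetic genome + architectures, shared across tests."""
    genome, arches = sd.build_genome(24, seed=101)
    return genome, arches


@pytest.fixture(scope="session")
def exo_model():
    return sd.ExoModel(depth=60.0, stop_jitter_sd=1.0, background_rate=0.005)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
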