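import numpy as np
import pytest

from solubag import load_phenytoin_dataset
from solubag.synthetic_data import GeneratorSpec, generate


@pytest.fixture(scope="session")
def phenytoin():
    return load_phenytoin_dataset()


@pytest.fixture(scope="session")
def synth_quadratic():
    """Moderate-noise degree-2 density surface on an 8x8 grid."""
    return generate(GeneratorSpec(n_temps=8, n_pressures=8, dispersion=0.02, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
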