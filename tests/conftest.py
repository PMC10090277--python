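import numpy as np
import pytest

from nmqsar import chem_data, synthetic_data


@pytest.fixture(scope="session")
def fixture_dataset():
    return chem_data.load_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def planted_table():
    """Noise-free descriptor table with a planted two-descriptor signal."""
    spec = synthetic_data.SyntheticSpec(
        seed=7, n=30, p=8, planted_subset=(0, 3), beta=(3.0, -2.0), noise_sd=0.0
    )
    return synthetic_data.gen_descriptor_table(spec)


@pytest.fixture(scope="session")
def aligned_set():
    """20 pre-aligned toy molecules with a planted electrostatic effect."""
    spec = synthetic_data.SyntheticSpec(seed=11, n=20, noise_sd=0.05, field_effect=(0, "E", 2.0))
    return synthetic_data.gen_aligned_molecules(spec)
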