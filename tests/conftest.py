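import numpy as np
import pytest

import tetrascan as ts
from tetrascan.simulate import DEFAULT_IMPLANT_SHARPNESS, DEFAULT_SHARPNESS


@pytest.fixture(scope="session")
def host_model():
    return ts.make_model(48.0, DEFAULT_SHARPNESS, seed=101, label="host")


@pytest.fixture(scope="session")
def implant_model():
    return ts.make_model(60.0, DEFAULT_IMPLANT_SHARPNESS, seed=202, label="implant")


@pytest.fixture(scope="session")
def implanted_fragment(host_model, implant_model):
    """A 12 kb fragment with a 4 kb implant at [4001, 8000]."""
    record, truth = ts.simulate_fragment(
        12_000, host_model, implant=(implant_model, 4001, 4000), seed=11
    )
    return record, truth


@pytest.fixture(scope="session")
def implanted_matrix(implanted_fragment):
    record, _ = implanted_fragment
    return ts.correlation_matrix(record)


@pytest.fixture(scope="session")
def homogeneous_matrix(host_model):
    record, _ = ts.simulate_fragment(12_000, host_model, seed=12)
    return ts.correlation_matrix(record)


def random_dna(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
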