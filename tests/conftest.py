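import numpy as np
import pytest

from emsrag.backends import MockTextBackend
from emsrag.ed_records import generate_cases, filter_ambulance


@pytest.fixture(scope="session")
def backend():
    return MockTextBackend()


@pytest.fixture(scope="session")
def cases():
    """A small deterministic ambulance-only corpus shared across tests."""
    return filter_ambulance(generate_cases(12, seed=42, walk_in_rate=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
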