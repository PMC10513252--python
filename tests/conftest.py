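import numpy as np
import pytest

from retrodetect import simulate


@pytest.fixture(scope="session")
def fixture_library():
    """A 30-element synthetic library plus background pool (seeded)."""
    return simulate.generate_fixture_library(30, 123)


@pytest.fixture(scope="session")
def max_lengths(fixture_library):
    library, _ = fixture_library
    return simulate.build_max_length_table(library)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
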