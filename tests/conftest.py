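import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from polarcyte.psa import AnalyzerLayout, theoretical_instrument_matrix

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def ideal_matrix():
    """Instrument matrix of the idealized equal-split analyzer."""
    return theoretical_instrument_matrix(AnalyzerLayout.equal_splits())


@pytest.fixture(scope="session")
def default_matrix():
    """Instrument matrix with the realistic 30/21/24.5/24.5 splitter tree."""
    return theoretical_instrument_matrix(AnalyzerLayout())
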