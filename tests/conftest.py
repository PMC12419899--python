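import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from paleobridge.occurrences import CladeDataset
from paleobridge.timescale import load_default_timescale

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ts():
    return load_default_timescale()


@pytest.fixture()
def rng():
    return np.random.Generator(np.random.PCG64(20250925))


@pytest.fixture(scope="session")
def toy_counts():
    """Three fossil bins: 1, 2, 1 species at 10-12 Ma."""
    counts = np.zeros(13, dtype=int)
    counts[10:13] = [1, 2, 1]
    return counts


@pytest.fixture()
def toy_extinct(toy_counts):
    return CladeDataset("toy_extinct", "family", 0, toy_counts.copy())


@pytest.fixture()
def toy_extant(toy_counts):
    return CladeDataset("toy_extant", "family", 25, toy_counts.copy())
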