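import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from oxynet.data_model import InteractionMatrix
from oxynet.synthetic_data import SyntheticConfig, simulate_study

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_matrix(counts, habitat="low"):
    counts = np.asarray(counts)
    return InteractionMatrix(
        species_ids=tuple(f"sp{i}" for i in range(counts.shape[0])),
        host_ids=tuple(f"h{j}" for j in range(counts.shape[1])),
        counts=counts,
        habitat=habitat,
    )


@pytest.fixture
def nested_matrix():
    """Hand-verified perfectly nested weighted matrix (all pair scores 100)."""
    return make_matrix([[3, 2, 1], [2, 1, 0], [1, 0, 0]])


@pytest.fixture
def checkerboard():
    return make_matrix([[1, 0], [0, 1]])


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic study (shared, treated as read-only)."""
    return simulate_study(SyntheticConfig())


@pytest.fixture
def rng():
    return np.random.default_rng(20100315)


def random_count_matrix(rng, n_rows=None, n_cols=None, max_count=9, p_zero=0.35):
    r = n_rows or int(rng.integers(2, 7))
    c = n_cols or int(rng.integers(2, 7))
    counts = rng.integers(1, max_count + 1, size=(r, c))
    counts[rng.random((r, c)) < p_zero] = 0
    if counts.sum() == 0:
        counts[0, 0] = 1
    return make_matrix(counts)
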