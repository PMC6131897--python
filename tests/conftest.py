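import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pureqtl import SimConfig, simulate_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """Compact mixed cohort: 6 groups x 20 genes, 400 samples."""
    return simulate_cohort(SimConfig(n_samples=400, genes_per_group=20, seed=11))


@pytest.fixture(scope="session")
def full_cohort():
    """Study-scale cohort: 6 groups x 100 genes, 1000 samples."""
    return simulate_cohort(SimConfig(n_samples=1000, genes_per_group=100, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
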