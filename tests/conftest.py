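import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nilseq.magic_sim import SimConfig, simulate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


SMALL_SIM = SimConfig(
    seed=7,
    n_genes=300,
    n_decoy_sites=20,
    n_ril=800,
    max_ril_batches=12,
    n_plates_per_class=5,
)


@pytest.fixture(scope="session")
def small_dataset():
    """One modest simulated experiment shared across test modules."""
    return simulate_dataset(SMALL_SIM)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
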