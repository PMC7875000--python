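import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

# deterministic, bounded hypothesis runs
settings.register_profile(
    "default", max_examples=50, derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

warnings.filterwarnings("ignore", category=DeprecationWarning)

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=n, p=p)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fixture_records():
    from mhcscan import load_table1_fixture

    return load_table1_fixture()


@pytest.fixture(scope="session")
def default_sim():
    """One default simulated genome shared by read-only tests."""
    from mhcscan import SimulationConfig, simulate_genome, template_queries

    config = SimulationConfig(seed=42)
    assembly, truth = simulate_genome(config)
    return config, assembly, truth, template_queries(config)
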