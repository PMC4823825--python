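import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "suite", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cohort():
    """A small seeded cohort at exome-like depth with CNV events possible."""
    from dipgevo import SimulationConfig, simulate_cohort
    cfg = SimulationConfig(n_clones=3, n_regions=4, mutations_per_clone=8,
                           mean_depth=70, cnv_rate=0.5, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def deep_cohort():
    """Deep-amplicon cohort without CNV, for reconstruction tests."""
    from dipgevo import SimulationConfig, simulate_cohort
    cfg = SimulationConfig(n_clones=4, n_regions=6, mutations_per_clone=20,
                           mean_depth=4000, cnv_rate=0.0, seed=5)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def branching_cohort():
    """Truncal oncohistone + two complementary partner subclones."""
    from dipgevo.studies import simulate_branching_fixture
    return simulate_branching_fixture(seed=42)
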