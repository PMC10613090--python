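import pytest

from gacalib import SimulationConfig, generate_cohort, simulate_cohort


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(n_records=2750, seed=42)


@pytest.fixture(scope="session")
def cohort_full_20k():
    """Fully observed default cohort, n=20,000 (no availability masking)."""
    return generate_cohort(SimulationConfig(n_records=20000, seed=1))


@pytest.fixture(scope="session")
def cohort_masked(default_config):
    """Default-availability cohort at the study's size (n=2,750)."""
    return simulate_cohort(default_config)
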