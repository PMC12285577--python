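import pytest

from gxlife import SimulationConfig, simulate
from gxlife.genetics import attach_genetic_risk


@pytest.fixture(scope="session")
def default_cohort():
    """Mid-size cohort at the default study conditions."""
    cfg = SimulationConfig(n_participants=20_000, seed=11)
    return attach_genetic_risk(simulate(cfg))


@pytest.fixture(scope="session")
def big_cohort():
    """Large cohort for parameter-recovery and mediation checks."""
    cfg = SimulationConfig(n_participants=50_000, seed=5)
    return attach_genetic_risk(simulate(cfg))
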