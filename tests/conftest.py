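import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import metmem as mm

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> mm.SimulationConfig:
    """A 600-probe study at the default arm sizes — enough probes for every
    category to be populated, small enough to keep tests fast."""
    return mm.SimulationConfig(n_probes=600, seed=7)


@pytest.fixture(scope="session")
def sim_study(small_config):
    """(matrix, design, truth) for a three-month synthetic cohort."""
    return mm.simulate_expression(small_config)


@pytest.fixture(scope="session")
def filtered_study(sim_study, small_config):
    """Normalized + detection-filtered matrix with its comparison table."""
    matrix, design, truth = sim_study
    normalized, _ = mm.normalize(matrix)
    filtered, kept, dropped = mm.detection_filter(normalized, design)
    table = mm.run_all_comparisons(filtered, design)
    return filtered, design, truth, table
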