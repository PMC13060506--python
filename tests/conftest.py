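import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from eftrial import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One small seeded trial shared by read-only tests."""
    return simulate_cohort(CohortConfig(n_per_group=6, seed=11))


@pytest.fixture(scope="session")
def default_config():
    return CohortConfig(n_per_group=6, seed=11)
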