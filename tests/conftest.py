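import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from thyropanel import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """120 nodules, 50 proteins, 5 planted informative, moderate missingness."""
    config = CohortConfig(
        n_per_histotype={"N": 10, "MNG": 40, "FA": 25, "FTC": 20, "PTC": 25},
        n_proteins=50,
        n_informative=5,
        effect_size=2.0,
        missing_fraction_target=0.3,
        seed=123,
    )
    return generate_cohort(config)


@pytest.fixture(scope="session")
def complete_cohort():
    """Same structure without any censoring (complete matrix)."""
    config = CohortConfig(
        n_per_histotype={"N": 10, "MNG": 40, "FA": 25, "FTC": 20, "PTC": 25},
        n_proteins=50,
        n_informative=5,
        effect_size=2.0,
        missing_fraction_target=0.0,
        seed=123,
    )
    return generate_cohort(config)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
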