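import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).resolve().parent))  # for oracles.py


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """One seeded phantom cohort shared by the slower integration tests."""
    from rfmap.phantom import PhantomConfig, generate_cohort

    return generate_cohort(PhantomConfig(seed=7, n_per_class=6))
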