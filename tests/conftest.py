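import numpy as np
import pytest

from nutribias.cohort import CohortConfig, generate


@pytest.fixture(scope="session")
def source_cohort():
    """A study-sized synthetic cohort (n=303) with its generating truths."""
    cfg = CohortConfig(n=303, pilot_n=20000)
    cohort, truth = generate(cfg, rng=np.random.default_rng(20230405))
    return cohort, truth


@pytest.fixture(scope="session")
def tiny_cohort():
    """Deterministic 10-row cohort for brute-force oracles."""
    cfg = CohortConfig(n=10, pilot_n=2000)
    cohort, _ = generate(cfg, rng=np.random.default_rng(7))
    return cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
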