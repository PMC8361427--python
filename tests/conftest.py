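import numpy as np
import pandas as pd
import pytest

from adsig.cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """Shared default-condition cohort, sized for fast unit tests."""
    return generate_cohort(CohortConfig(seed=42, n_pairs=300))


@pytest.fixture(scope="session")
def large_cohort() -> pd.DataFrame:
    """Cohort at the parameter-recovery scale (5000 twin pairs)."""
    return generate_cohort(CohortConfig(seed=42, n_pairs=5000))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
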