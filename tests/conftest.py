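import numpy as np
import pytest

from sdaeval import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def cohort():
    """One medium synthetic cohort shared across tests (20 babies x 20
    seizures, random-intercept SD 1, default planted effects)."""
    records, features, truth = generate_cohort(CohortConfig(seed=11))
    features = features.copy()
    for t in (0.4, 0.5, 0.6):
        features[f"detected_{t}"] = features[f"detected_{t}"].astype(float)
    return records, features, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
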