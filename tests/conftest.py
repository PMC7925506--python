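import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gaitbench as gb

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """The emulated 60-trial campaign at default class separation."""
    return gb.generate_cohort(seed=1)


@pytest.fixture(scope="session")
def default_features(default_cohort):
    """Feature vectors for every trial of the default cohort."""
    return [gb.extract_features(t) for t in default_cohort]


@pytest.fixture(scope="session")
def normalized_matrix(default_features):
    return gb.normalize_features(gb.features_to_matrix(default_features))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
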