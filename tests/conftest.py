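import numpy as np
import pytest

from carrygait import default_config, generate_cohort
from carrygait.pipeline import build_feature_table


@pytest.fixture(scope="session")
def small_cohort():
    """A 4-participant cohort under the default study conditions."""
    return generate_cohort(4, default_config(seed=7))


@pytest.fixture(scope="session")
def small_table(small_cohort):
    return build_feature_table(small_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
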