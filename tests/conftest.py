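import numpy as np
import pytest

from fedistill.synthetic_cohort import default_roster, generate_cohort, partition_non_iid


@pytest.fixture(scope="session")
def roster():
    return default_roster()


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(n=400, prevalence=0.35, effect_scale=1.0, seed=42)


@pytest.fixture(scope="session")
def small_partition(small_cohort, roster):
    return partition_non_iid(small_cohort, roster, skew=0.1, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
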