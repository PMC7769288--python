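import numpy as np
import pytest

from ahglm import (
    CohortSpec,
    generate_cohort,
    generate_volumes,
    hemi3_preset,
    lobar16_preset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(CohortSpec(), seed=7)


@pytest.fixture(scope="session")
def hemi_table(default_cohort):
    return generate_volumes(default_cohort, hemi3_preset(), seed=8)


@pytest.fixture(scope="session")
def lobar_table(default_cohort):
    return generate_volumes(default_cohort, lobar16_preset(), seed=9)
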