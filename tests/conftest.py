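import dataclasses

import numpy as np
import pytest

from digiphen.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """4+4 participants over 2 weeks: big enough for every stage, fast."""
    cfg = dataclasses.replace(CohortConfig(), n_per_group=4, weeks=2, seed=1234)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
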