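import numpy as np
import pytest

import chronnectome as cn


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced two-group cohort (C=10, T=120) shared across tests."""
    cfg = cn.CohortConfig(n_group_a=5, n_group_b=5, C=10, T=120, k_true=3, seed=11)
    return cn.generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def window_spec():
    return cn.WindowSpec()
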