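import numpy as np
import pytest

import deprivix as dx


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study shared by read-only tests."""
    cfg = dx.GeneratorConfig(seed=1, n_cases=120, n_controls=140, n_tracts=30)
    return dx.generate_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
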