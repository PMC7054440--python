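import numpy as np
import pytest

from rotdiag.synthetic_data import GeneratorConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition synthetic cohort shared across tests."""
    return simulate_cohort(GeneratorConfig(seed=20240))


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort for fast structural checks."""
    cfg = GeneratorConfig(
        seed=7, n_persons=60, n_male=16, n_china=35, n_color=29,
        n_analytic=7, n_holistic=7,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
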