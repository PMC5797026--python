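import numpy as np
import pytest

from nkaml import SimConfig, default_panel, generate_cohort


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-patient synthetic cohort shared across tests."""
    return generate_cohort(SimConfig(n_patients=60, seed=7))


@pytest.fixture(scope="session")
def default_cohort():
    """A full-size (393-patient) synthetic cohort."""
    return generate_cohort(SimConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def competing_risk_sample(rng, n, relapse_scale=1.0, death_scale=2.0, cens=(0.2, 3.0)):
    """Exponential competing-risks draws with uniform censoring."""
    t1 = rng.exponential(relapse_scale, n)
    t2 = rng.exponential(death_scale, n)
    c = rng.uniform(*cens, n)
    t = np.minimum(np.minimum(t1, t2), c)
    code = np.where(t == c, 0, np.where(t == t1, 1, 2))
    return t, code
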