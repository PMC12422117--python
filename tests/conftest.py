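import numpy as np
import pytest

from breathdx.synthcohort import CohortSpec, generate_cohort, table_profile


@pytest.fixture(scope="session")
def adult_profile():
    return table_profile("adult")


@pytest.fixture(scope="session")
def small_cohort():
    """20-subject adult cohort (10 asthmatic / 10 control), triplicates."""
    spec = CohortSpec(n_asthmatic=10, n_control=10, age_group="adult", seed=7)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def default_cohort_45():
    """The default study-sized cohort: 20 asthmatic + 25 control adults."""
    spec = CohortSpec(n_asthmatic=20, n_control=25, age_group="adult", seed=3)
    return generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def numeric_grad(f, x, eps=1e-6):
    """Central-difference gradient of scalar f at array x."""
    x = np.asarray(x, dtype=float)
    g = np.zeros_like(x)
    flat = x.ravel()
    gf = g.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        fp = f(x)
        flat[i] = orig - eps
        fm = f(x)
        flat[i] = orig
        gf[i] = (fp - fm) / (2 * eps)
    return g
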