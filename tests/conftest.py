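import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_study():
    """One moderate simulated study shared by read-only tests."""
    from qbill.synthetic_data import simulate_study

    return simulate_study(300, seed=7)


def random_instance(rng, n_max=12, p_max=2, n_min=6):
    """Small generic-position regression instance for oracle comparisons."""
    n = int(rng.integers(n_min, n_max + 1))
    p = int(rng.integers(1, p_max + 1))
    X = rng.standard_normal((n, p))
    y = rng.standard_normal(n) * 2.0 + X @ rng.standard_normal(p)
    return X, y
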