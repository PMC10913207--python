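import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from adaptivepi.models import AdaptivePIParams, adaptive_pi_rhs
from adaptivepi.reference import BASELINE_PARAMS

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def baseline():
    return BASELINE_PARAMS


@pytest.fixture
def rng():
    return np.random.default_rng(20240304)


def random_valid_params(rng) -> tuple:
    """Draw (params, r, d) from the admissible stable regime."""
    params = AdaptivePIParams(
        b=rng.uniform(0.1, 1.0),
        s=rng.uniform(0.1, 2.0),
        l=rng.uniform(0.1, 0.9),
        c=rng.uniform(0.5, 5.0),
    )
    return params, rng.uniform(1.0, 20.0), rng.uniform(0.01, 5.0)


def finite_difference_jacobian(params, state, r, d, step=1e-6) -> np.ndarray:
    """Central-difference Jacobian of the adaptive PI right-hand side."""
    state = np.asarray(state, dtype=float)
    jac = np.empty((2, 2))
    for j in range(2):
        delta = np.zeros(2)
        delta[j] = step
        f_plus = adaptive_pi_rhs(0.0, state + delta, params, r, d)
        f_minus = adaptive_pi_rhs(0.0, state - delta, params, r, d)
        jac[:, j] = (f_plus - f_minus) / (2.0 * step)
    return jac
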