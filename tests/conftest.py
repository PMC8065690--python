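import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from bftrim import DrawMatrix, gaussian

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def conj_models():
    return gaussian.gaussian_models()


@pytest.fixture(scope="session")
def conj_setup():
    """Conjugate Gaussian data with exact truth and large iid draw sets."""
    rng = np.random.default_rng(7)
    y = gaussian.simulate_data(8, 0.2, rng)
    return {
        "y": y,
        "truth_log10_bf_ur": gaussian.closed_form_log10_bf_ur(y),
        "posterior": gaussian.posterior_mu_draws(y, 100_000, rng),
        "prior": gaussian.prior_mu_draws(100_000, rng),
    }


def make_draws(columns, values, **kw):
    return DrawMatrix(pd.DataFrame(np.asarray(values, float), columns=columns), **kw)
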