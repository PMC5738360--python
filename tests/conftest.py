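import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import chachakit as ck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def demo_truth() -> ck.SteadyStateParams:
    """Documented demo truth surface (n = 2.33, K_L on the nM dose scale)."""
    return ck.SteadyStateParams(
        G_max=1000.0, K_L=105.0, K_A=668343.917568615, n_stoich=2.33
    )


@pytest.fixture
def unit_rates() -> ck.ChaChaRateParams:
    return ck.ChaChaRateParams(
        alpha_R=1, alpha_Rstar=1, alpha_A=1, beta_R=1, beta_Rstar=1,
        beta_A=1, beta_C=1, beta_G=1, gamma_C=1, gamma_G=1, n_stoich=1,
    )


@pytest.fixture
def pulse_rates() -> ck.ChaChaRateParams:
    """Slow-degradation rate set used for the reversibility scenario."""
    return ck.ChaChaRateParams(
        alpha_R=1.0, alpha_Rstar=0.001, alpha_A=10.0, beta_R=0.1,
        beta_Rstar=0.1, beta_A=0.1, beta_C=0.02, beta_G=0.05,
        gamma_C=2.2e-6, gamma_G=0.01, n_stoich=2.33,
    )


def random_rate_params(rng: np.random.Generator, n_stoich: float) -> ck.ChaChaRateParams:
    """Loguniform positive rate draw for property checks."""
    def draw(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    return ck.ChaChaRateParams(
        alpha_R=draw(0.1, 10), alpha_Rstar=draw(0.05, 2), alpha_A=draw(0.1, 10),
        beta_R=draw(0.05, 1), beta_Rstar=draw(0.05, 1), beta_A=draw(0.05, 1),
        beta_C=draw(0.05, 1), beta_G=draw(0.05, 1),
        gamma_C=draw(0.01, 1), gamma_G=draw(0.05, 1), n_stoich=n_stoich,
    )
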