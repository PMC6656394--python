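import warnings

import numpy as np
import pytest

import kpsize as kp

# GP-parameter warnings (low ESS on deliberately short chains) are noise in
# most tests; tests that assert on warnings re-enable them locally.
warnings.filterwarnings("ignore", message=".*effective sample size.*")
warnings.filterwarnings("ignore", message=".*acceptance rate.*")


@pytest.fixture(scope="session")
def default_study() -> kp.SyntheticStudy:
    """One synthetic study at the default design (61 areas, 5 training)."""
    return kp.generate_study(kp.SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def fitted_study(default_study):
    """The default study plus a short posterior fit, shared across tests."""
    obs = kp.prepare_observations(default_study.estimates, default_study.areas)
    observed_H = [a for a in default_study.areas if a.has_H]
    draws = kp.run_mcmc(
        obs, observed_H, kp.MCMCConfig(n_iter=3000, n_burn=1500, seed=42)
    )
    return default_study, obs, observed_H, draws


@pytest.fixture(scope="session")
def reference_estimates():
    return kp.load_reference_direct_estimates()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
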