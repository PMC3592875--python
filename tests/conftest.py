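import pytest
from hypothesis import HealthCheck, settings

from markovcea import CostEffectivenessModel

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def results():
    """Fitted base case at the published defaults."""
    return CostEffectivenessModel().fit()


@pytest.fixture(scope="session")
def psa_1000(results):
    """One 1000-iteration PSA, shared across tests that only read it."""
    return results.run_psa(n_iter=1000, seed=2013)
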