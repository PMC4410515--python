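import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def urn_spec():
    from explanationism import UrnSpec
    return UrnSpec()


@pytest.fixture
def two_hyp():
    """Equal-prior two-hypothesis space with the one-black-draw likelihoods."""
    from explanationism import EvidenceModel, HypothesisSpace
    return (HypothesisSpace(["H_A", "H_B"], [0.5, 0.5]),
            EvidenceModel([0.75, 0.375]))


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
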