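import numpy as np
import pytest

from survhta.pipeline import build_decision_model
from survhta.synthetic import (CensoringSpec, TrueArmModel,
                               make_reference_scenario, simulate_arm)


@pytest.fixture(scope="session")
def reference():
    """The synthetic reference scenario: two-arm OS/PFS evidence plus a
    complete economic configuration (seeded, so shared across tests)."""
    return make_reference_scenario(seed=1)


@pytest.fixture(scope="session")
def decision_model(reference):
    """Decision model assembled from the reference scenario (28 fits)."""
    model, meta = build_decision_model(reference.config, reference.datasets)
    return model


@pytest.fixture(scope="session")
def weibull_arm_300():
    """One simulated Weibull arm under trial-like censoring (the digitization
    round-trip subject): n=300, ~30% censored."""
    truth = TrueArmModel("weibull", {"shape": 1.3, "scale": 2.0})
    cens = CensoringSpec(admin_time=2.5, dropout_rate=0.12)
    return truth, simulate_arm(truth, cens, 300, seed=42)
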