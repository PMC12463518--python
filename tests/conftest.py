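import warnings

import pytest

from edflow import ScenarioConfig
from edflow.distributions import DistributionWarning


@pytest.fixture(autouse=True)
def _silence_triangular_warning():
    # the stock service-time table contains one ill-ordered triangular,
    # which is canonicalized with a warning on every config parse
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DistributionWarning)
        yield


@pytest.fixture
def small_config():
    """Quick-running scenario: ~2 days, 2 replications."""
    return ScenarioConfig(
        horizon_days=2.0,
        warmup_days=0.25,
        replications=2,
        seed=7,
    )


@pytest.fixture
def ample_config():
    """No-contention scenario: huge capacities, light arrivals."""
    cfg = ScenarioConfig(
        horizon_days=3.0,
        warmup_days=0.0,
        replications=1,
        seed=3,
    )
    cfg.resources = {k: 500 for k in cfg.resources}
    return cfg


def constant_service_times():
    """All-constant service laws with hand-checkable stage sums."""
    return {
        "registration": "CONST(3)",
        "triage": "CONST(5)",
        "triage_notes": "CONST(4)",
        "consult_notes": "CONST(6)",
        "consult_exam": "CONST(7)",
        "nurse_notes": "CONST(5)",
        "test_ct": "CONST(10)",
        "test_delay": "CONST(8)",
        "test_xray": "CONST(7)",
        "test_lab": "CONST(7)",
        "reassess_exam": "CONST(2)",
        "reassess_notes": "CONST(3)",
        "reassess_nurse_notes": "CONST(4)",
        "discharge_notes": "CONST(1)",
        "discharge": "CONST(2)",
        "discharge_delay": "CONST(3)",
        "single_stage_consult": "CONST(20)",
    }
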