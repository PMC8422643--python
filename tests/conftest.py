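import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dentalcua as d

settings.register_profile(
    "suite", derandomize=True, max_examples=40, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def reference_model() -> d.DecisionModel:
    return d.make_reference_config()


@pytest.fixture(scope="session")
def reference_outcome(reference_model) -> d.CUAOutcome:
    return d.run_cua(reference_model)


@pytest.fixture(scope="session")
def reference_config() -> dict:
    return d.reference_config_dict()


def geometric_utility_oracle(p: float, utility: float, horizon: int,
                             rate: float = 0.0) -> float:
    """Closed-form cumulative utility of the two-state constant-hazard model.

    Occupancy of the live state at the start of cycle t is (1-p)^(t-1); the
    first year is undiscounted (discounting applies beyond one year).
    """
    return sum(
        (utility / 100.0) * (1.0 - p) ** (t - 1) * (1.0 + rate) ** (-(t - 1))
        for t in range(1, horizon + 1)
    )


def geometric_cost_oracle(p: float, annual: float, initial: float,
                          entry: float, horizon: int, rate: float = 0.0) -> float:
    """Closed-form cumulative cost of the two-state constant-hazard model.

    Live-state maintenance accrues on (1-p)^(t-1); the fraction failing at
    the end of cycle t, (1-p)^(t-1) p, pays the terminal entry cost in cycle
    t+1 (none beyond the horizon).
    """
    total = initial
    for t in range(1, horizon + 1):
        df = (1.0 + rate) ** (-(t - 1))
        total += (1.0 - p) ** (t - 1) * annual * df
        if t < horizon:
            df_next = (1.0 + rate) ** (-t)
            total += (1.0 - p) ** (t - 1) * p * entry * df_next
    return total
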