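import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import effortdisc as ed

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

# scipy's trust-region solver occasionally emits harmless divide warnings on
# degenerate jacobian columns (flat blocks); keep test output readable.
warnings.filterwarnings(
    "ignore", message="divide by zero", category=RuntimeWarning)


@pytest.fixture(scope="session")
def spec():
    return ed.DesignSpec()


@pytest.fixture(scope="session")
def small_cohort(spec):
    """A 6-agent default-condition cohort shared across tests."""
    config = ed.CohortConfig(seed=20240, n_agents=6)
    agents, choices = ed.generate_cohort(config, spec)
    return config, agents, choices


@pytest.fixture(scope="session")
def small_ips(small_cohort, spec):
    _, _, choices = small_cohort
    return ed.apply_exclusions(ed.extract_ips(choices, spec), spec)


@pytest.fixture(scope="session")
def small_fits(small_ips, spec):
    """Power + one-parameter fits for the 6-agent cohort (kept small)."""
    return ed.fit_all(small_ips, models=["hyperbolic", "exponential",
                                         "parabolic", "power"],
                      spec=spec, units="both")


def make_ip_frame(spec, fn):
    """Build a complete IP table for one unit x domain from ip = fn(A, E)."""
    rows = []
    for amount in spec.amounts:
        for level in spec.effort_levels:
            rows.append({"amount": amount, "effort_level": level,
                         "ip": float(fn(amount, level))})
    return pd.DataFrame(rows)
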