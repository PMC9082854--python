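import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


def toy_records(premiums, incomes=None, informal=None, income_levels=None, members=None):
    """Hand-sized valid household table for arithmetic oracles."""
    n = len(premiums)
    return pd.DataFrame(
        {
            "household_id": np.arange(n),
            "premium_expenditure": premiums,
            "household_income": incomes if incomes is not None else [1000.0] * n,
            "head_male": [1, 0] * (n // 2) + [1] * (n % 2),
            "head_age_group": ["30-39"] * n,
            "head_education": ["tertiary"] * n,
            "member_over_65": [0] * n,
            "child_under_5": [0] * n,
            "income_level": income_levels if income_levels is not None else ["middle"] * n,
            "region": ["Bogota"] * n,
            "head_works": [1] * n,
            "contributory_member": [1] * n,
            "head_informal": informal if informal is not None else [0] * n,
            "head_occupation": ["private"] * n,
            "n_members": members if members is not None else [3] * n,
        }
    )


@pytest.fixture(scope="session")
def default_params():
    from vphi_demand import StructuralParams

    return StructuralParams()


@pytest.fixture(scope="session")
def clean_survey(default_params):
    """Mid-sized uncontaminated survey with latent truth, shared across tests."""
    import dataclasses

    from vphi_demand import generate

    params = dataclasses.replace(default_params, contamination_rate=0.0)
    return generate(params, 30_000, seed=20_001)


@pytest.fixture(scope="session")
def highshare_params(default_params):
    """Default structure with a raised intercept: ~7% take-up.

    Small-sample work (bootstrap, equality tests) needs enough purchasers
    at n of a few thousand; beta1, rho, sigma_u are unchanged so the
    structural scale (and the truth beta1 = -1) is unchanged.
    """
    import dataclasses

    return dataclasses.replace(default_params, beta0=-0.9, contamination_rate=0.0)
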