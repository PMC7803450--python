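import copy
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from hypercea import base_case_fixture
from hypercea.params import NONFATAL_EVENTS, SEXES

settings.register_profile(
    "repro", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("repro")

REPO_ROOT = Path(__file__).resolve().parents[1]
FIXTURE_DIR = REPO_ROOT / "fixtures" / "base_case"


@pytest.fixture(scope="session")
def base_params():
    """Synthetic base case: age 60, male, 10% 10-year risk."""
    return base_case_fixture(age=60, sex="male", r10=0.10)


@pytest.fixture()
def params(base_params):
    """Mutable copy of the base case for per-test tweaking."""
    return copy.deepcopy(base_params)


def zero_mortality(p):
    """Remove all background mortality in place."""
    p.mortality.lifetable["all_cause_q"] = 0.0
    return p


def zero_cvd_risk(p):
    """Remove all CVD events in place (degenerate no-risk cohort)."""
    p.profile.r10 = 0.0
    p.risk_increment = 0.0
    return p


def flat_utilities(p, value=1.0):
    """Baseline utility == value everywhere, all multipliers 1."""
    p.utilities.baseline["utility"] = value
    for cat in NONFATAL_EVENTS:
        p.utilities.event_multiplier[cat] = 1.0
        p.utilities.post_multiplier[cat] = 1.0
    return p


def no_costs(p):
    """Zero every cost and the adverse-event model in place."""
    p.costs.annual_drug_cost = 0.0
    p.costs.annual_monitoring_cost = 0.0
    p.costs.fatal_event_cost = 0.0
    for cat in NONFATAL_EVENTS:
        p.costs.event_year_cost[cat] = 0.0
        p.costs.post_event_annual_cost[cat] = 0.0
    p.adverse.annual_prob_treated = 0.0
    p.adverse.annual_prob_background = 0.0
    p.adverse.cost_per_event = 0.0
    p.adverse.disutility = 0.0
    return p


def null_treatment(p):
    """Make treatment biologically inert: every relative risk 1."""
    for cat in p.effect.rr:
        p.effect.rr[cat] = 1.0
    p.effect.age_factors["factor"] = 1.0
    return p
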