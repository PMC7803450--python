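"""Synthetic parameter bundles: base-case fixtures and randomized ParamSets.

No deposited dataset exists for this model; it consumes parameter tables.
This module generates complete, internally consistent bundles of the right
structure so every stage of the pipeline is testable offline:

* :func:`base_case_fixture` — a deterministic, realistic-scale UK-like
  bundle (Gompertz lifetable, first-event distribution by age band and sex,
  post-event SMRs, treatment relative risks with age transformation,
  EQ-5D-like utilities, 2016/17-scale costs).  The values are synthetic
  stand-ins chosen once at field-plausible magnitudes; they are not the
  published inputs, which live in sources this package does not bundle.
* :func:`random_paramset` — seeded random but always-valid bundles, the
  workhorse for property tests.
* :func:`default_psa_specs` — role-appropriate sampling distributions for
  the uncertain parameters of any bundle.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .params import (
    EVENT_CATEGORIES,
    FATAL_EVENT,
    NONFATAL_EVENTS,
    SEXES,
    AdverseEventModel,
    CostSet,
    EconSettings,
    EventDistribution,
    MortalityModel,
    ParamSet,
    RiskProfile,
    TreatmentEffect,
    UtilitySet,
)
from .psa import DistributionSpec

__all__ = ["base_case_fixture", "random_paramset", "default_psa_specs", "BASE_AGES", "BASE_RISKS"]

BASE_AGES = (40, 50, 60, 70, 75)
BASE_RISKS = (0.05, 0.10, 0.15, 0.20)

_LIFETABLE_AGES = np.arange(35, 111)

# Gompertz all-cause mortality q(a) = A * exp(B * a), capped
_GOMPERTZ = {"male": (4.0e-5, 0.090), "female": (2.2e-5, 0.092)}

# first-event split by age band and sex; columns follow EVENT_CATEGORIES:
# stable_angina, unstable_angina, mi, stroke, tia, heart_failure, fatal_cvd
_EVENT_BANDS = (40, 59), (60, 74), (75, 115)
_EVENT_SPLIT = {
    "male": (
        (0.20, 0.10, 0.30, 0.16, 0.10, 0.04, 0.10),
        (0.16, 0.09, 0.25, 0.22, 0.11, 0.07, 0.10),
        (0.10, 0.07, 0.20, 0.26, 0.12, 0.12, 0.13),
    ),
    "female": (
        (0.22, 0.10, 0.20, 0.22, 0.12, 0.04, 0.10),
        (0.18, 0.09, 0.17, 0.26, 0.13, 0.07, 0.10),
        (0.11, 0.07, 0.14, 0.29, 0.13, 0.13, 0.13),
    ),
}

_SMR = {"stable_angina": 1.4, "unstable_angina": 1.8, "mi": 2.5, "stroke": 2.2, "tia": 1.5, "heart_failure": 3.0}

_RR = {"stable_angina": 0.90, "unstable_angina": 0.88, "mi": 0.85, "stroke": 0.75, "tia": 0.80, "heart_failure": 0.72, FATAL_EVENT: 0.85}
_AGE_FACTOR_BANDS = ((40, 59, 0.95), (60, 69, 1.00), (70, 115, 1.05))

_UTIL_BANDS = ((35, 49), (50, 59), (60, 69), (70, 79), (80, 115))
_UTIL_BASE = {"male": (0.87, 0.84, 0.80, 0.77, 0.72), "female": (0.85, 0.82, 0.78, 0.74, 0.69)}
_UTIL_EVENT = {"stable_angina": 0.81, "unstable_angina": 0.77, "mi": 0.76, "stroke": 0.63, "tia": 0.90, "heart_failure": 0.68}
_UTIL_POST = {"stable_angina": 0.88, "unstable_angina": 0.88, "mi": 0.88, "stroke": 0.65, "tia": 0.96, "heart_failure": 0.75}

_COST_EVENT = {"stable_angina": 2300.0, "unstable_angina": 3900.0, "mi": 4800.0, "stroke": 11500.0, "tia": 1600.0, "heart_failure": 5900.0}
_COST_POST = {"stable_angina": 250.0, "unstable_angina": 280.0, "mi": 280.0, "stroke": 2100.0, "tia": 120.0, "heart_failure": 1300.0}

#: additive annual risk increase per unit of 10-year risk: each subgroup's
#: annual first-event risk grows by 1% of its 10-year risk per year of age
#: (0.001/year for the 10%-risk base case), keeping the calibration feasible
#: at every risk level
_RISK_INCREMENT_PER_R10 = 0.01


def _lifetable(gompertz=_GOMPERTZ, noncirc_base=0.85, noncirc_slope=0.0025) -> pd.DataFrame:
    rows = []
    for sex in SEXES:
        a_coef, b_coef = gompertz[sex]
        q = np.minimum(a_coef * np.exp(b_coef * _LIFETABLE_AGES), 0.9)
        f = np.clip(noncirc_base - noncirc_slope * (_LIFETABLE_AGES - 40), 0.55, 0.95)
        for age, qi, fi in zip(_LIFETABLE_AGES, q, f):
            rows.append({"age": int(age), "sex": sex, "all_cause_q": float(qi), "noncirc_fraction": float(fi)})
    return pd.DataFrame(rows)


def _event_table(split=_EVENT_SPLIT) -> pd.DataFrame:
    rows = []
    for sex in SEXES:
        for (lo, hi), fracs in zip(_EVENT_BANDS, split[sex]):
            row = {"age_lo": lo, "age_hi": hi, "sex": sex}
            row.update(dict(zip(EVENT_CATEGORIES, fracs)))
            rows.append(row)
    return pd.DataFrame(rows)


def _utility_table(levels=_UTIL_BASE) -> pd.DataFrame:
    rows = []
    for sex in SEXES:
        for (lo, hi), u in zip(_UTIL_BANDS, levels[sex]):
            rows.append({"age_lo": lo, "age_hi": hi, "sex": sex, "utility": u})
    return pd.DataFrame(rows)


def _age_factor_table(bands=_AGE_FACTOR_BANDS) -> pd.DataFrame:
    return pd.DataFrame([{"age_lo": lo, "age_hi": hi, "factor": f} for lo, hi, f in bands])


def base_case_fixture(age: int = 60, sex: str = "male", r10: float = 0.10) -> ParamSet:
    """Synthetic base-case parameter bundle for one scenario.

    Supported scenarios are the study grid: ages 40/50/60/70/75, both sexes,
    10-year risks 5/10/15/20%.  Two fixtures differing only in ``r10`` are
    identical in every other input (ceteris paribus by construction).
    """
    if age not in BASE_AGES:
        raise ValueError(f"unsupported starting age {age}; choose from {BASE_AGES}")
    if sex not in SEXES:
        raise ValueError(f"unsupported sex {sex!r}; choose from {SEXES}")
    if not any(abs(r10 - r) < 1e-12 for r in BASE_RISKS):
        raise ValueError(f"unsupported 10-year risk {r10}; choose from {BASE_RISKS}")
    p = ParamSet(
        settings=EconSettings(),
        profile=RiskProfile(start_age=age, sex=sex, r10=r10),
        events=EventDistribution(_event_table()),
        mortality=MortalityModel(lifetable=_lifetable(), smr=dict(_SMR)),
        effect=TreatmentEffect(rr=dict(_RR), age_factors=_age_factor_table()),
        adverse=AdverseEventModel(
            annual_prob_treated=0.02, annual_prob_background=0.0, cost_per_event=400.0, disutility=0.05
        ),
        utilities=UtilitySet(
            baseline=_utility_table(), event_multiplier=dict(_UTIL_EVENT), post_multiplier=dict(_UTIL_POST)
        ),
        costs=CostSet(
            annual_drug_cost=30.0,
            annual_monitoring_cost=45.0,
            event_year_cost=dict(_COST_EVENT),
            post_event_annual_cost=dict(_COST_POST),
            fatal_event_cost=1700.0,
        ),
        risk_increment=_RISK_INCREMENT_PER_R10 * r10,
        comparator_treatment_delay=None,
    )
    return p.validate()


def random_paramset(seed: int) -> ParamSet:
    """A random but always-valid ParamSet (reproducible by seed).

    Draws every scalar from documented plausible ranges, regenerates the
    stratified tables with random levels under their structural constraints
    (event fractions sum to 1, lifetable mortality non-decreasing in age,
    baseline utility non-increasing in age), and keeps the risk increment
    small enough that the 10-year calibration stays feasible.
    """
    rng = np.random.default_rng(seed)
    sex = str(rng.choice(SEXES))
    start_age = int(rng.integers(40, 76))
    r10 = float(rng.uniform(0.02, 0.30))
    delta = float(rng.uniform(0.0, r10 / 60.0))

    gompertz = {
        s: (float(rng.uniform(1.5e-5, 8e-5)), float(rng.uniform(0.082, 0.098))) for s in SEXES
    }
    # Dirichlet-style split per band: gamma draws normalized to 1
    split = {}
    for s in SEXES:
        w = rng.gamma(2.0, 1.0, size=(len(_EVENT_BANDS), len(EVENT_CATEGORIES)))
        split[s] = tuple(tuple(row / row.sum()) for row in w)

    util_levels = {}
    for s in SEXES:
        u0 = rng.uniform(0.80, 0.95)
        decs = rng.uniform(0.0, 0.05, size=len(_UTIL_BANDS) - 1)
        util_levels[s] = tuple(np.concatenate([[u0], u0 - np.cumsum(decs)]))

    rr = {cat: float(rng.uniform(0.6, 1.0)) for cat in EVENT_CATEGORIES}
    smr = {cat: float(rng.uniform(1.0, 3.0)) for cat in NONFATAL_EVENTS}
    event_mult = {cat: float(rng.uniform(0.5, 1.0)) for cat in NONFATAL_EVENTS}
    post_mult = {cat: float(rng.uniform(0.5, 1.0)) for cat in NONFATAL_EVENTS}
    age_factors = pd.DataFrame(
        [{"age_lo": lo, "age_hi": hi, "factor": float(rng.uniform(0.9, 1.1))} for lo, hi, _ in _AGE_FACTOR_BANDS]
    )

    p = ParamSet(
        settings=EconSettings(wtp_threshold=float(rng.uniform(10_000, 40_000))),
        profile=RiskProfile(start_age=start_age, sex=sex, r10=r10),
        events=EventDistribution(_event_table(split)),
        mortality=MortalityModel(
            lifetable=_lifetable(gompertz, noncirc_base=float(rng.uniform(0.7, 0.9))), smr=smr
        ),
        effect=TreatmentEffect(rr=rr, age_factors=age_factors),
        adverse=AdverseEventModel(
            annual_prob_treated=float(rng.uniform(0.0, 0.05)),
            annual_prob_background=0.0,
            cost_per_event=float(rng.uniform(0.0, 1000.0)),
            disutility=float(rng.uniform(0.0, 0.2)),
        ),
        utilities=UtilitySet(
            baseline=_utility_table(util_levels), event_multiplier=event_mult, post_multiplier=post_mult
        ),
        costs=CostSet(
            annual_drug_cost=float(rng.uniform(10.0, 100.0)),
            annual_monitoring_cost=float(rng.uniform(0.0, 100.0)),
            event_year_cost={cat: float(rng.uniform(1000.0, 15000.0)) for cat in NONFATAL_EVENTS},
            post_event_annual_cost={cat: float(rng.uniform(100.0, 3000.0)) for cat in NONFATAL_EVENTS},
            fatal_event_cost=float(rng.uniform(0.0, 3000.0)),
        ),
        risk_increment=delta,
        comparator_treatment_delay=None,
    )
    return p.validate()


def default_psa_specs(p: ParamSet) -> list[DistributionSpec]:
    """Role-appropriate sampling distributions for a bundle's uncertain inputs.

    Relative risks: lognormal (SD 0.08 on the log scale).  Event and
    post-event costs and the adverse-event cost: gamma with a 20% coefficient
    of variation.  Utility multipliers, adverse-event probability and
    disutility: beta around the base value.  Drug and monitoring costs are
    tariffs and stay fixed.
    """
    specs: list[DistributionSpec] = []
    for cat, value in p.effect.rr.items():
        specs.append(DistributionSpec(f"effect.rr[{cat}]", "lognormal", value, 0.08))
    for cat, value in p.costs.event_year_cost.items():
        specs.append(DistributionSpec(f"costs.event_year_cost[{cat}]", "gamma", value, 0.2 * value))
    for cat, value in p.costs.post_event_annual_cost.items():
        if value > 0:
            specs.append(DistributionSpec(f"costs.post_event_annual_cost[{cat}]", "gamma", value, 0.2 * value))
    for cat, value in p.utilities.event_multiplier.items():
        specs.append(DistributionSpec(f"utilities.event_multiplier[{cat}]", "beta", value, 0.03))
    for cat, value in p.utilities.post_multiplier.items():
        specs.append(DistributionSpec(f"utilities.post_multiplier[{cat}]", "beta", value, 0.03))
    if p.adverse.annual_prob_treated > 0:
        specs.append(DistributionSpec("adverse.annual_prob_treated", "beta", p.adverse.annual_prob_treated, 0.005))
    if p.adverse.cost_per_event > 0:
        specs.append(DistributionSpec("adverse.cost_per_event", "gamma", p.adverse.cost_per_event, 0.2 * p.adverse.cost_per_event))
    if p.adverse.disutility > 0:
        specs.append(DistributionSpec("adverse.disutility", "beta", p.adverse.disutility, 0.01))
    return specs
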