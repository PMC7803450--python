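"""Calibration of annual first-event risk to a 10-year CVD risk.

The annual probability of a first CVD event starts at ``p1`` and increases by
a fixed additive increment ``delta`` each year of age.  ``p1`` is calibrated
so that the schedule, compounded over the 10-year horizon, reproduces the
subgroup's 10-year risk exactly:

    1 - prod_{t=1..H} (1 - (p1 + (t-1) * delta)) = r10

``delta`` is an explicit model input (the constraint alone cannot identify
both unknowns).  Beyond the 10-year horizon the same additive growth
continues for the lifetime of the cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .params import EVENT_CATEGORIES, EventDistribution, MortalityModel, RiskProfile

__all__ = [
    "InfeasibleRiskError",
    "AnnualRiskSchedule",
    "compound_risk",
    "solve_first_event_risk",
    "annual_schedule",
    "non_cvd_death_prob",
    "post_event_death_prob",
]

logger = logging.getLogger(__name__)


class InfeasibleRiskError(ValueError):
    """No first-year risk in (0, 1) can reproduce the target 10-year risk."""


def compound_risk(p1: float, delta: float, horizon: int) -> float:
    """Cumulative event risk over ``horizon`` years of the additive schedule."""
    t = np.arange(horizon)
    return float(1.0 - np.prod(1.0 - (p1 + t * delta)))


def solve_first_event_risk(r10: float, delta: float, horizon: int = 10) -> float:
    """First-year event probability whose additive schedule compounds to ``r10``.

    Solved by bisection: the compounded risk is strictly increasing in ``p1``
    on (0, 1 - (horizon-1)*delta), so the root is unique when it exists.
    ``r10 = 0`` returns 0 (degenerate no-risk limit; requires ``delta = 0``).

    Raises
    ------
    InfeasibleRiskError
        If even ``p1 -> 0`` over-shoots ``r10`` (the age increment alone
        accumulates more than the 10-year risk) or no root is below the cap.
    """
    if not (0.0 <= r10 < 1.0):
        raise ValueError(f"10-year risk must be in [0, 1), got {r10!r}")
    if delta < 0:
        raise ValueError(f"risk increment must be >= 0, got {delta!r}")
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon!r}")
    if r10 == 0.0:
        if delta > 0:
            raise InfeasibleRiskError("r10 = 0 is incompatible with a positive risk increment")
        return 0.0

    lo = 1e-12
    hi = 1.0 - (horizon - 1) * delta - 1e-12
    if hi <= lo:
        raise InfeasibleRiskError(
            f"risk increment delta={delta} leaves no room for a first-year risk over {horizon} years"
        )
    if compound_risk(lo, delta, horizon) > r10:
        raise InfeasibleRiskError(
            f"delta={delta} alone compounds past r10={r10} over {horizon} years; no root in (0, 1)"
        )
    if compound_risk(hi, delta, horizon) < r10:
        raise InfeasibleRiskError(f"r10={r10} unreachable with delta={delta} over {horizon} years")

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if compound_risk(mid, delta, horizon) < r10:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-13:
            break
    return 0.5 * (lo + hi)


@dataclass(eq=False)
class AnnualRiskSchedule:
    """Per-cycle first-event risk and its split across event categories.

    ``p_total[t]`` is the probability that a person still in the well state
    has any first CVD event during cycle ``t`` (0-based); ``p_category[t, k]``
    splits it across :data:`~hypercea.params.EVENT_CATEGORIES` using the event
    distribution for the age reached at that cycle.
    """

    p_total: np.ndarray      # shape (n_cycles,)
    p_category: np.ndarray   # shape (n_cycles, len(EVENT_CATEGORIES))
    capped: bool = False


def annual_schedule(
    p1: float,
    delta: float,
    events: EventDistribution,
    profile: RiskProfile,
    n_cycles: int,
    cap: float = 0.95,
) -> AnnualRiskSchedule:
    """Build the lifetime additive risk schedule for a cohort.

    The total annual risk follows ``p1 + t * delta`` capped at ``cap`` (with a
    logged warning — reaching the cap before the end of the horizon distorts
    the additive growth assumption but keeps probabilities valid).
    """
    t = np.arange(n_cycles)
    p_total = p1 + t * delta
    capped = bool((p_total > cap).any())
    if capped:
        first = int(np.argmax(p_total > cap))
        logger.warning(
            "annual first-event risk reached the cap %.3f at cycle %d; schedule truncated", cap, first
        )
        p_total = np.minimum(p_total, cap)
    ages = np.arange(profile.start_age, profile.start_age + n_cycles)
    fracs = events.fractions_for_ages(ages, profile.sex)
    p_category = p_total[:, None] * fracs
    return AnnualRiskSchedule(p_total=p_total, p_category=p_category, capped=capped)


def non_cvd_death_prob(age: int, sex: str, mortality: MortalityModel) -> float:
    """Annual non-CVD death probability: all-cause q times non-circulatory fraction."""
    q = mortality.all_cause_q(age, sex)
    return q * mortality.noncirc_fraction(age, sex)


def post_event_death_prob(base_q: float, smr: float) -> float:
    """Scale an annual death probability by an SMR on the rate scale.

    q' = 1 - (1 - q)^SMR, i.e. the hazard is multiplied by the SMR; this keeps
    q' in [q, 1] for any SMR >= 1 (naive probability multiplication does not).
    """
    if not (0.0 <= base_q < 1.0):
        raise ValueError(f"base probability must be in [0, 1), got {base_q!r}")
    if smr < 1.0:
        raise ValueError(f"standardized mortality ratio must be >= 1, got {smr!r}")
    return 1.0 - (1.0 - base_q) ** smr
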