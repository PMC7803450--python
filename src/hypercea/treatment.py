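"""Treatment-arm mechanics: relative risks, treatment status, adverse events.

Antihypertensive treatment acts on the model only through (a) relative risks
applied to first CVD events (including fatal ones), (b) annual drug and
monitoring costs, and (c) an expected adverse-event cost and disutility on
on-treatment person-years.  Non-CVD mortality is unaffected by treatment.
"""

from __future__ import annotations

import logging
from typing import Optional

from .params import EVENT_CATEGORIES, TreatmentEffect

__all__ = ["ARMS", "effective_rr", "treated_event_prob", "arm_is_on_treatment"]

logger = logging.getLogger(__name__)

ARMS = ("treated", "comparator")


def effective_rr(effect: TreatmentEffect, event_category: str, age: int) -> float:
    """Relative risk for one event category at one age.

    The category's base RR is multiplied by the age-transformation factor for
    the band containing ``age`` (treatment effects attenuate or strengthen
    with age; the same transformation applies to every category).
    """
    if event_category not in EVENT_CATEGORIES:
        raise ValueError(f"unknown event category {event_category!r}")
    if event_category not in effect.rr:
        raise ValueError(f"no relative risk configured for category {event_category!r}")
    return effect.rr[event_category] * effect.age_factor(age)


def treated_event_prob(p_untreated: float, rr: float) -> float:
    """Event probability under treatment: ``min(p * rr, 1)``."""
    if not (0.0 <= p_untreated <= 1.0):
        raise ValueError(f"probability must be in [0, 1], got {p_untreated!r}")
    if rr <= 0:
        raise ValueError(f"relative risk must be positive, got {rr!r}")
    p = p_untreated * rr
    if p > 1.0:
        logger.warning("treated event probability %.4f capped at 1", p)
        return 1.0
    return p


def arm_is_on_treatment(arm: str, cycle: int, state: str, delay: Optional[int]) -> bool:
    """Whether a person in ``state`` of ``arm`` takes antihypertensives in ``cycle``.

    The treated arm is on treatment whenever alive.  The comparator arm starts
    treatment after any nonfatal CVD event (event-year and post-event states),
    or from cycle ``delay`` onward if a finite delay is configured; in the
    base case (``delay=None``, "never") it otherwise stays untreated for life.
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    if state.startswith("death"):
        return False
    if arm == "treated":
        return True
    if state.startswith(("event_", "post_")):
        return True
    return delay is not None and cycle >= delay
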