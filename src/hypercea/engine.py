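"""Markov cohort engine: 15-state transition matrices, trace, payoffs.

State space (annual cycles):

* ``well`` — alive, no CVD event yet;
* six event-year tunnel states (``event_<category>``), occupied for exactly
  one cycle after a nonfatal first event, carrying first-year costs/utilities;
* six post-event states (``post_<category>``), absorbing apart from death —
  repeat events are not modelled;
* ``death_cvd`` and ``death_noncvd``, absorbing.

Each arm is run as a cohort simulation: the whole cohort starts in ``well``,
occupancy is propagated through per-cycle transition matrices, and costs and
QALYs are accumulated with half-cycle correction and annual discounting.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import annual_schedule, solve_first_event_risk
from .params import EVENT_CATEGORIES, FATAL_EVENT, NONFATAL_EVENTS, ParamSet
from .treatment import arm_is_on_treatment

__all__ = [
    "STATES",
    "STATE_INDEX",
    "WELL",
    "DEATH_CVD",
    "DEATH_NONCVD",
    "EVENT_STATES",
    "POST_STATES",
    "CohortTrace",
    "ArmResult",
    "build_transition_matrix",
    "run_cohort",
    "accumulate",
    "run_arm",
]

logger = logging.getLogger(__name__)

EVENT_STATES = tuple(f"event_{c}" for c in NONFATAL_EVENTS)
POST_STATES = tuple(f"post_{c}" for c in NONFATAL_EVENTS)
STATES: tuple[str, ...] = ("well",) + EVENT_STATES + POST_STATES + ("death_cvd", "death_noncvd")
STATE_INDEX = {s: i for i, s in enumerate(STATES)}
N_STATES = len(STATES)  # 15

WELL = STATE_INDEX["well"]
DEATH_CVD = STATE_INDEX["death_cvd"]
DEATH_NONCVD = STATE_INDEX["death_noncvd"]
_EVENT_IDX = np.array([STATE_INDEX[s] for s in EVENT_STATES])
_POST_IDX = np.array([STATE_INDEX[s] for s in POST_STATES])
_FATAL_COL = EVENT_CATEGORIES.index(FATAL_EVENT)


class _ModelArrays:
    """Age-indexed inputs for one ParamSet, resolved from tables once per run."""

    def __init__(self, p: ParamSet):
        sex = p.profile.sex
        n = p.n_cycles
        self.ages = np.arange(p.profile.start_age, p.profile.start_age + n)
        self.q_all, self.noncirc = p.mortality.arrays_for_ages(self.ages, sex)
        self.age_factor = p.effect.age_factors_for_ages(self.ages)
        self.u_base = p.utilities.baseline_for_ages(self.ages, sex)
        self.rr = np.array([p.effect.rr[cat] for cat in EVENT_CATEGORIES])
        self.smr = np.array([p.mortality.smr[cat] for cat in NONFATAL_EVENTS])
        p1 = solve_first_event_risk(p.profile.r10, p.risk_increment)
        self.schedule = annual_schedule(
            p1, p.risk_increment, p.events, p.profile, n, cap=p.max_annual_risk
        )


def _death_split_arrays(p: ParamSet, arrays: _ModelArrays, cycle: int) -> tuple[np.ndarray, np.ndarray]:
    """(to death_cvd, to death_noncvd) per nonfatal category, one cycle.

    Total mortality in event-year/post-event states is the all-cause
    probability scaled by the category's SMR on the rate scale.  The
    background non-circulatory share goes to non-CVD death; by default the
    remainder (circulatory background plus SMR excess) counts as CVD death.
    With ``excess_death_to_cvd=False`` the total splits by noncirc_fraction.
    """
    q_all = arrays.q_all[cycle]
    f_nc = arrays.noncirc[cycle]
    q_total = 1.0 - (1.0 - q_all) ** arrays.smr
    if p.excess_death_to_cvd:
        q_noncvd = np.full_like(q_total, q_all * f_nc)
        q_cvd = q_total - q_noncvd
    else:
        q_noncvd = q_total * f_nc
        q_cvd = q_total * (1.0 - f_nc)
    return q_cvd, q_noncvd


def _matrix_from_arrays(p: ParamSet, arrays: _ModelArrays, arm: str, cycle: int) -> np.ndarray:
    age = int(arrays.ages[cycle])
    delay = p.comparator_treatment_delay
    m = np.zeros((N_STATES, N_STATES))

    # well row: competing first events (nonfatal, fatal) and non-CVD death
    p_cat = arrays.schedule.p_category[cycle].copy()
    if arm_is_on_treatment(arm, cycle, "well", delay):
        p_cat *= arrays.rr * arrays.age_factor[cycle]
    q_nc = arrays.q_all[cycle] * arrays.noncirc[cycle]
    total_exit = p_cat.sum() + q_nc
    if total_exit > 1.0:
        raise ValueError(
            f"well-state exit probabilities sum to {total_exit:.6f} > 1 at cycle {cycle} (age {age})"
        )
    m[WELL, _EVENT_IDX] = p_cat[: len(NONFATAL_EVENTS)]
    m[WELL, DEATH_CVD] = p_cat[_FATAL_COL]
    m[WELL, DEATH_NONCVD] = q_nc
    m[WELL, WELL] = 1.0 - total_exit

    # event-year and post-event rows: SMR-scaled mortality, no repeat events
    q_cvd, q_noncvd = _death_split_arrays(p, arrays, cycle)
    survive = 1.0 - q_cvd - q_noncvd
    m[_EVENT_IDX, DEATH_CVD] = q_cvd
    m[_EVENT_IDX, DEATH_NONCVD] = q_noncvd
    m[_EVENT_IDX, _POST_IDX] = survive
    m[_POST_IDX, DEATH_CVD] = q_cvd
    m[_POST_IDX, DEATH_NONCVD] = q_noncvd
    m[_POST_IDX, _POST_IDX] = survive

    m[DEATH_CVD, DEATH_CVD] = 1.0
    m[DEATH_NONCVD, DEATH_NONCVD] = 1.0

    row_sums = m.sum(axis=1)
    if np.abs(row_sums - 1.0).max() > 1e-9:
        raise ValueError(f"transition matrix rows deviate from 1: {row_sums}")
    return m


@dataclass(eq=False)
class CohortTrace:
    """State-occupancy proportions at each cycle boundary (rows 0..n_cycles)."""

    occupancy: np.ndarray  # shape (n_cycles + 1, N_STATES)

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def alive(self) -> np.ndarray:
        """Proportion alive at each cycle boundary."""
        return 1.0 - self.occupancy[:, DEATH_CVD] - self.occupancy[:, DEATH_NONCVD]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(STATES))
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\n")


@dataclass(eq=False)
class ArmResult:
    """Discounted lifetime cost and QALYs for one arm, with its trace."""

    arm: str
    discounted_cost: float
    discounted_qalys: float
    life_years: float  # undiscounted
    trace: CohortTrace

    def to_dict(self) -> dict:
        return {
            "arm": self.arm,
            "discounted_cost": self.discounted_cost,
            "discounted_qalys": self.discounted_qalys,
            "life_years": self.life_years,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def build_transition_matrix(p: ParamSet, arm: str, cycle: int, arrays: _ModelArrays | None = None) -> np.ndarray:
    """Row-stochastic transition matrix for one cycle of one arm.

    ``cycle`` is 0-based; transitions happen during the year in which the
    cohort is aged ``start_age + cycle``.
    """
    if cycle >= p.n_cycles:
        raise ValueError(f"cycle {cycle} out of range (horizon {p.n_cycles})")
    if arrays is None:
        arrays = _ModelArrays(p)
    return _matrix_from_arrays(p, arrays, arm, cycle)


def run_cohort(p: ParamSet, arm: str) -> CohortTrace:
    """Propagate the full cohort from ``well`` through the lifetime horizon."""
    n = p.n_cycles
    arrays = _ModelArrays(p)
    occ = np.zeros((n + 1, N_STATES))
    occ[0, WELL] = 1.0
    for t in range(n):
        m = _matrix_from_arrays(p, arrays, arm, t)
        occ[t + 1] = occ[t] @ m
    return CohortTrace(occupancy=occ)


def _payoff_vectors(p: ParamSet, arrays: _ModelArrays, arm: str, cycle: int) -> tuple[np.ndarray, np.ndarray]:
    """(utility weight, recurring annual cost) per state for one cycle."""
    u_base = arrays.u_base[cycle]
    u = np.zeros(N_STATES)
    c = np.zeros(N_STATES)
    u[WELL] = u_base
    for k, cat in enumerate(NONFATAL_EVENTS):
        u[_EVENT_IDX[k]] = u_base * p.utilities.event_multiplier[cat]
        u[_POST_IDX[k]] = u_base * p.utilities.post_multiplier[cat]
        c[_POST_IDX[k]] = p.costs.post_event_annual_cost[cat]
    delay = p.comparator_treatment_delay
    treat_cost = p.costs.annual_drug_cost + p.costs.annual_monitoring_cost
    # expected adverse-event burden and treatment costs on alive person-years
    for i, state in enumerate(STATES):
        if state.startswith("death"):
            continue
        on_trt = arm_is_on_treatment(arm, cycle, state, delay)
        ae_p = p.adverse.annual_prob_treated if on_trt else p.adverse.annual_prob_background
        u[i] -= ae_p * p.adverse.disutility
        c[i] += ae_p * p.adverse.cost_per_event + (treat_cost if on_trt else 0.0)
    if (u < 0).any():
        logger.warning("negative state utility clamped to 0 at cycle %d", cycle)
        u = np.maximum(u, 0.0)
    return u, c


def accumulate(trace: CohortTrace, p: ParamSet, arm: str) -> ArmResult:
    """Half-cycle-corrected, discounted lifetime costs and QALYs for one arm.

    Recurring payoffs (utilities, drug/monitoring/AE/post-event costs) accrue
    on the mean of the two boundary occupancies of each cycle.  One-off event
    costs are not half-cycle corrected: the first-year cost of a nonfatal
    event applies to the full end-of-cycle occupancy of its tunnel state, and
    the fatal-event cost to the cycle's increment in CVD-death occupancy.
    Cycle ``t`` (1-based) is discounted by ``(1 + r)^-t``.
    """
    n = trace.n_cycles
    occ = trace.occupancy
    arrays = _ModelArrays(p)
    r_c = p.settings.discount_rate_costs
    r_q = p.settings.discount_rate_qalys
    event_cost_vec = np.zeros(N_STATES)
    for k, cat in enumerate(NONFATAL_EVENTS):
        event_cost_vec[_EVENT_IDX[k]] = p.costs.event_year_cost[cat]
    alive = trace.alive()

    total_cost = 0.0
    total_qalys = 0.0
    life_years = 0.0
    for t in range(1, n + 1):
        cycle = t - 1
        mean_occ = 0.5 * (occ[t - 1] + occ[t])
        u, c = _payoff_vectors(p, arrays, arm, cycle)
        qalys_t = float(mean_occ @ u)
        cost_t = float(mean_occ @ c) + float(occ[t] @ event_cost_vec)
        d_cvd_death = occ[t, DEATH_CVD] - occ[t - 1, DEATH_CVD]
        cost_t += p.costs.fatal_event_cost * max(d_cvd_death, 0.0)
        total_qalys += qalys_t / (1.0 + r_q) ** t
        total_cost += cost_t / (1.0 + r_c) ** t
        life_years += 0.5 * (alive[t - 1] + alive[t])
    return ArmResult(
        arm=arm,
        discounted_cost=float(total_cost),
        discounted_qalys=float(total_qalys),
        life_years=float(life_years),
        trace=trace,
    )


def run_arm(p: ParamSet, arm: str) -> ArmResult:
    """Run one arm end to end: cohort trace plus discounted payoffs."""
    return accumulate(run_cohort(p, arm), p, arm)
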