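"""Incremental cost-effectiveness: ICER, dominance, NMB, NNT.

The comparison is always treatment minus no treatment from the same ParamSet.
The incremental cost-effectiveness ratio (ICER) is the difference in
discounted lifetime costs divided by the difference in discounted QALYs;
treatment is cost-effective when it dominates (cheaper, more effective) or
its ICER falls at or below the willingness-to-pay threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from .engine import ArmResult
from .params import ParamSet, RiskProfile, TreatmentEffect
from .treatment import effective_rr

__all__ = ["CEResult", "NNTResult", "compare", "compare_arms", "nnt_10yr", "write_results_table"]

_QALY_TIE_TOL = 1e-12


@dataclass
class CEResult:
    """Incremental comparison of treatment vs no treatment."""

    delta_cost: float
    delta_qalys: float
    icer: Optional[float]   # undefined under dominance or zero QALY difference
    label: str              # "icer" | "dominant" | "dominated" | "cost_only"
    nmb: float              # net monetary benefit at the WTP threshold
    wtp: float
    cost_effective_at_wtp: bool

    def icer_or_label(self) -> str:
        return f"{self.icer:.0f}" if self.icer is not None else self.label


def compare(treated: ArmResult, untreated: ArmResult, wtp: float) -> CEResult:
    """Classify the incremental comparison at willingness-to-pay ``wtp``."""
    d_cost = float(treated.discounted_cost - untreated.discounted_cost)
    d_qalys = float(treated.discounted_qalys - untreated.discounted_qalys)
    nmb = float(wtp * d_qalys - d_cost)

    if abs(d_qalys) < _QALY_TIE_TOL and d_cost != 0.0:
        # no QALY difference: cost-minimization, ICER undefined
        return CEResult(d_cost, d_qalys, None, "cost_only", nmb, wtp, d_cost < 0)
    if d_cost < 0 and d_qalys > 0:
        return CEResult(d_cost, d_qalys, None, "dominant", nmb, wtp, True)
    if d_cost > 0 and d_qalys < 0:
        return CEResult(d_cost, d_qalys, None, "dominated", nmb, wtp, False)
    icer = d_cost / d_qalys if abs(d_qalys) >= _QALY_TIE_TOL else None
    cost_effective = bool(d_qalys > 0 and icer is not None and icer <= wtp)
    return CEResult(d_cost, d_qalys, icer, "icer", nmb, wtp, cost_effective)


def compare_arms(treated: ArmResult, untreated: ArmResult, p: ParamSet) -> CEResult:
    return compare(treated, untreated, p.settings.wtp_threshold)


@dataclass
class NNTResult:
    """Number needed to treat over 10 years to avoid one CVD event."""

    value: int        # ceiling of the raw reciprocal
    raw: float
    mean_rr: float    # crude (unweighted) mean of per-event relative risks


def nnt_10yr(r10: float, effect: TreatmentEffect, profile: RiskProfile) -> NNTResult:
    """Crude 10-year number needed to treat.

    Uses the unweighted average of the effective per-event relative risks at
    the profile's starting age:  NNT = 1 / (r10 * (1 - mean RR)), rounded up.
    This is a deliberately simple calculation on the 10-year risk itself, not
    on the modelled lifetime trajectory.
    """
    if not (0.0 < r10 < 1.0):
        raise ValueError(f"10-year risk must be in (0, 1), got {r10!r}")
    rrs = [effective_rr(effect, cat, profile.start_age) for cat in effect.rr]
    mean_rr = sum(rrs) / len(rrs)
    if mean_rr >= 1.0:
        raise ValueError(
            f"mean relative risk {mean_rr:.3f} >= 1: no absolute risk reduction, NNT undefined"
        )
    raw = 1.0 / (r10 * (1.0 - mean_rr))
    return NNTResult(value=math.ceil(raw - 1e-12), raw=raw, mean_rr=mean_rr)


def write_results_table(rows: list[dict], path: str | Path) -> pd.DataFrame:
    """Write a per-subgroup results table (ΔC, ΔQ, ICER, P(cost-effective)) as CSV."""
    df = pd.DataFrame(rows)
    df.to_csv(Path(path), index=False, lineterminator="\n")
    return df
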