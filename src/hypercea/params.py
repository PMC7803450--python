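"""Typed parameter model for the hypertension treatment cost-utility model.

The model compares antihypertensive drug treatment against no treatment in a
cohort with stage 1 hypertension, stratified by 10-year cardiovascular disease
(CVD) risk.  All inputs for one scenario live in a :class:`ParamSet`: economic
settings, the cohort's risk profile, the first-event distribution, mortality,
treatment effects, adverse events, utilities and costs.

Scalar inputs are stored in a YAML config; age/sex-stratified inputs are CSV
tables referenced from the config.  ``load_paramset`` / ``save_paramset``
round-trip a ParamSet through this on-disk layout and validate every invariant.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "NONFATAL_EVENTS",
    "FATAL_EVENT",
    "EVENT_CATEGORIES",
    "SEXES",
    "ParamValidationError",
    "EconSettings",
    "RiskProfile",
    "EventDistribution",
    "MortalityModel",
    "TreatmentEffect",
    "AdverseEventModel",
    "UtilitySet",
    "CostSet",
    "ParamSet",
    "load_paramset",
    "save_paramset",
    "paramsets_equal",
]

SCHEMA_VERSION = 1

#: Nonfatal first-event categories, each with an event-year and post-event state.
NONFATAL_EVENTS: tuple[str, ...] = (
    "stable_angina",
    "unstable_angina",
    "mi",
    "stroke",
    "tia",
    "heart_failure",
)
#: Fatal first CVD events transition straight to CVD death.
FATAL_EVENT = "fatal_cvd"
EVENT_CATEGORIES: tuple[str, ...] = NONFATAL_EVENTS + (FATAL_EVENT,)

SEXES = ("male", "female")


class ParamValidationError(ValueError):
    """Raised when a ParamSet (or a file being loaded) violates an invariant.

    ``errors`` holds ``(field_path, message)`` pairs, one per violation.
    """

    def __init__(self, errors: list[tuple[str, str]]):
        self.errors = list(errors)
        lines = "; ".join(f"{path}: {msg}" for path, msg in self.errors)
        super().__init__(f"invalid parameters: {lines}")


def _check_finite(errors, path, value, lo=None, hi=None):
    if not isinstance(value, (int, float)) or isinstance(value, bool):
        errors.append((path, f"expected a number, got {value!r}"))
        return
    if not math.isfinite(value):
        errors.append((path, f"non-finite value {value!r}"))
        return
    if lo is not None and value < lo:
        errors.append((path, f"value {value} below minimum {lo}"))
    if hi is not None and value > hi:
        errors.append((path, f"value {value} above maximum {hi}"))


def _band_row(table: pd.DataFrame, age: int, sex: Optional[str], context: str) -> pd.Series:
    """Row of a banded table whose [age_lo, age_hi] band contains ``age``."""
    mask = (table["age_lo"] <= age) & (age <= table["age_hi"])
    if sex is not None:
        mask &= table["sex"] == sex
    rows = table[mask]
    if len(rows) == 0:
        raise KeyError(f"{context}: no band covering age={age}" + (f", sex={sex}" if sex else ""))
    return rows.iloc[0]


def _band_values(
    table: pd.DataFrame,
    ages: np.ndarray,
    sex: Optional[str],
    value_cols: list[str],
    context: str,
) -> np.ndarray:
    """Vectorized banded lookup: values for every age in ``ages`` at once.

    Bands are assumed non-overlapping; coverage gaps raise ``KeyError``.
    """
    sub = table[table["sex"] == sex] if sex is not None else table
    sub = sub.sort_values("age_lo")
    lo = sub["age_lo"].to_numpy()
    hi = sub["age_hi"].to_numpy()
    if len(sub) == 0:
        raise KeyError(f"{context}: no rows for sex={sex}")
    idx = np.searchsorted(lo, ages, side="right") - 1
    clipped = np.clip(idx, 0, len(lo) - 1)
    bad = (idx < 0) | (ages > hi[clipped])
    if bad.any():
        missing = np.asarray(ages)[bad]
        raise KeyError(f"{context}: no band covering ages {missing.tolist()}" + (f" for sex={sex}" if sex else ""))
    return sub[value_cols].to_numpy(dtype=float)[clipped]


# ---------------------------------------------------------------------------
# component types
# ---------------------------------------------------------------------------


@dataclass
class EconSettings:
    """Economic evaluation settings (NICE reference case defaults)."""

    cycle_length: float = 1.0           # years; the model is built on annual cycles
    max_cycles: int = 60
    max_age: int = 100                  # horizon truncation: run to this age at most
    discount_rate_costs: float = 0.035  # per annum
    discount_rate_qalys: float = 0.035
    wtp_threshold: float = 20_000.0     # currency per QALY gained
    currency_year: str = "2016/17"

    def validate(self, errors, prefix="settings"):
        if self.cycle_length != 1.0:
            errors.append((f"{prefix}.cycle_length", "only 1-year cycles are supported"))
        if not isinstance(self.max_cycles, int) or self.max_cycles < 1:
            errors.append((f"{prefix}.max_cycles", f"must be an integer >= 1, got {self.max_cycles!r}"))
        _check_finite(errors, f"{prefix}.discount_rate_costs", self.discount_rate_costs, 0.0, 0.1)
        _check_finite(errors, f"{prefix}.discount_rate_qalys", self.discount_rate_qalys, 0.0, 0.1)
        _check_finite(errors, f"{prefix}.wtp_threshold", self.wtp_threshold)
        if isinstance(self.wtp_threshold, (int, float)) and not self.wtp_threshold > 0:
            errors.append((f"{prefix}.wtp_threshold", "willingness-to-pay must be positive"))


@dataclass
class RiskProfile:
    """Cohort starting age, sex and 10-year first-CVD-event risk."""

    start_age: int = 60
    sex: str = "male"
    r10: float = 0.10

    def validate(self, errors, prefix="profile"):
        if not isinstance(self.start_age, int) or not (40 <= self.start_age <= 75):
            errors.append((f"{prefix}.start_age", f"start age must be an integer in [40, 75], got {self.start_age!r}"))
        if self.sex not in SEXES:
            errors.append((f"{prefix}.sex", f"sex must be one of {SEXES}, got {self.sex!r}"))
        # r10 == 0 is accepted as a degenerate no-CVD-risk limit (used for
        # lifetable validation runs); otherwise any risk in (0, 1).
        _check_finite(errors, f"{prefix}.r10", self.r10, 0.0)
        if isinstance(self.r10, (int, float)) and math.isfinite(self.r10) and not (0.0 <= self.r10 < 1.0):
            errors.append((f"{prefix}.r10", f"10-year risk must be in [0, 1), got {self.r10!r}"))


@dataclass(eq=False)
class EventDistribution:
    """Relative distribution of first CVD events by age band and sex.

    ``table`` columns: age_lo, age_hi, sex, then one fraction column per
    category in :data:`EVENT_CATEGORIES`.  Fractions in each stratum sum to 1.
    """

    table: pd.DataFrame

    def fractions(self, age: int, sex: str) -> np.ndarray:
        """Category fractions (ordered as EVENT_CATEGORIES) for the stratum at ``age``."""
        row = _band_row(self.table, age, sex, "event distribution")
        return row[list(EVENT_CATEGORIES)].to_numpy(dtype=float)

    def fractions_for_ages(self, ages: np.ndarray, sex: str) -> np.ndarray:
        """Category fractions for a whole age vector, shape (len(ages), 7)."""
        return _band_values(self.table, ages, sex, list(EVENT_CATEGORIES), "event distribution")

    def validate(self, errors, prefix="events"):
        required = {"age_lo", "age_hi", "sex", *EVENT_CATEGORIES}
        missing = required - set(self.table.columns)
        if missing:
            errors.append((prefix, f"missing columns {sorted(missing)}"))
            return
        for idx, row in self.table.iterrows():
            stratum = f"{prefix}[age {row['age_lo']}-{row['age_hi']}, {row['sex']}]"
            fracs = row[list(EVENT_CATEGORIES)].to_numpy(dtype=float)
            if (fracs < 0).any():
                errors.append((stratum, "negative event fraction"))
            total = float(fracs.sum())
            if abs(total - 1.0) > 1e-9:
                errors.append((stratum, f"event fractions sum to {total!r}, expected 1"))


@dataclass(eq=False)
class MortalityModel:
    """All-cause lifetable, non-circulatory death fraction and post-event SMRs.

    ``lifetable`` columns: age, sex, all_cause_q, noncirc_fraction.
    ``smr`` maps each nonfatal event category to a standardized mortality
    ratio >= 1, applied on the rate scale in event-year and post-event states.
    """

    lifetable: pd.DataFrame
    smr: dict[str, float]

    def _row(self, age: int, sex: str) -> pd.Series:
        rows = self.lifetable[(self.lifetable["age"] == age) & (self.lifetable["sex"] == sex)]
        if len(rows) == 0:
            raise KeyError(f"lifetable: no entry for age={age}, sex={sex}")
        return rows.iloc[0]

    def all_cause_q(self, age: int, sex: str) -> float:
        return float(self._row(age, sex)["all_cause_q"])

    def noncirc_fraction(self, age: int, sex: str) -> float:
        return float(self._row(age, sex)["noncirc_fraction"])

    def arrays_for_ages(self, ages: np.ndarray, sex: str) -> tuple[np.ndarray, np.ndarray]:
        """(all_cause_q, noncirc_fraction) vectors for a whole age range."""
        sub = self.lifetable[self.lifetable["sex"] == sex].sort_values("age")
        table_ages = sub["age"].to_numpy()
        idx = np.searchsorted(table_ages, ages)
        clipped = np.clip(idx, 0, len(table_ages) - 1)
        bad = (idx >= len(table_ages)) | (table_ages[clipped] != ages)
        if bad.any():
            raise KeyError(f"lifetable: no entries for ages {np.asarray(ages)[bad].tolist()}, sex={sex}")
        return (
            sub["all_cause_q"].to_numpy(dtype=float)[clipped],
            sub["noncirc_fraction"].to_numpy(dtype=float)[clipped],
        )

    def validate(self, errors, prefix="mortality"):
        required = {"age", "sex", "all_cause_q", "noncirc_fraction"}
        missing = required - set(self.lifetable.columns)
        if missing:
            errors.append((f"{prefix}.lifetable", f"missing columns {sorted(missing)}"))
            return
        q = self.lifetable["all_cause_q"].to_numpy(dtype=float)
        f = self.lifetable["noncirc_fraction"].to_numpy(dtype=float)
        if not np.isfinite(q).all() or (q < 0).any() or (q > 1).any():
            errors.append((f"{prefix}.lifetable.all_cause_q", "probabilities must be finite and in [0, 1]"))
        if not np.isfinite(f).all() or (f < 0).any() or (f > 1).any():
            errors.append((f"{prefix}.lifetable.noncirc_fraction", "fractions must be finite and in [0, 1]"))
        for cat in NONFATAL_EVENTS:
            if cat not in self.smr:
                errors.append((f"{prefix}.smr.{cat}", "missing standardized mortality ratio"))
            else:
                _check_finite(errors, f"{prefix}.smr.{cat}", self.smr[cat], 1.0)


@dataclass(eq=False)
class TreatmentEffect:
    """Relative risks of CVD events on treatment, with an age adjustment.

    ``rr`` maps event categories (including fatal CVD) to base relative risks;
    ``age_factors`` (columns age_lo, age_hi, factor) is the multiplicative age
    transformation applied to every category's RR.
    """

    rr: dict[str, float]
    age_factors: pd.DataFrame
    n_drugs_scenario: str = "1 drug"

    def age_factor(self, age: int) -> float:
        return float(_band_row(self.age_factors, age, None, "rr age factors")["factor"])

    def age_factors_for_ages(self, ages: np.ndarray) -> np.ndarray:
        return _band_values(self.age_factors, ages, None, ["factor"], "rr age factors")[:, 0]

    def validate(self, errors, prefix="effect"):
        for cat, value in self.rr.items():
            if cat not in EVENT_CATEGORIES:
                errors.append((f"{prefix}.rr.{cat}", f"unknown event category {cat!r}"))
                continue
            _check_finite(errors, f"{prefix}.rr.{cat}", value)
            if isinstance(value, (int, float)) and math.isfinite(value) and value <= 0:
                errors.append((f"{prefix}.rr.{cat}", "relative risk must be positive"))
        missing = {"age_lo", "age_hi", "factor"} - set(self.age_factors.columns)
        if missing:
            errors.append((f"{prefix}.age_factors", f"missing columns {sorted(missing)}"))
        else:
            fac = self.age_factors["factor"].to_numpy(dtype=float)
            if not np.isfinite(fac).all() or (fac <= 0).any():
                errors.append((f"{prefix}.age_factors.factor", "factors must be finite and positive"))


@dataclass
class AdverseEventModel:
    """Expected annual treatment adverse-event burden (no explicit AE state).

    ``annual_prob_treated`` applies to on-treatment, alive person-years;
    ``annual_prob_background`` to off-treatment person-years (0 by default).
    """

    annual_prob_treated: float = 0.0
    annual_prob_background: float = 0.0
    cost_per_event: float = 0.0
    disutility: float = 0.0

    def validate(self, errors, prefix="adverse"):
        _check_finite(errors, f"{prefix}.annual_prob_treated", self.annual_prob_treated, 0.0, 1.0)
        _check_finite(errors, f"{prefix}.annual_prob_background", self.annual_prob_background, 0.0, 1.0)
        _check_finite(errors, f"{prefix}.cost_per_event", self.cost_per_event, 0.0)
        _check_finite(errors, f"{prefix}.disutility", self.disutility, 0.0, 1.0)


@dataclass(eq=False)
class UtilitySet:
    """General-population baseline utilities and CVD event multipliers.

    Event/post-event multipliers are applied multiplicatively to the baseline
    utility; adverse events enter as an additive disutility elsewhere.
    ``baseline`` columns: age_lo, age_hi, sex, utility.
    """

    baseline: pd.DataFrame
    event_multiplier: dict[str, float]
    post_multiplier: dict[str, float]

    def baseline_utility(self, age: int, sex: str) -> float:
        return float(_band_row(self.baseline, age, sex, "baseline utility")["utility"])

    def baseline_for_ages(self, ages: np.ndarray, sex: str) -> np.ndarray:
        return _band_values(self.baseline, ages, sex, ["utility"], "baseline utility")[:, 0]

    def validate(self, errors, prefix="utilities"):
        missing = {"age_lo", "age_hi", "sex", "utility"} - set(self.baseline.columns)
        if missing:
            errors.append((f"{prefix}.baseline", f"missing columns {sorted(missing)}"))
        else:
            u = self.baseline["utility"].to_numpy(dtype=float)
            if not np.isfinite(u).all() or (u < 0).any() or (u > 1).any():
                errors.append((f"{prefix}.baseline.utility", "utilities must be finite and in [0, 1]"))
        for name, mult in (("event_multiplier", self.event_multiplier), ("post_multiplier", self.post_multiplier)):
            for cat in NONFATAL_EVENTS:
                if cat not in mult:
                    errors.append((f"{prefix}.{name}.{cat}", "missing utility multiplier"))
                    continue
                _check_finite(errors, f"{prefix}.{name}.{cat}", mult[cat], 0.0, 1.0)
                v = mult[cat]
                if isinstance(v, (int, float)) and math.isfinite(v) and v <= 0:
                    errors.append((f"{prefix}.{name}.{cat}", "multiplier must be in (0, 1]"))


@dataclass(eq=False)
class CostSet:
    """Annual treatment costs and CVD event costs (2016/17 currency).

    ``event_year_cost`` is a one-off first-year cost per nonfatal event;
    ``post_event_annual_cost`` recurs every subsequent year in the post-event
    state; ``fatal_event_cost`` is a one-off cost per fatal CVD event.
    """

    annual_drug_cost: float
    annual_monitoring_cost: float
    event_year_cost: dict[str, float]
    post_event_annual_cost: dict[str, float]
    fatal_event_cost: float = 0.0

    def validate(self, errors, prefix="costs"):
        _check_finite(errors, f"{prefix}.annual_drug_cost", self.annual_drug_cost, 0.0)
        _check_finite(errors, f"{prefix}.annual_monitoring_cost", self.annual_monitoring_cost, 0.0)
        _check_finite(errors, f"{prefix}.fatal_event_cost", self.fatal_event_cost, 0.0)
        for name, costs in (("event_year_cost", self.event_year_cost), ("post_event_annual_cost", self.post_event_annual_cost)):
            for cat in NONFATAL_EVENTS:
                if cat not in costs:
                    errors.append((f"{prefix}.{name}.{cat}", "missing cost"))
                else:
                    _check_finite(errors, f"{prefix}.{name}.{cat}", costs[cat], 0.0)


@dataclass(eq=False)
class ParamSet:
    """Complete input bundle for one model scenario (both arms)."""

    settings: EconSettings
    profile: RiskProfile
    events: EventDistribution
    mortality: MortalityModel
    effect: TreatmentEffect
    adverse: AdverseEventModel
    utilities: UtilitySet
    costs: CostSet
    #: additive annual increase in first-event risk (fraction/year)
    risk_increment: float = 0.0
    #: cycle at which the no-treatment arm starts treatment anyway; None = never
    comparator_treatment_delay: Optional[int] = None
    #: attribute post-event excess mortality (beyond background non-circulatory
    #: deaths) to CVD death; if False, split all deaths by noncirc_fraction
    excess_death_to_cvd: bool = True
    #: cap on the additive annual first-event risk schedule
    max_annual_risk: float = 0.95

    # -- derived -----------------------------------------------------------

    @property
    def n_cycles(self) -> int:
        """Cycles actually run: the horizon stops at ``settings.max_age``."""
        return max(1, min(self.settings.max_cycles, self.settings.max_age - self.profile.start_age))

    def validate(self) -> "ParamSet":
        """Check every invariant; raise :class:`ParamValidationError` on failure."""
        errors: list[tuple[str, str]] = []
        self.settings.validate(errors)
        self.profile.validate(errors)
        self.events.validate(errors)
        self.mortality.validate(errors)
        self.effect.validate(errors)
        self.adverse.validate(errors)
        self.utilities.validate(errors)
        self.costs.validate(errors)
        _check_finite(errors, "risk_increment", self.risk_increment, 0.0)
        _check_finite(errors, "max_annual_risk", self.max_annual_risk)
        if isinstance(self.max_annual_risk, float) and not (0 < self.max_annual_risk < 1):
            errors.append(("max_annual_risk", "cap must be in (0, 1)"))
        if self.comparator_treatment_delay is not None and (
            not isinstance(self.comparator_treatment_delay, int) or self.comparator_treatment_delay < 0
        ):
            errors.append(("comparator_treatment_delay", "must be a non-negative integer or None"))
        if errors:
            raise ParamValidationError(errors)
        # band/lifetable coverage over every age the cohort reaches
        if isinstance(self.profile.start_age, int):
            ages = np.arange(self.profile.start_age, self.profile.start_age + self.n_cycles)
            try:
                self.events.fractions_for_ages(ages, self.profile.sex)
                self.mortality.arrays_for_ages(ages, self.profile.sex)
                self.effect.age_factors_for_ages(ages)
                self.utilities.baseline_for_ages(ages, self.profile.sex)
            except KeyError as exc:
                raise ParamValidationError([("coverage", str(exc))]) from exc
        return self


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_TABLE_FILES = {
    "events": "events.csv",
    "lifetable": "lifetable.csv",
    "age_factors": "rr_age_factors.csv",
    "baseline_utility": "baseline_utility.csv",
}


def _dataclass_to_dict(obj) -> dict:
    return {f.name: getattr(obj, f.name) for f in fields(obj)}


def save_paramset(p: ParamSet, path: str | Path) -> Path:
    """Write ``p`` as ``config.yaml`` plus CSV tables under directory ``path``.

    The representation reloads bit-identically for non-float fields and within
    1e-12 for floats (in practice exactly: floats round-trip through repr).
    Returns the path of the config file.
    """
    p.validate()
    directory = Path(path)
    directory.mkdir(parents=True, exist_ok=True)

    config = {
        "schema_version": SCHEMA_VERSION,
        "settings": _dataclass_to_dict(p.settings),
        "profile": _dataclass_to_dict(p.profile),
        "risk_increment": p.risk_increment,
        "comparator_treatment_delay": (
            "never" if p.comparator_treatment_delay is None else p.comparator_treatment_delay
        ),
        "excess_death_to_cvd": p.excess_death_to_cvd,
        "max_annual_risk": p.max_annual_risk,
        "mortality": {"smr": dict(sorted(p.mortality.smr.items()))},
        "effect": {
            "rr": dict(sorted(p.effect.rr.items())),
            "n_drugs_scenario": p.effect.n_drugs_scenario,
        },
        "adverse": _dataclass_to_dict(p.adverse),
        "utilities": {
            "event_multiplier": dict(sorted(p.utilities.event_multiplier.items())),
            "post_multiplier": dict(sorted(p.utilities.post_multiplier.items())),
        },
        "costs": {
            "annual_drug_cost": p.costs.annual_drug_cost,
            "annual_monitoring_cost": p.costs.annual_monitoring_cost,
            "fatal_event_cost": p.costs.fatal_event_cost,
            "event_year_cost": dict(sorted(p.costs.event_year_cost.items())),
            "post_event_annual_cost": dict(sorted(p.costs.post_event_annual_cost.items())),
        },
        "tables": dict(_TABLE_FILES),
    }
    config_path = directory / "config.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=True, default_flow_style=False))

    tables = {
        "events": p.events.table[["age_lo", "age_hi", "sex", *EVENT_CATEGORIES]],
        "lifetable": p.mortality.lifetable[["age", "sex", "all_cause_q", "noncirc_fraction"]],
        "age_factors": p.effect.age_factors[["age_lo", "age_hi", "factor"]],
        "baseline_utility": p.utilities.baseline[["age_lo", "age_hi", "sex", "utility"]],
    }
    for key, df in tables.items():
        # shortest round-trip float repr keeps save -> load -> save byte-identical
        df.to_csv(
            directory / _TABLE_FILES[key],
            index=False,
            lineterminator="\n",
            float_format=lambda x: repr(float(x)),
        )
    return config_path


def load_paramset(path: str | Path) -> ParamSet:
    """Load and fully validate a ParamSet from a config file or its directory."""
    path = Path(path)
    config_path = path / "config.yaml" if path.is_dir() else path
    if not config_path.exists():
        raise FileNotFoundError(f"no such config file: {config_path}")
    directory = config_path.parent
    raw = yaml.safe_load(config_path.read_text())
    errors: list[tuple[str, str]] = []

    def section(name) -> dict:
        value = raw.get(name)
        if not isinstance(value, dict):
            errors.append((name, "missing or malformed section"))
            return {}
        return value

    def table(key) -> pd.DataFrame:
        filename = section("tables").get(key, _TABLE_FILES[key])
        file = directory / filename
        if not file.exists():
            errors.append((f"tables.{key}", f"missing table file {file.name}"))
            return pd.DataFrame()
        return pd.read_csv(file, float_precision="round_trip")

    try:
        settings = EconSettings(**section("settings"))
        profile = RiskProfile(**section("profile"))
        adverse = AdverseEventModel(**section("adverse"))
    except TypeError as exc:
        raise ParamValidationError(errors + [("config", str(exc))]) from exc

    effect_raw = section("effect")
    utilities_raw = section("utilities")
    costs_raw = section("costs")
    mortality_raw = section("mortality")
    if errors:
        raise ParamValidationError(errors)

    delay_raw = raw.get("comparator_treatment_delay", "never")
    delay = None if delay_raw in (None, "never") else delay_raw

    p = ParamSet(
        settings=settings,
        profile=profile,
        events=EventDistribution(table("events")),
        mortality=MortalityModel(lifetable=table("lifetable"), smr=dict(mortality_raw.get("smr", {}))),
        effect=TreatmentEffect(
            rr=dict(effect_raw.get("rr", {})),
            age_factors=table("age_factors"),
            n_drugs_scenario=effect_raw.get("n_drugs_scenario", "1 drug"),
        ),
        adverse=adverse,
        utilities=UtilitySet(
            baseline=table("baseline_utility"),
            event_multiplier=dict(utilities_raw.get("event_multiplier", {})),
            post_multiplier=dict(utilities_raw.get("post_multiplier", {})),
        ),
        costs=CostSet(
            annual_drug_cost=costs_raw.get("annual_drug_cost", float("nan")),
            annual_monitoring_cost=costs_raw.get("annual_monitoring_cost", float("nan")),
            event_year_cost=dict(costs_raw.get("event_year_cost", {})),
            post_event_annual_cost=dict(costs_raw.get("post_event_annual_cost", {})),
            fatal_event_cost=costs_raw.get("fatal_event_cost", 0.0),
        ),
        risk_increment=raw.get("risk_increment", 0.0),
        comparator_treatment_delay=delay,
        excess_death_to_cvd=raw.get("excess_death_to_cvd", True),
        max_annual_risk=raw.get("max_annual_risk", 0.95),
    )
    if errors:
        raise ParamValidationError(errors)
    return p.validate()


def _floats_close(a, b, tol):
    if isinstance(a, float) or isinstance(b, float):
        return abs(float(a) - float(b)) <= tol or (math.isnan(a) and math.isnan(b))
    return a == b


def paramsets_equal(a: ParamSet, b: ParamSet, float_tol: float = 1e-12) -> bool:
    """Structural equality of two ParamSets with a float tolerance."""

    def close(x, y):
        if isinstance(x, pd.DataFrame):
            if list(x.columns) != list(y.columns) or len(x) != len(y):
                return False
            for col in x.columns:
                xv, yv = x[col].to_numpy(), y[col].to_numpy()
                if xv.dtype.kind == "f" or yv.dtype.kind == "f":
                    if not np.allclose(xv.astype(float), yv.astype(float), atol=float_tol, rtol=0):
                        return False
                elif not (xv == yv).all():
                    return False
            return True
        if isinstance(x, dict):
            return set(x) == set(y) and all(close(x[k], y[k]) for k in x)
        if hasattr(x, "__dataclass_fields__"):
            return all(close(getattr(x, f.name), getattr(y, f.name)) for f in fields(x))
        if isinstance(x, float) or isinstance(y, float):
            return _floats_close(x, y, float_tol)
        return x == y

    return close(a, b)
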