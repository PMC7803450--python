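"""Probabilistic sensitivity analysis (PSA) and acceptability curves.

Each PSA draw resamples uncertain inputs from per-parameter distributions
chosen by role — beta for probabilities and utility multipliers, gamma for
costs, lognormal for relative risks — reruns both arms, and records the
incremental cost and QALY pair.  The probability that treatment is
cost-effective at a willingness-to-pay threshold λ is the fraction of draws
with positive net monetary benefit; sweeping λ gives the cost-effectiveness
acceptability curve (CEAC).
"""

from __future__ import annotations

import copy
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .economics import compare
from .engine import run_arm
from .params import ParamSet, ParamValidationError

__all__ = ["DistributionSpec", "PSAResult", "sample_paramset", "run_psa", "default_wtp_grid"]

# spec family aliases by parameter role
_FAMILY_ALIASES = {
    "beta": "beta",
    "bounded": "beta",
    "gamma": "gamma",
    "positive": "gamma",
    "lognormal": "lognormal",
    "log-scale": "lognormal",
    "fixed": "fixed",
}

_SEGMENT_RE = re.compile(r"^(\w+)(?:\[(\w+)\])?$")
_MAX_RESAMPLE = 50


@dataclass
class DistributionSpec:
    """Sampling rule for one scalar parameter of a ParamSet.

    ``path`` addresses the parameter with dots and dict keys, e.g.
    ``costs.annual_drug_cost`` or ``effect.rr[stroke]``.  ``mean`` is the
    base-case value (for lognormal: the median, i.e. the base RR); ``se`` is
    the uncertainty — a standard error on the natural scale for beta/gamma,
    and the standard deviation of the log for lognormal.
    """

    path: str
    family: str
    mean: float
    se: float = 0.0

    def canonical_family(self) -> str:
        key = self.family.lower().split("-on-")[0]
        for alias, canon in _FAMILY_ALIASES.items():
            if key.startswith(alias):
                return canon
        raise ValueError(f"unknown distribution family {self.family!r}")

    def sample(self, rng: np.random.Generator) -> float:
        family = self.canonical_family()
        if family == "fixed" or self.se == 0.0:
            return self.mean
        if family == "beta":
            if not (0.0 < self.mean < 1.0):
                raise ValueError(f"{self.path}: beta mean must be in (0,1), got {self.mean}")
            v = self.se**2
            cap = self.mean * (1.0 - self.mean)
            if v >= cap:
                raise ValueError(f"{self.path}: beta variance {v} too large for mean {self.mean}")
            nu = cap / v - 1.0
            a, b = self.mean * nu, (1.0 - self.mean) * nu
            return float(stats.beta.rvs(a, b, random_state=rng))
        if family == "gamma":
            if self.mean <= 0:
                raise ValueError(f"{self.path}: gamma mean must be positive, got {self.mean}")
            shape = (self.mean / self.se) ** 2
            scale = self.se**2 / self.mean
            return float(stats.gamma.rvs(shape, scale=scale, random_state=rng))
        if family == "lognormal":
            if self.mean <= 0:
                raise ValueError(f"{self.path}: lognormal median must be positive, got {self.mean}")
            return float(stats.lognorm.rvs(self.se, scale=self.mean, random_state=rng))
        raise AssertionError(family)


def _resolve(p: ParamSet, path: str):
    """Return (container, key_or_attr, is_item) for a dotted parameter path."""
    obj = p
    segments = path.split(".")
    for i, seg in enumerate(segments):
        m = _SEGMENT_RE.match(seg)
        if m is None:
            raise KeyError(f"malformed parameter path segment {seg!r} in {path!r}")
        name, key = m.group(1), m.group(2)
        last = i == len(segments) - 1
        if not hasattr(obj, name):
            raise KeyError(f"parameter path {path!r}: no attribute {name!r}")
        if key is None:
            if last:
                return obj, name, False
            obj = getattr(obj, name)
        else:
            container = getattr(obj, name)
            if key not in container:
                raise KeyError(f"parameter path {path!r}: no key {key!r} in {name}")
            if last:
                return container, key, True
            obj = container[key]
    raise AssertionError


def _set_path(p: ParamSet, path: str, value: float) -> None:
    container, key, is_item = _resolve(p, path)
    if is_item:
        container[key] = value
    else:
        setattr(container, key, value)


def sample_paramset(
    base: ParamSet,
    specs: Sequence[DistributionSpec],
    seed: int,
    draw_index: int,
) -> ParamSet:
    """One reproducible PSA draw: resample every spec'd parameter of ``base``.

    Parameters without a spec keep their base values.  A draw violating a
    ParamSet invariant is resampled (fresh substream) up to a bounded number
    of retries, then raises.
    """
    for spec in specs:  # fail fast on dangling paths
        _resolve(base, spec.path)
    last_error: Exception | None = None
    for attempt in range(_MAX_RESAMPLE):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(draw_index, attempt)))
        draw = copy.deepcopy(base)
        try:
            for spec in specs:
                _set_path(draw, spec.path, spec.sample(rng))
            return draw.validate()
        except ParamValidationError as exc:
            last_error = exc
    raise ParamValidationError(
        [("psa", f"draw {draw_index} failed validation after {_MAX_RESAMPLE} resamples: {last_error}")]
    )


def default_wtp_grid() -> np.ndarray:
    """CEAC grid: £0 to £50 000 per QALY in £1000 steps."""
    return np.arange(0.0, 50_001.0, 1000.0)


@dataclass(eq=False)
class PSAResult:
    """Paired incremental draws, CEAC, and probability cost-effective at λ."""

    delta_costs: np.ndarray
    delta_qalys: np.ndarray
    wtp: float
    prob_cost_effective: float
    ceac: pd.DataFrame  # columns: wtp, probability
    seed: int
    n_draws: int

    def prob_at(self, wtp: float) -> float:
        """Fraction of draws with positive net monetary benefit at ``wtp``."""
        return float(np.mean(wtp * self.delta_qalys - self.delta_costs > 0))

    def mean_icer(self) -> float:
        """ICER of the mean incremental point (costs and QALYs averaged first)."""
        return float(np.mean(self.delta_costs) / np.mean(self.delta_qalys))

    def scatter_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"delta_cost": self.delta_costs, "delta_qalys": self.delta_qalys})

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.scatter_frame().to_csv(directory / "psa_scatter.csv", index=False, lineterminator="\n")
        self.ceac.to_csv(directory / "ceac.csv", index=False, lineterminator="\n")
        summary = {
            "seed": self.seed,
            "n_draws": self.n_draws,
            "wtp": self.wtp,
            "prob_cost_effective": self.prob_cost_effective,
            "mean_delta_cost": float(np.mean(self.delta_costs)),
            "mean_delta_qalys": float(np.mean(self.delta_qalys)),
        }
        (directory / "psa_summary.json").write_text(json.dumps(summary, indent=2) + "\n")


def run_psa(
    base: ParamSet,
    specs: Sequence[DistributionSpec],
    n_draws: int = 5000,
    seed: int = 0,
    wtp_grid: Optional[np.ndarray] = None,
) -> PSAResult:
    """Monte-Carlo propagation of parameter uncertainty through both arms."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    wtp = base.settings.wtp_threshold
    if wtp_grid is None:
        wtp_grid = default_wtp_grid()
    d_costs = np.empty(n_draws)
    d_qalys = np.empty(n_draws)
    for i in range(n_draws):
        draw = sample_paramset(base, specs, seed, i)
        res = compare(run_arm(draw, "treated"), run_arm(draw, "comparator"), wtp)
        d_costs[i] = res.delta_cost
        d_qalys[i] = res.delta_qalys
    ceac_probs = [float(np.mean(lam * d_qalys - d_costs > 0)) for lam in wtp_grid]
    ceac = pd.DataFrame({"wtp": np.asarray(wtp_grid, dtype=float), "probability": ceac_probs})
    return PSAResult(
        delta_costs=d_costs,
        delta_qalys=d_qalys,
        wtp=wtp,
        prob_cost_effective=float(np.mean(wtp * d_qalys - d_costs > 0)),
        ceac=ceac,
        seed=seed,
        n_draws=n_draws,
    )
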