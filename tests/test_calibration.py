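import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import brentq

from hypercea import (
    EventDistribution,
    InfeasibleRiskError,
    MortalityModel,
    RiskProfile,
    annual_schedule,
    compound_risk,
    non_cvd_death_prob,
    post_event_death_prob,
    solve_first_event_risk,
)
from hypercea.params import EVENT_CATEGORIES


class TestSolveFirstEventRisk:
    def test_zero_risk_limit(self):
        assert solve_first_event_risk(0.0, 0.0) == 0.0
        assert solve_first_event_risk(1e-8, 0.0) < 1e-8

    def test_constant_risk_closed_form(self):
        # with no age increment, p1 = 1 - (1 - r10)^(1/10); built from p1=0.01
        r10 = 1.0 - (1.0 - 0.01) ** 10
        assert solve_first_event_risk(r10, 0.0) == pytest.approx(0.01, abs=1e-10)

    def test_matches_independent_root_finder(self):
        r10, delta, horizon = 0.10, 0.001, 10
        oracle = brentq(
            lambda p1: compound_risk(p1, delta, horizon) - r10, 1e-12, 1.0 - 9 * delta - 1e-12,
            xtol=1e-14,
        )
        assert solve_first_event_risk(r10, delta) == pytest.approx(oracle, abs=1e-10)

    def test_infeasible_delta_raises(self):
        # the increment alone compounds past the 10-year risk
        with pytest.raises(InfeasibleRiskError):
            solve_first_event_risk(0.01, 0.01)
        with pytest.raises(InfeasibleRiskError):
            solve_first_event_risk(0.5, 0.2)

    @given(
        r10=st.floats(0.001, 0.6),
        delta_frac=st.floats(0.0, 1.0),
    )
    def test_calibration_inversion_property(self, r10, delta_frac):
        """Compounding the calibrated schedule over 10 years recovers r10."""
        delta = delta_frac * r10 / 60.0
        p1 = solve_first_event_risk(r10, delta)
        assert compound_risk(p1, delta, 10) == pytest.approx(r10, abs=1e-9)
        assert p1 + 9 * delta < 1

    @given(r10=st.floats(0.01, 0.5), bump=st.floats(1e-4, 0.1))
    def test_p1_monotone_in_r10(self, r10, bump):
        delta = r10 / 100.0
        assert solve_first_event_risk(min(r10 + bump, 0.7), delta) > solve_first_event_risk(r10, delta)

    @given(r10=st.floats(0.05, 0.5))
    def test_p1_decreases_with_delta(self, r10):
        assert solve_first_event_risk(r10, r10 / 100.0) < solve_first_event_risk(r10, 0.0)


def _two_band_events(split_young, split_old, boundary=62):
    rows = []
    for lo, hi, split in ((35, boundary - 1, split_young), (boundary, 115, split_old)):
        row = {"age_lo": lo, "age_hi": hi, "sex": "male"}
        row.update(dict(zip(EVENT_CATEGORIES, split)))
        rows.append(row)
    return EventDistribution(pd.DataFrame(rows))


class TestAnnualSchedule:
    def test_constant_when_delta_zero(self):
        events = _two_band_events([0, 0, 0.5, 0.5, 0, 0, 0], [0, 0, 0.5, 0.5, 0, 0, 0])
        sched = annual_schedule(0.02, 0.0, events, RiskProfile(60, "male", 0.1), 10)
        assert np.allclose(sched.p_total, 0.02)
        # proportional split: MI 0.01, stroke 0.01
        assert sched.p_category[0, EVENT_CATEGORIES.index("mi")] == pytest.approx(0.01)
        assert sched.p_category[0, EVENT_CATEGORIES.index("stroke")] == pytest.approx(0.01)

    def test_additive_rule(self):
        events = _two_band_events([1, 0, 0, 0, 0, 0, 0], [1, 0, 0, 0, 0, 0, 0])
        sched = annual_schedule(0.01, 0.002, events, RiskProfile(60, "male", 0.1), 5)
        assert np.allclose(sched.p_total, 0.01 + 0.002 * np.arange(5))

    def test_band_boundary_switches_split_at_correct_cycle(self):
        # age 60 start; the split flips from all-MI to all-stroke at age 62 = cycle 2
        events = _two_band_events([0, 0, 1, 0, 0, 0, 0], [0, 0, 0, 1, 0, 0, 0], boundary=62)
        sched = annual_schedule(0.02, 0.0, events, RiskProfile(60, "male", 0.1), 4)
        mi, stroke = EVENT_CATEGORIES.index("mi"), EVENT_CATEGORIES.index("stroke")
        assert np.allclose(sched.p_category[:2, mi], 0.02)
        assert np.allclose(sched.p_category[:2, stroke], 0.0)
        assert np.allclose(sched.p_category[2:, mi], 0.0)
        assert np.allclose(sched.p_category[2:, stroke], 0.02)

    def test_cap_warns_but_does_not_raise(self, caplog):
        events = _two_band_events([1, 0, 0, 0, 0, 0, 0], [1, 0, 0, 0, 0, 0, 0])
        with caplog.at_level("WARNING"):
            sched = annual_schedule(0.5, 0.1, events, RiskProfile(60, "male", 0.1), 10, cap=0.9)
        assert sched.capped
        assert sched.p_total.max() == 0.9
        assert "cap" in caplog.text


class TestMortalityScaling:
    @pytest.fixture()
    def lifetable(self):
        return MortalityModel(
            lifetable=pd.DataFrame(
                [{"age": 60, "sex": "male", "all_cause_q": 0.02, "noncirc_fraction": 0.7}]
            ),
            smr={c: 1.0 for c in EVENT_CATEGORIES[:-1]},
        )

    def test_non_cvd_death_prob_is_product(self, lifetable):
        assert non_cvd_death_prob(60, "male", lifetable) == pytest.approx(0.014)

    def test_non_cvd_death_prob_limits(self, lifetable):
        lifetable.lifetable["noncirc_fraction"] = 1.0
        assert non_cvd_death_prob(60, "male", lifetable) == 0.02
        lifetable.lifetable["noncirc_fraction"] = 0.0
        assert non_cvd_death_prob(60, "male", lifetable) == 0.0

    def test_age_outside_lifetable_errors(self, lifetable):
        with pytest.raises(KeyError):
            non_cvd_death_prob(40, "male", lifetable)

    def test_smr_identity_and_zero(self):
        assert post_event_death_prob(0.123, 1.0) == pytest.approx(0.123)
        assert post_event_death_prob(0.0, 5.0) == 0.0

    def test_smr_closed_form(self):
        assert post_event_death_prob(0.01, 2.0) == pytest.approx(1 - 0.99**2)

    @given(q=st.floats(1e-9, 0.5), smr=st.floats(1.0, 10.0))
    def test_smr_rate_scale_equivalence_and_monotonicity(self, q, smr):
        qp = post_event_death_prob(q, smr)
        assert 0.0 <= qp <= 1.0
        assert qp >= q - 1e-15  # equality at smr=1 up to float round-off
        # hazard multiplication: q' = 1 - exp(-smr * (-ln(1-q)))
        assert qp == pytest.approx(1 - np.exp(-smr * (-np.log1p(-q))), rel=1e-9, abs=1e-12)
        assert post_event_death_prob(q, smr + 0.5) >= qp
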