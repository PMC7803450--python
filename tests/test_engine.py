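import numpy as np
import pytest

from hypercea import (
    ParamSet,
    accumulate,
    build_transition_matrix,
    run_arm,
    run_cohort,
    solve_first_event_risk,
)
from hypercea.engine import DEATH_CVD, DEATH_NONCVD, STATE_INDEX, STATES, WELL
from hypercea.params import EVENT_CATEGORIES, NONFATAL_EVENTS
from hypercea.synthetic import random_paramset

from conftest import flat_utilities, no_costs, zero_cvd_risk, zero_mortality
from microsim import binomial_3se, microsimulate

N = len(STATES)


def _allowed_mask():
    """Boolean mask of transitions the model structure permits."""
    allowed = np.zeros((N, N), dtype=bool)
    allowed[WELL, WELL] = True
    allowed[WELL, DEATH_CVD] = allowed[WELL, DEATH_NONCVD] = True
    for cat in NONFATAL_EVENTS:
        ev, po = STATE_INDEX[f"event_{cat}"], STATE_INDEX[f"post_{cat}"]
        allowed[WELL, ev] = True
        allowed[ev, po] = allowed[ev, DEATH_CVD] = allowed[ev, DEATH_NONCVD] = True
        allowed[po, po] = allowed[po, DEATH_CVD] = allowed[po, DEATH_NONCVD] = True
    allowed[DEATH_CVD, DEATH_CVD] = True
    allowed[DEATH_NONCVD, DEATH_NONCVD] = True
    return allowed


class TestTransitionMatrix:
    def test_death_rows_are_absorbing_unit_vectors(self, params):
        m = build_transition_matrix(params, "treated", 0)
        for i in (DEATH_CVD, DEATH_NONCVD):
            expected = np.zeros(N)
            expected[i] = 1.0
            assert np.array_equal(m[i], expected)

    def test_no_risk_no_mortality_freezes_the_cohort(self, params):
        """With zero risks and mortality nothing moves: well and post-event
        rows are identity; event-year tunnels still exit to their post state."""
        zero_mortality(zero_cvd_risk(params))
        m = build_transition_matrix(params, "comparator", 0)
        for state in ("well", "death_cvd", "death_noncvd", *(f"post_{c}" for c in NONFATAL_EVENTS)):
            i = STATE_INDEX[state]
            expected = np.zeros(N)
            expected[i] = 1.0
            assert np.array_equal(m[i], expected)
        for cat in NONFATAL_EVENTS:
            assert m[STATE_INDEX[f"event_{cat}"], STATE_INDEX[f"post_{cat}"]] == 1.0

    def test_well_row_matches_hand_calculation(self, params):
        """Spreadsheet-style check of the untreated well row at cycle 0."""
        age, sex = 60, "male"
        p1 = solve_first_event_risk(params.profile.r10, params.risk_increment)
        fracs = params.events.fractions(age, sex)
        q_nc = params.mortality.all_cause_q(age, sex) * params.mortality.noncirc_fraction(age, sex)
        m = build_transition_matrix(params, "comparator", 0)
        for k, cat in enumerate(NONFATAL_EVENTS):
            assert m[WELL, STATE_INDEX[f"event_{cat}"]] == pytest.approx(p1 * fracs[k], rel=1e-12)
        assert m[WELL, DEATH_CVD] == pytest.approx(p1 * fracs[-1], rel=1e-12)
        assert m[WELL, DEATH_NONCVD] == pytest.approx(q_nc, rel=1e-12)
        assert m[WELL, WELL] == pytest.approx(1 - p1 * fracs.sum() - q_nc, rel=1e-12)

    def test_treated_well_row_applies_rr_with_age_factor(self, params):
        p1 = solve_first_event_risk(params.profile.r10, params.risk_increment)
        fracs = params.events.fractions(60, "male")
        m = build_transition_matrix(params, "treated", 0)
        k = NONFATAL_EVENTS.index("stroke")
        rr = params.effect.rr["stroke"] * params.effect.age_factor(60)
        assert m[WELL, STATE_INDEX["event_stroke"]] == pytest.approx(p1 * fracs[k] * rr, rel=1e-12)

    def test_post_event_mortality_uses_smr_split(self, params):
        """Event/post rows: rate-scale SMR on all-cause mortality, background
        non-circulatory share to non-CVD death, remainder to CVD death."""
        age = 60
        q_all = params.mortality.all_cause_q(age, "male")
        f_nc = params.mortality.noncirc_fraction(age, "male")
        m = build_transition_matrix(params, "comparator", 0)
        for cat in ("mi", "heart_failure"):
            q_total = 1 - (1 - q_all) ** params.mortality.smr[cat]
            ev = STATE_INDEX[f"event_{cat}"]
            po = STATE_INDEX[f"post_{cat}"]
            assert m[ev, DEATH_NONCVD] == pytest.approx(q_all * f_nc, rel=1e-12)
            assert m[ev, DEATH_CVD] == pytest.approx(q_total - q_all * f_nc, rel=1e-12)
            assert m[ev, po] == pytest.approx(1 - q_total, rel=1e-12)
            assert np.array_equal(m[po, [DEATH_CVD, DEATH_NONCVD, po]], m[ev, [DEATH_CVD, DEATH_NONCVD, po]])

    def test_structural_zeros(self, params):
        allowed = _allowed_mask()
        for cycle in (0, 15, 30):
            for arm in ("treated", "comparator"):
                m = build_transition_matrix(params, arm, cycle)
                assert (m[~allowed] == 0).all()


class TestRunCohort:
    def test_cycle_one_occupancy_is_first_well_row(self, params):
        trace = run_cohort(params, "treated")
        m0 = build_transition_matrix(params, "treated", 0)
        assert np.allclose(trace.occupancy[1], m0[WELL], atol=1e-15)
        assert trace.occupancy[0, WELL] == 1.0

    def test_immortal_eventless_cohort_stays_well(self, params):
        zero_mortality(zero_cvd_risk(params))
        params.profile.start_age = 40  # full 60-cycle horizon
        trace = run_cohort(params, "comparator")
        assert trace.n_cycles == 60
        assert np.array_equal(trace.occupancy[:, WELL], np.ones(61))

    @pytest.mark.parametrize("seed", range(8))
    def test_conservation_and_death_monotonicity(self, seed):
        p = random_paramset(seed)
        for arm in ("treated", "comparator"):
            trace = run_cohort(p, arm)
            assert np.abs(trace.occupancy.sum(axis=1) - 1).max() < 1e-9
            assert (trace.occupancy >= -1e-15).all()
            for col in (DEATH_CVD, DEATH_NONCVD):
                assert (np.diff(trace.occupancy[:, col]) >= -1e-15).all()

    def test_matches_microsimulation(self, params):
        """Cohort trace vs an individual-level sampling oracle (3 binomial SEs)."""
        params.settings.max_cycles = 10
        params.profile.r10 = 0.20
        params.risk_increment = 0.002
        n_people = 20_000
        trace = run_cohort(params, "treated")
        freq = microsimulate(params, "treated", n_people, seed=7)
        tol = binomial_3se(trace.occupancy, n_people)
        assert (np.abs(freq - trace.occupancy) <= tol).all()


class TestAccumulate:
    @pytest.fixture()
    def immortal(self, params):
        flat_utilities(no_costs(zero_mortality(zero_cvd_risk(params))))
        params.settings.max_cycles = 10
        return params

    def test_undiscounted_full_health_gives_cycle_count(self, immortal):
        immortal.settings.discount_rate_costs = 0.0
        immortal.settings.discount_rate_qalys = 0.0
        res = run_arm(immortal, "comparator")
        assert res.discounted_qalys == pytest.approx(10.0, abs=1e-10)
        assert res.discounted_cost == 0.0
        assert res.life_years == pytest.approx(10.0)

    def test_constant_payoff_reproduces_annuity(self, immortal):
        """a per cycle for n cycles at rate r totals a * (1-(1+r)^-n)/r."""
        r = 0.035
        immortal.costs.annual_monitoring_cost = 75.0
        res = run_arm(immortal, "treated")
        annuity = (1 - 1.035**-10) / r
        assert res.discounted_qalys == pytest.approx(annuity, abs=1e-10)
        assert res.discounted_cost == pytest.approx(75.0 * annuity, abs=1e-8)

    def test_half_cycle_correction_on_immediate_death(self, params):
        flat_utilities(no_costs(zero_cvd_risk(params)))
        params.mortality.lifetable["all_cause_q"] = 1.0
        params.mortality.lifetable["noncirc_fraction"] = 1.0
        params.settings.discount_rate_qalys = 0.0
        res = run_arm(params, "comparator")
        assert res.discounted_qalys == pytest.approx(0.5, abs=1e-12)
        assert res.life_years == pytest.approx(0.5, abs=1e-12)

    def test_qalys_bounded_by_life_years(self, params):
        for arm in ("treated", "comparator"):
            res = run_arm(params, arm)
            assert 0 < res.discounted_qalys <= res.life_years


class TestLifetableValidation:
    def test_no_cvd_cohort_reproduces_lifetable_survival(self, params):
        """With CVD risks removed and all deaths non-circulatory, the
        comparator arm's survival curve equals the lifetable product."""
        zero_cvd_risk(params)
        params.mortality.lifetable["noncirc_fraction"] = 1.0
        trace = run_cohort(params, "comparator")
        ages = np.arange(60, 60 + trace.n_cycles)
        q, _ = params.mortality.arrays_for_ages(ages, "male")
        expected = np.concatenate([[1.0], np.cumprod(1 - q)])
        assert np.abs(trace.alive() - expected).max() <= 1e-12


class TestMonotonicity:
    def test_higher_state_cost_weakly_increases_arm_cost(self, params):
        base = run_arm(params, "comparator").discounted_cost
        params.costs.post_event_annual_cost["stroke"] *= 2
        assert run_arm(params, "comparator").discounted_cost > base

    def test_higher_risk_weakly_decreases_qalys(self):
        from hypercea import base_case_fixture

        for arm in ("treated", "comparator"):
            q10 = run_arm(base_case_fixture(r10=0.10), arm).discounted_qalys
            q20 = run_arm(base_case_fixture(r10=0.20), arm).discounted_qalys
            assert q20 < q10


def test_trace_csv_export_round_trips(params, tmp_path):
    import pandas as pd

    trace = run_cohort(params, "treated")
    trace.to_csv(tmp_path / "trace.csv")
    df = pd.read_csv(tmp_path / "trace.csv")
    assert list(df.columns) == ["cycle"] + list(STATES)
    assert np.allclose(df[list(STATES)].to_numpy(), trace.occupancy)
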