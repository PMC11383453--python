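"""Unit and property tests for the Markov cohort engine."""

import decimal

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from markovcea import (
    DEAD,
    HOSPITALIZED,
    REFERENCE_STATES,
    STABLE,
    CohortTrace,
    CyclePlan,
    StatePayoffs,
    StateSpace,
    TransitionMatrix,
    accumulate_payoffs,
    annual_prob_to_cycle_prob,
    build_transition_matrix,
    discount_factor,
    half_cycle_correct,
    run_cohort,
)

probs01 = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


def _high_precision_cycle_prob(p_annual: str, cycle_length_denominator: int) -> float:
    """Independent oracle: 1 - (1-p)^(1/d) at 50 decimal digits."""
    with decimal.localcontext() as ctx:
        ctx.prec = 50
        one = decimal.Decimal(1)
        base = one - decimal.Decimal(p_annual)
        result = one - (base.ln() / cycle_length_denominator).exp()
    return float(result)


class TestAnnualToCycleProb:
    @pytest.mark.parametrize(
        "p_annual, cycle_length, expected",
        [
            (0.0, 1 / 12, 0.0),
            (0.10, 1.0, 0.10),
            (1.0, 1.0, 1.0),
        ],
    )
    def test_identities(self, p_annual, cycle_length, expected):
        assert annual_prob_to_cycle_prob(p_annual, cycle_length) == pytest.approx(expected, abs=1e-15)

    def test_monthly_rescaling_matches_high_precision_oracle(self):
        got = annual_prob_to_cycle_prob(0.10, 1 / 12)
        assert got == pytest.approx(_high_precision_cycle_prob("0.10", 12), abs=1e-12)
        assert got == pytest.approx(0.008742, abs=5e-7)  # printed-precision check

    def test_result_bounded_by_annual_probability(self):
        for p in (0.01, 0.1, 0.5, 0.99):
            assert 0.0 <= annual_prob_to_cycle_prob(p, 1 / 12) <= p

    def test_certain_annual_event_rejected_for_short_cycles(self):
        with pytest.raises(ValueError, match="undefined"):
            annual_prob_to_cycle_prob(1.0, 1 / 12)

    @pytest.mark.parametrize("bad_p, bad_cl", [(-0.1, 1 / 12), (1.1, 1 / 12), (0.5, 0.0), (0.5, 2.0)])
    def test_domain_errors(self, bad_p, bad_cl):
        with pytest.raises(ValueError):
            annual_prob_to_cycle_prob(bad_p, bad_cl)


class TestBuildTransitionMatrix:
    def test_no_event_case_is_identity_on_living(self):
        m = build_transition_matrix(0, 0, 0, 0)
        assert np.array_equal(m.probs, np.eye(3))

    def test_certain_hospitalization(self):
        m = build_transition_matrix(1, 0, 0, 0)
        assert np.array_equal(m.probs[0], [0, 1, 0])

    def test_death_first_composition_matches_two_step_enumeration(self):
        """Brute-force enumeration of the death-then-move process per state."""
        psh, phs, pds, pdh = 0.3, 0.6, 0.008742, 0.008742
        m = build_transition_matrix(psh, phs, pds, pdh)
        # From Stable: die; or survive and (move | stay).
        expected_stable = {"die": pds, "move": (1 - pds) * psh, "stay": (1 - pds) * (1 - psh)}
        assert m.probs[0, 2] == pytest.approx(expected_stable["die"], abs=1e-15)
        assert m.probs[0, 1] == pytest.approx(expected_stable["move"], abs=1e-15)
        assert m.probs[0, 0] == pytest.approx(expected_stable["stay"], abs=1e-15)
        expected_hosp = {"die": pdh, "move": (1 - pdh) * phs, "stay": (1 - pdh) * (1 - phs)}
        assert m.probs[1, 2] == pytest.approx(expected_hosp["die"], abs=1e-15)
        assert m.probs[1, 0] == pytest.approx(expected_hosp["move"], abs=1e-15)
        assert m.probs[1, 1] == pytest.approx(expected_hosp["stay"], abs=1e-15)
        assert np.allclose(m.probs.sum(axis=1), 1.0, atol=1e-12)

    def test_negative_probability_names_offending_state(self):
        with pytest.raises(ValueError, match="Stable"):
            build_transition_matrix(-0.1, 0, 0, 0)
        with pytest.raises(ValueError, match="Hospitalized"):
            build_transition_matrix(0, 0, 0, 1.5)

    @settings(max_examples=200, derandomize=True)
    @given(psh=probs01, phs=probs01, pds=probs01, pdh=probs01)
    def test_row_stochastic_for_any_valid_inputs(self, psh, phs, pds, pdh):
        m = build_transition_matrix(psh, phs, pds, pdh)
        assert np.all(m.probs >= 0) and np.all(m.probs <= 1)
        assert np.allclose(m.probs.sum(axis=1), 1.0, atol=1e-12)
        assert np.array_equal(m.probs[2], [0, 0, 1])


class TestTransitionMatrixValidation:
    def test_rejects_non_stochastic_rows(self):
        bad = np.array([[0.5, 0.4, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        with pytest.raises(ValueError, match="sums to"):
            TransitionMatrix(REFERENCE_STATES, bad)

    def test_rejects_broken_absorbing_row(self):
        bad = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.1, 0.0, 0.9]])
        with pytest.raises(ValueError, match="absorbing"):
            TransitionMatrix(REFERENCE_STATES, bad)


class TestRunCohort:
    def test_identity_matrix_gives_constant_trace_and_no_inflow(self):
        m = build_transition_matrix(0, 0, 0, 0)
        plan = CyclePlan(n_cycles=12)
        trace = run_cohort(m, [0.9, 0.1, 0.0], plan)
        assert np.allclose(trace.occupancy, np.tile([0.9, 0.1, 0.0], (13, 1)))
        assert trace.episode_inflow[0] == 0.1  # starting episode
        assert np.all(trace.episode_inflow[1:] == 0.0)

    def test_matches_matrix_power_oracle_at_120_cycles(self):
        m = build_transition_matrix(0.0293, 0.7, 0.00874, 0.00874)
        init = np.array([1.0, 0.0, 0.0])
        trace = run_cohort(m, init, CyclePlan(n_cycles=120))
        expected = init @ np.linalg.matrix_power(m.probs, 120)
        assert np.allclose(trace.occupancy[120], expected, atol=1e-10)

    def test_dead_occupancy_strictly_increases_under_mortality(self):
        m = build_transition_matrix(0.1, 0.5, 0.02, 0.05)
        trace = run_cohort(m, [1.0, 0.0, 0.0], CyclePlan(n_cycles=60))
        dead = trace.occupancy[:, 2]
        assert np.all(np.diff(dead) > 0)

    def test_episode_inflow_counts_arrivals_from_other_states(self):
        m = build_transition_matrix(0.3, 0.6, 0.01, 0.02)
        trace = run_cohort(m, [1.0, 0.0, 0.0], CyclePlan(n_cycles=3))
        occ = trace.occupancy
        for t in range(1, 4):
            expected = occ[t - 1, 0] * m.probs[0, 1]  # only Stable feeds Hospitalized
            assert trace.episode_inflow[t] == pytest.approx(expected, abs=1e-14)

    def test_trace_export_layout(self, tmp_path):
        """CSV contract: cycle, time_years, one column per state, inflow."""
        import pandas as pd

        m = build_transition_matrix(0.1, 0.5, 0.01, 0.02)
        trace = run_cohort(m, [1.0, 0.0, 0.0], CyclePlan(n_cycles=4))
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["cycle", "time_years", "Stable", "Hospitalized",
                                    "Dead", "episode_inflow"]
        assert len(df) == 5
        assert df["time_years"].iloc[-1] == pytest.approx(4 / 12)

    def test_invalid_init_rejected(self):
        m = build_transition_matrix(0.1, 0.5, 0.01, 0.01)
        with pytest.raises(ValueError, match="distribution"):
            run_cohort(m, [0.5, 0.2, 0.0], CyclePlan(n_cycles=2))


class TestHalfCycleCorrection:
    def test_flat_trace_unchanged(self):
        occ = np.tile([0.6, 0.3, 0.1], (5, 1))
        trace = CohortTrace(REFERENCE_STATES, occ, np.zeros(5), 1 / 12)
        st_time = half_cycle_correct(trace)
        assert np.allclose(st_time, occ[1:] / 12)

    def test_linear_fall_gives_midpoint(self):
        occ = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        trace = CohortTrace(REFERENCE_STATES, occ, np.zeros(2), 1 / 12)
        st_time = half_cycle_correct(trace)
        assert st_time[0, 0] == pytest.approx(0.5 / 12)
        assert st_time[0, 2] == pytest.approx(0.5 / 12)

    def test_total_person_time_bounded_by_horizon(self):
        m = build_transition_matrix(0.2, 0.6, 0.05, 0.08)
        plan = CyclePlan(n_cycles=24)
        trace = run_cohort(m, [1.0, 0.0, 0.0], plan)
        assert half_cycle_correct(trace).sum() <= plan.horizon_years + 1e-12


class TestDiscounting:
    @pytest.mark.parametrize(
        "rate, time, expected",
        [(0.0, 7.3, 1.0), (0.03, 1.0, 1 / 1.03), (0.03, 0.0, 1.0)],
    )
    def test_examples(self, rate, time, expected):
        assert discount_factor(rate, time) == pytest.approx(expected, abs=1e-12)

    def test_strictly_decreasing_in_time(self):
        times = np.linspace(0, 10, 50)
        factors = discount_factor(0.05, times)
        assert np.all(np.diff(factors) < 0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(-0.01, 1.0)


class TestAccumulatePayoffs:
    def _payoffs(self, med=50.0, episode=5000.0, u_s=0.75, u_h=0.6):
        return StatePayoffs(
            REFERENCE_STATES,
            cost_per_cycle={STABLE: med, HOSPITALIZED: med, DEAD: 0.0},
            cost_per_episode=episode,
            utility={STABLE: u_s, HOSPITALIZED: u_h, DEAD: 0.0},
        )

    def test_zero_payoffs_give_zero_totals(self):
        m = build_transition_matrix(0.1, 0.5, 0.01, 0.02)
        plan = CyclePlan(n_cycles=12)
        trace = run_cohort(m, [1.0, 0.0, 0.0], plan)
        res = accumulate_payoffs(trace, self._payoffs(0.0, 0.0, 0.0, 0.0), plan)
        assert res.discounted_cost == 0.0
        assert res.discounted_qalys == 0.0

    def test_perfect_health_identity(self):
        """Utility 1, no death, no discounting, 10-year horizon -> 10 QALYs."""
        space = StateSpace(("Alive", "Gone"), frozenset({"Gone"}))
        m = TransitionMatrix(space, np.array([[1.0, 0.0], [0.0, 1.0]]))
        plan = CyclePlan(cycle_length=1 / 12, n_cycles=120,
                         annual_discount_rate_costs=0.0, annual_discount_rate_effects=0.0)
        trace = run_cohort(m, [1.0, 0.0], plan)
        payoffs = StatePayoffs(space, {"Alive": 0.0, "Gone": 0.0}, 0.0, {"Alive": 1.0, "Gone": 0.0})
        res = accumulate_payoffs(trace, payoffs, plan)
        assert res.discounted_qalys == pytest.approx(10.0, abs=1e-9)
        assert res.life_years == pytest.approx(10.0, abs=1e-9)

    def test_three_cycle_hand_computation(self):
        """Spreadsheet-style oracle over a hand-set 3-cycle trace."""
        occ = np.array(
            [[1.00, 0.00, 0.00],
             [0.80, 0.15, 0.05],
             [0.70, 0.18, 0.12],
             [0.65, 0.15, 0.20]]
        )
        inflow = np.array([0.0, 0.15, 0.10, 0.05])
        cl = 1 / 12
        plan = CyclePlan(cycle_length=cl, n_cycles=3)
        trace = CohortTrace(REFERENCE_STATES, occ, inflow, cl)
        res = accumulate_payoffs(trace, self._payoffs(), plan)

        # Independent recomputation with plain arithmetic.
        exp_cost, exp_qaly, exp_cost0, exp_qaly0 = 0.0, 0.0, 0.0, 0.0
        for t in (1, 2, 3):
            frac = (occ[t - 1] + occ[t]) / 2.0        # mean membership fraction
            cycle_cost = (frac[0] + frac[1]) * 50.0 + inflow[t] * 5000.0
            cycle_qaly = (frac[0] * 0.75 + frac[1] * 0.6) * cl
            dfc = 1.03 ** (-(t * cl))
            exp_cost += dfc * cycle_cost
            exp_qaly += dfc * cycle_qaly
            exp_cost0 += cycle_cost
            exp_qaly0 += cycle_qaly
        assert res.discounted_cost == pytest.approx(exp_cost, rel=1e-12)
        assert res.discounted_qalys == pytest.approx(exp_qaly, rel=1e-12)
        assert res.undiscounted_cost == pytest.approx(exp_cost0, rel=1e-12)
        assert res.undiscounted_qalys == pytest.approx(exp_qaly0, rel=1e-12)
        assert res.discounted_cost < res.undiscounted_cost

    def test_discounted_totals_non_increasing_in_rate(self):
        m = build_transition_matrix(0.1, 0.6, 0.02, 0.03)
        costs = []
        for rate in (0.0, 0.03, 0.05, 0.10):
            plan = CyclePlan(n_cycles=60, annual_discount_rate_costs=rate,
                             annual_discount_rate_effects=rate)
            trace = run_cohort(m, [1.0, 0.0, 0.0], plan)
            costs.append(accumulate_payoffs(trace, self._payoffs(), plan).discounted_cost)
        assert all(a >= b for a, b in zip(costs, costs[1:]))

    def test_mismatched_state_labels_rejected(self):
        m = build_transition_matrix(0.1, 0.5, 0.01, 0.02)
        plan = CyclePlan(n_cycles=2)
        trace = run_cohort(m, [1.0, 0.0, 0.0], plan)
        other = StateSpace(("Well", "Sick", "Gone"), frozenset({"Gone"}))
        payoffs = StatePayoffs(other, {"Well": 0, "Sick": 0, "Gone": 0}, 0.0,
                               {"Well": 0.5, "Sick": 0.3, "Gone": 0.0})
        with pytest.raises(ValueError, match="do not match"):
            accumulate_payoffs(trace, payoffs, plan)
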