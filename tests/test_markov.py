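"""Cohort engine: RR adjustment, mortality overlay, traces and payoffs."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hivcea import OutOfRangeError
from hivcea.exceptions import InfeasibleAdjustmentError
from hivcea.markov import (
    StrategySpec,
    accumulate_outcomes,
    apply_relative_risk,
    background_mortality_at,
    combine_background_mortality,
    daart_strategy,
    evaluate_strategy,
    run_cohort,
    saart_strategy,
)
from hivcea.parameters import (
    EconSettings,
    HealthState,
    ModelParameters,
    MortalityTable,
    StateValues,
    TransitionMatrix,
    TreatmentEffect,
)
from hivcea.synthetic import SyntheticSpec, generate

from _oracles import microsimulate

I, II, III, IV, D = range(5)


class TestApplyRelativeRisk:
    def test_state_one_row_all_worse(self, params):
        m = apply_relative_risk(params.saart_matrix, 1.29, adjust_death=True)
        row = m.probabilities[I]
        assert row[II] == pytest.approx(0.17597, abs=5e-6)
        assert row[III] == pytest.approx(0.06667, abs=5e-6)
        assert row[IV] == pytest.approx(0.04806, abs=5e-6)
        assert row[D] == pytest.approx(0.01705, abs=5e-6)
        assert row[I] == pytest.approx(0.69225, abs=5e-6)

    def test_state_three_row_mixed_directions(self, params):
        m = apply_relative_risk(params.saart_matrix, 1.29, adjust_death=True)
        row = m.probabilities[III]
        assert row[I] == pytest.approx(0.06837, abs=5e-6)
        assert row[II] == pytest.approx(0.22059, abs=5e-6)
        assert row[IV] == pytest.approx(0.18372, abs=5e-6)
        assert row[D] == pytest.approx(0.03333, abs=5e-6)
        assert row[III] == pytest.approx(0.49399, abs=5e-6)

    def test_rr_one_is_identity(self, params):
        for adjust_death in (True, False):
            m = apply_relative_risk(params.saart_matrix, 1.0, adjust_death)
            assert np.allclose(m.probabilities, params.saart_matrix.probabilities)

    def test_death_column_untouched_without_death_adjustment(self, params):
        m = apply_relative_risk(params.saart_matrix, 1.29, adjust_death=False)
        assert np.allclose(
            m.probabilities[:4, D], params.saart_matrix.probabilities[:4, D]
        )

    def test_infeasible_rr_raises(self, params):
        # enormous RR inflates improvement transitions beyond row capacity
        with pytest.raises(InfeasibleAdjustmentError):
            apply_relative_risk(params.saart_matrix, 60.0)

    def test_nonpositive_rr_rejected(self, params):
        with pytest.raises(OutOfRangeError):
            apply_relative_risk(params.saart_matrix, 0.0)


class TestBackgroundMortality:
    @pytest.mark.parametrize("age, expected", [(20, 0.0034), (23, 0.0034), (95, 0.1138)])
    def test_step_lookup(self, params, age, expected):
        assert background_mortality_at(params.mortality, age) == expected

    def test_below_table_start(self, params):
        with pytest.raises(OutOfRangeError):
            background_mortality_at(params.mortality, 5)

    def test_competing_risk_overlay(self, params):
        m = combine_background_mortality(params.saart_matrix, 0.0034)
        row = m.probabilities[I]
        assert row[D] == pytest.approx(0.025325, abs=5e-7)
        assert row[II] == pytest.approx(0.226228, abs=5e-7)

    def test_zero_background_is_identity(self, params):
        m = combine_background_mortality(params.saart_matrix, 0.0)
        assert np.allclose(m.probabilities, params.saart_matrix.probabilities)

    def test_certain_background_death(self, params):
        m = combine_background_mortality(params.saart_matrix, 1.0)
        assert np.allclose(m.probabilities[:4, D], 1.0)
        assert np.allclose(m.probabilities[:4, :4], 0.0)


@given(seed=st.integers(0, 10**6), rr=st.floats(0.7, 1.6), p_bg=st.floats(0, 1))
def test_row_stochasticity_preserved_by_transforms(seed, rr, p_bg):
    """RR adjustment composed with the mortality overlay keeps rows stochastic."""
    matrix = generate(SyntheticSpec(seed=seed)).saart_matrix
    for adjust_death in (True, False):
        try:
            m = apply_relative_risk(matrix, rr, adjust_death)
        except InfeasibleAdjustmentError:
            continue  # a declared-infeasible adjustment is a valid outcome
        m2 = combine_background_mortality(m, p_bg)
        assert np.allclose(m2.probabilities.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(m2.probabilities >= -1e-12)


class TestRunCohort:
    def test_single_cycle_occupancy(self, params):
        trace = run_cohort(params, saart_strategy())
        expected = (0.60095, 0.226228, 0.085708, 0.061789, 0.025325)
        assert trace.occupancy[1] == pytest.approx(expected, abs=5e-7)
        assert trace.occupancy[0] == pytest.approx((1, 0, 0, 0, 0))

    def test_rows_sum_to_one_and_death_monotone(self, params):
        for strategy in (saart_strategy(), daart_strategy(params)):
            trace = run_cohort(params, strategy)
            assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
            assert np.all(np.diff(trace.death_column) >= -1e-12)

    def test_identity_dynamics(self):
        from hivcea.synthetic import degenerate_cases

        case = degenerate_cases()["identity"]
        trace = run_cohort(case, saart_strategy())
        assert np.allclose(trace.occupancy[:, I], 1.0)


class TestAccumulateOutcomes:
    def _toy_params(self, p_die=0.5, utility=1.0, cost=0.0, discount=0.0):
        m = np.eye(5)
        m[I, I] = 1 - p_die
        m[I, D] = p_die
        utils = np.zeros(5)
        utils[I] = utility
        costs = np.zeros(5)
        costs[I] = cost
        return ModelParameters(
            saart_matrix=TransitionMatrix(m),
            state_values=StateValues(costs, utils),
            daart_annual_cost=0.0,
            treatment_effect=TreatmentEffect(1.0, 1.0, 1.0),
            mortality=MortalityTable([0.0], [0.0]),
            econ=EconSettings(
                discount_rate_costs=discount,
                discount_rate_qalys=discount,
                start_age=20,
                max_age=100,
            ),
        )

    def test_geometric_survival_qalys(self):
        """Trapezoid of 0.5^t survival sums to 1.5 QALYs undiscounted."""
        params = self._toy_params()
        res = evaluate_strategy(params, saart_strategy())
        assert res.discounted_qalys == pytest.approx(1.5, abs=1e-9)
        assert res.discounted_cost == 0.0

    def test_zero_utilities_zero_qalys(self):
        params = self._toy_params(utility=0.0)
        res = evaluate_strategy(params, saart_strategy())
        assert res.discounted_qalys == 0.0

    def test_discounting_strictly_shrinks_payoffs(self, params):
        import dataclasses

        res3 = evaluate_strategy(params, saart_strategy())
        p0 = dataclasses.replace(
            params,
            econ=dataclasses.replace(
                params.econ, discount_rate_costs=0.0, discount_rate_qalys=0.0
            ),
        )
        res0 = evaluate_strategy(p0, saart_strategy())
        assert res3.discounted_cost < res0.discounted_cost
        assert res3.discounted_qalys < res0.discounted_qalys

    def test_scale_equivariance_of_costs(self, params):
        import dataclasses

        k = 3.7
        scaled = dataclasses.replace(
            params,
            state_values=StateValues(
                params.state_values.annual_cost * k, params.state_values.utility
            ),
            daart_annual_cost=params.daart_annual_cost * k,
        )
        for build in (saart_strategy, daart_strategy):
            strat = build(params) if build is daart_strategy else build()
            strat_scaled = build(scaled) if build is daart_strategy else build()
            base = evaluate_strategy(params, strat)
            res = evaluate_strategy(scaled, strat_scaled)
            assert res.discounted_cost == pytest.approx(
                k * base.discounted_cost, rel=1e-12
            )
            assert res.discounted_qalys == pytest.approx(
                base.discounted_qalys, rel=1e-12
            )


class TestStrategyLevel:
    def test_base_case_magnitudes(self, fitted):
        """SAART and DAART land in the published ballpark (lifetime, 3%)."""
        assert 4000 < fitted.saart.discounted_cost < 8000
        assert 8 < fitted.saart.discounted_qalys < 11
        assert fitted.daart.discounted_cost > fitted.saart.discounted_cost
        assert fitted.daart.discounted_qalys > fitted.saart.discounted_qalys

    def test_daart_with_rr_one_and_no_price_equals_saart(self, params):
        neutral = StrategySpec("DAART", 0.0, 1.0)
        a = evaluate_strategy(params, saart_strategy())
        b = evaluate_strategy(params, neutral)
        assert a.discounted_cost == pytest.approx(b.discounted_cost)
        assert a.discounted_qalys == pytest.approx(b.discounted_qalys)

    def test_qalys_nondecreasing_in_rr(self, params):
        qalys = [
            evaluate_strategy(params, StrategySpec("DAART", 964.0, rr)).discounted_qalys
            for rr in np.linspace(1.0, 1.5, 6)
        ]
        assert np.all(np.diff(qalys) >= 0)


class TestMicrosimulationOracle:
    def test_cohort_matches_microsimulation_on_fixture(self, params):
        """Individual-level simulation reproduces cohort totals within 3 SE."""
        for strategy in (saart_strategy(), daart_strategy(params)):
            cohort = evaluate_strategy(params, strategy)
            sim = microsimulate(params, strategy, n_patients=120_000, seed=99)
            assert abs(cohort.discounted_cost - sim["cost"]) < 3 * sim["cost_se"]
            assert abs(cohort.discounted_qalys - sim["qalys"]) < 3 * sim["qalys_se"]

    @pytest.mark.parametrize("seed", [11, 29])
    def test_cohort_matches_microsimulation_on_synthetic(self, seed):
        params = generate(SyntheticSpec(seed=seed))
        strategy = daart_strategy(params)
        cohort = evaluate_strategy(params, strategy)
        sim = microsimulate(params, strategy, n_patients=40_000, seed=seed + 1)
        assert abs(cohort.discounted_cost - sim["cost"]) < 3 * sim["cost_se"]
        assert abs(cohort.discounted_qalys - sim["qalys"]) < 3 * sim["qalys_se"]
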