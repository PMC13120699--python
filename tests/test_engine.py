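"""Cohort engine: transition-matrix assembly (against a hand-assembled
toy), propagation (against an individual-level microsimulation), and the
accrual/discounting conventions."""

from __future__ import annotations

import numpy as np
import pytest

import trdcea as t
from trdcea.engine import ModelError

from conftest import make_toy_ps, microsimulate


class TestBuildTransitionMatrix:
    def test_rows_sum_to_one(self, base_ps, settings):
        for name in base_ps.strategy_names:
            P = t.build_transition_matrix(name, base_ps, settings)
            np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_death_row_is_identity(self, base_ps, settings):
        P = t.build_transition_matrix("AUG", base_ps, settings)
        expected = np.zeros(P.shape[0])
        expected[-1] = 1.0
        np.testing.assert_array_equal(P[-1], expected)

    def test_certain_mortality_absorbs_everything(self):
        ps = make_toy_ps(mortality_p=0.999999999)
        # mortality must stay < 1 by domain; use a value numerically at 1
        ps.mortality.value = 0.0
        ps.mortality = t.TransitionEstimate("probability", 0.99, 4.0)
        P = t.build_transition_matrix("S", ps, t.EconomicSettings())
        assert np.all(P[:-1, -1] >= 0.99)

    def test_zero_transitions_zero_mortality_parameterised_rows_identity(self):
        """With every parameterised transition zero and no mortality, the
        Treatment/Response/Remission rows are identity; only the
        structural line-failure routing (Nonresponse/Relapse starting the
        next line with certainty) remains off-diagonal."""
        ps = make_toy_ps(mortality_p=0.0, rr=(1.0, 1.0, 1.0))
        for line in ps.lines:
            for est in line.transitions.values():
                est.value = 0.0
        P = t.build_transition_matrix("S", ps, t.EconomicSettings())
        space = t.StateSpace(2)
        eye = np.eye(P.shape[0])
        for k in (1, 2):
            for state in ("treatment", "response", "remission"):
                i = space.index(k, state)
                np.testing.assert_allclose(P[i], eye[i], atol=1e-15)
        assert P[space.index(1, "nonresponse"), space.index(2, "treatment")] == 1.0
        assert P[space.index(1, "relapse"), space.index(2, "treatment")] == 1.0

    def test_matches_hand_assembled_toy(self, toy_ps):
        """11-state two-line toy enumerated by hand.

        Mortality 0.01 applies first; survivors split per the effective
        probabilities (baseline x RR, RRs inherited by line 2)."""
        P = t.build_transition_matrix("S", toy_ps, t.EconomicSettings())
        space = t.StateSpace(2)
        s = 0.99  # survivor fraction

        expected = np.zeros((11, 11))
        expected[10, 10] = 1.0
        # L1 treatment: ->resp 0.2*1.5=0.3, ->rem 0.1*1.2=0.12, ->nonresp 0.3
        i = space.index(1, "treatment")
        expected[i, space.index(1, "response")] = s * 0.30
        expected[i, space.index(1, "remission")] = s * 0.12
        expected[i, space.index(1, "nonresponse")] = s * 0.30
        expected[i, i] = s * (1 - 0.72)
        expected[i, 10] = 0.01
        # L1 response: ->rem 0.15, ->relapse 0.05
        i = space.index(1, "response")
        expected[i, space.index(1, "remission")] = s * 0.15
        expected[i, space.index(1, "relapse")] = s * 0.05
        expected[i, i] = s * 0.80
        expected[i, 10] = 0.01
        # L1 remission: ->relapse 0.08*0.5=0.04
        i = space.index(1, "remission")
        expected[i, space.index(1, "relapse")] = s * 0.04
        expected[i, i] = s * 0.96
        expected[i, 10] = 0.01
        # L1 nonresponse/relapse -> L2 treatment
        for st_name in ("nonresponse", "relapse"):
            i = space.index(1, st_name)
            expected[i, space.index(2, "treatment")] = s
            expected[i, 10] = 0.01
        # L2 treatment (RRs inherited): ->resp 0.1*1.5, ->rem 0.05*1.2, ->nonresp 0.4
        i = space.index(2, "treatment")
        expected[i, space.index(2, "response")] = s * 0.15
        expected[i, space.index(2, "remission")] = s * 0.06
        expected[i, space.index(2, "nonresponse")] = s * 0.40
        expected[i, i] = s * (1 - 0.61)
        expected[i, 10] = 0.01
        # L2 response: ->rem 0.1, ->relapse 0.1
        i = space.index(2, "response")
        expected[i, space.index(2, "remission")] = s * 0.10
        expected[i, space.index(2, "relapse")] = s * 0.10
        expected[i, i] = s * 0.80
        expected[i, 10] = 0.01
        # L2 remission: ->relapse 0.12*0.5=0.06
        i = space.index(2, "remission")
        expected[i, space.index(2, "relapse")] = s * 0.06
        expected[i, i] = s * 0.94
        expected[i, 10] = 0.01
        # last line failure states collect in L2 nonresponse
        i = space.index(2, "nonresponse")
        expected[i, i] = s
        expected[i, 10] = 0.01
        i = space.index(2, "relapse")
        expected[i, space.index(2, "nonresponse")] = s
        expected[i, 10] = 0.01

        np.testing.assert_allclose(P, expected, atol=1e-14)

    def test_infeasible_outgoing_raises_or_rescales(self, toy_ps):
        bad = toy_ps.copy()
        bad.strategies["S"].effects["treatment_to_response"].rr = 5.0
        with pytest.raises(ModelError, match="sum"):
            t.build_transition_matrix("S", bad, t.EconomicSettings())
        P = t.build_transition_matrix("S", bad, t.EconomicSettings(),
                                      infeasible="rescale")
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)


class TestRunCohort:
    def test_zero_cycle_horizon_returns_initial_vector(self, toy_ps):
        s = t.EconomicSettings(horizon_years=1 / 52)  # under one cycle
        trace = t.run_cohort("S", toy_ps, s)
        assert trace.n_cycles == 0
        assert trace.occupancy[0, trace.space.index(1, "treatment")] == 1.0

    def test_inert_model_stays_in_initial_state(self):
        ps = make_toy_ps(mortality_p=0.0, rr=(1.0, 1.0, 1.0))
        for line in ps.lines:
            for est in line.transitions.values():
                est.value = 0.0
        trace = t.run_cohort("S", ps, t.EconomicSettings())
        i = trace.space.index(1, "treatment")
        assert np.all(trace.occupancy[:, i] == 1.0)

    def test_cycle_count(self, base_ps, settings):
        trace = t.run_cohort("AUG", base_ps, settings)
        assert trace.n_cycles == 65  # floor(5 * 52 / 4)

    @pytest.mark.parametrize("seed", range(100))
    def test_conservation_and_death_monotonicity_random_fixtures(self, seed):
        """Occupancy rows sum to 1 and the Death column never decreases,
        on 100 seeded random input sets."""
        ps = t.generate_parameter_set(t.FixtureConfig(seed=seed))
        name = ps.strategy_names[seed % len(ps.strategy_names)]
        trace = t.run_cohort(name, ps, t.EconomicSettings())
        np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-10)
        death = trace.occupancy[:, -1]
        assert np.all(np.diff(death) >= -1e-15)
        assert np.all(trace.occupancy >= -1e-15)
        assert np.all(trace.occupancy <= 1 + 1e-12)

    def test_agrees_with_microsimulation(self, base_ps, settings):
        """Cohort propagation vs a 1e5-agent individual-level simulation:
        per-state occupancy within 3 Monte-Carlo standard errors at
        early, middle and final cycles."""
        n_agents = 100_000
        P = t.build_transition_matrix("ESK+AD", base_ps, settings)
        trace = t.run_cohort("ESK+AD", base_ps, settings)
        start = trace.space.index(1, "treatment")
        occ_sim = microsimulate(P, start, n_agents, settings.n_cycles, seed=20240901)
        for cycle in (1, 5, 20, 65):
            p = trace.occupancy[cycle]
            se = np.sqrt(p * (1 - p) / n_agents)
            assert np.all(np.abs(occ_sim[cycle] - p) <= 3 * se + 1e-9), (
                f"cycle {cycle}: max dev "
                f"{np.max(np.abs(occ_sim[cycle] - p) - 3 * se)}"
            )


class TestDiscountFactor:
    @pytest.mark.parametrize(
        "cycle,rate,cw,expected",
        [
            (0, 0.03, 4, 1.0),
            (7, 0.0, 4, 1.0),
            (13, 0.03, 4, 1 / 1.03),  # 13 cycles = 52 weeks = 1 year
        ],
    )
    def test_known_values(self, cycle, rate, cw, expected):
        assert t.discount_factor(cycle, rate, cw) == pytest.approx(expected, abs=1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(t.ValidationError):
            t.discount_factor(1, -0.01, 4)


class TestAccrueOutcomes:
    def test_person_time_conservation(self):
        """All utilities 1, no mortality, no discounting: QALYs equal the
        horizon exactly (65 cycles x 4/52 years = 5.0)."""
        ps = make_toy_ps(mortality_p=0.0)
        ps.utilities = t.UtilitySet({s: 1.0 for s in t.HEALTH_STATES})
        s = t.EconomicSettings(annual_discount_rate=0.0)
        out = t.run_strategy("S", ps, s)
        assert out.qaly == pytest.approx(5.0, abs=1e-10)

    def test_zero_utilities_zero_qalys(self, toy_ps):
        ps = toy_ps.copy()
        ps.utilities = t.UtilitySet({s: 0.0 for s in t.HEALTH_STATES})
        out = t.run_strategy("S", ps, t.EconomicSettings())
        assert out.qaly == 0.0
        assert out.cost > 0

    def test_discounted_below_undiscounted(self, base_outcomes):
        for o in base_outcomes.values():
            assert o.cost < o.cost_undiscounted
            assert o.qaly < o.qaly_undiscounted

    def test_discount_monotonicity(self, base_ps):
        """Totals are nonincreasing in the annual discount rate."""
        rates = [0.0, 0.015, 0.03, 0.05]
        outs = [
            t.run_strategy("ESK+AD", base_ps, t.EconomicSettings(annual_discount_rate=r))
            for r in rates
        ]
        costs = [o.cost for o in outs]
        qalys = [o.qaly for o in outs]
        assert costs == sorted(costs, reverse=True)
        assert qalys == sorted(qalys, reverse=True)

    def test_qalys_bounded_by_horizon(self, base_outcomes, settings):
        for o in base_outcomes.values():
            assert o.qaly <= settings.horizon_years

    def test_cost_components_sum_to_total(self, base_outcomes):
        for o in base_outcomes.values():
            assert sum(o.cost_components.values()) == pytest.approx(o.cost, rel=1e-12)

    def test_zero_mortality_living_time_equals_horizon(self):
        ps = make_toy_ps(mortality_p=0.0)
        out = t.run_strategy("S", ps, t.EconomicSettings(annual_discount_rate=0.0))
        assert sum(out.time_in_state_years.values()) == pytest.approx(5.0, abs=1e-10)

    def test_maintenance_flag_controls_response_remission_drug_cost(self, toy_ps):
        s = t.EconomicSettings(annual_discount_rate=0.0)
        with_m = t.run_strategy("S", toy_ps, s)
        ps2 = toy_ps.copy()
        ps2.strategies["S"].maintenance_in_response_remission = False
        without_m = t.run_strategy("S", ps2, s)
        assert without_m.cost < with_m.cost
        assert without_m.qaly == pytest.approx(with_m.qaly)

    def test_half_cycle_correction_averages_occupancy(self, toy_ps):
        plain = t.run_strategy("S", toy_ps, t.EconomicSettings())
        hcc = t.run_strategy(
            "S", toy_ps, t.EconomicSettings(half_cycle_correction=True)
        )
        assert hcc.qaly != plain.qaly  # convention changes accrual
        assert abs(hcc.qaly - plain.qaly) < 0.1  # but only at cycle granularity
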