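"""Costing rules, discounting, accrual and incremental summaries."""

import numpy as np
import pytest

from gvhdcea import (
    ArmOutcome,
    ArmParameters,
    CostInputs,
    HealthState,
    RunSettings,
    SocComponent,
    UtilityInputs,
    accrue,
    compare,
    discount_factor,
    event_costs,
    run_cohort,
    state_cost_per_cycle,
    weighted_soc_cost,
)

ON = HealthState.RESPONSE_ON_TREATMENT
OFF = HealthState.RESPONSE_OFF_TREATMENT
PROG = HealthState.PROGRESSED
DEAD = HealthState.DEAD


class TestDiscounting:
    def test_first_cycle_undiscounted(self, default_settings):
        assert discount_factor(0, default_settings) == 1.0

    def test_three_years_elapsed(self, default_settings):
        # 13 cycles * 12 weeks = 3 years at 5% per annum
        assert discount_factor(13, default_settings) == pytest.approx(1.05 ** -3)

    def test_zero_rate_is_identity(self):
        settings = RunSettings(annual_discount_rate=0.0)
        assert all(discount_factor(c, settings) == 1.0 for c in range(0, 45))


class TestWeightedSocCost:
    def test_survey_weighted_blend(self):
        blend = weighted_soc_cost(CostInputs().soc_components)
        assert blend == pytest.approx(0.44 * 349 + 0.23 * 5258 + 0.33 * 1987)
        assert blend == pytest.approx(2018.61)

    def test_single_component(self):
        assert weighted_soc_cost([SocComponent("only", 1234.0, 1.0)]) == 1234.0

    def test_equal_costs_independent_of_weights(self):
        comps = [SocComponent("a", 500.0, 0.2), SocComponent("b", 500.0, 0.8)]
        assert weighted_soc_cost(comps) == pytest.approx(500.0)

    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            weighted_soc_cost([SocComponent("a", 100.0, 0.5), SocComponent("b", 100.0, 0.4)])


class TestStateCosts:
    def test_ecp_induction_cycle(self):
        costs = CostInputs()
        assert state_cost_per_cycle(ON, "ECP", 1, costs) == pytest.approx(
            52_932 + 92 + 309
        )

    def test_ecp_maintenance_cycle(self):
        costs = CostInputs()
        assert state_cost_per_cycle(ON, "ECP", 5, costs) == pytest.approx(
            12_704 + 42 + 309
        )

    def test_progressed_state(self):
        costs = CostInputs()
        assert state_cost_per_cycle(PROG, "SoC", 7, costs) == pytest.approx(
            5_793 + 7_147 + 92
        )

    def test_off_treatment_drops_treatment_cost(self):
        costs = CostInputs()
        assert state_cost_per_cycle(OFF, "ECP", 5, costs) == pytest.approx(309 + 42)

    def test_dead_costs_nothing(self):
        assert state_cost_per_cycle(DEAD, "ECP", 3, CostInputs()) == 0.0


class TestEventCosts:
    def test_no_flows_no_cost(self, table_params):
        ecp, _ = table_params
        assert event_costs(np.zeros((4, 4)), ecp, CostInputs()) == 0.0

    def test_progression_entries(self, table_params):
        ecp, _ = table_params
        flows = np.zeros((4, 4))
        flows[ON, PROG] = 0.198
        assert event_costs(flows, ecp, CostInputs()) == pytest.approx(
            0.198 * (4_324 + 562)
        )

    def test_remaining_in_progression_costs_nothing(self, table_params):
        ecp, _ = table_params
        flows = np.zeros((4, 4))
        flows[PROG, PROG] = 0.5  # staying progressed is not a new entry
        assert event_costs(flows, ecp, CostInputs()) == 0.0

    def test_respiratory_death_fraction(self, table_params):
        ecp, _ = table_params
        flows = np.zeros((4, 4))
        flows[PROG, DEAD] = 0.10
        assert event_costs(flows, ecp, CostInputs()) == pytest.approx(
            0.10 * 0.55 * 21_061
        )


class TestAccrue:
    def test_single_cycle_response_qaly(self, frozen_params):
        settings = RunSettings(horizon_cycles=1)
        params = ArmParameters(
            arm_name="ECP",
            p_response_week12=1.0,
            p_progression_week12=0.0,
            p_progress_per_cycle=0.0,
            p_death_responder_per_cycle=0.0,
            p_death_progressed_per_cycle=0.0,
            p_discontinue_per_cycle=0.0,
        )
        trace = run_cohort(params, settings)
        outcome = accrue(trace, CostInputs(), UtilityInputs(), settings, "ECP", params)
        assert outcome.qaly == pytest.approx(0.786 * 12 / 52)
        assert outcome.cost == pytest.approx(52_932 + 92 + 309)

    def test_zero_costs_and_utilities(self, table_params, default_settings):
        ecp, _ = table_params
        trace = run_cohort(ecp, default_settings)
        zero_costs = CostInputs(
            ecp_cycle1=0.0,
            ecp_maintenance=0.0,
            soc_components=[SocComponent("a", 0.0, 1.0)],
            prednisone_start=0.0,
            prednisone_down=0.0,
            subsequent_therapy=0.0,
            progression_event=0.0,
            infection_hospitalization=0.0,
            death_respiratory_event=0.0,
            management_response=0.0,
            management_progressed=0.0,
        )
        zero_utils = UtilityInputs(u_response=0.0, u_progressed=0.0, u_dead=0.0)
        outcome = accrue(trace, zero_costs, zero_utils, default_settings, "ECP", ecp)
        assert outcome.cost == 0.0 and outcome.qaly == 0.0

    def test_zero_rate_matches_manual_sum(self, table_params):
        """With no discounting the QALY total equals the plain occupancy sum."""
        ecp, _ = table_params
        settings = RunSettings(annual_discount_rate=0.0, half_cycle_correction=False)
        trace = run_cohort(ecp, settings)
        outcome = accrue(trace, CostInputs(), UtilityInputs(), settings, "ECP", ecp)
        u = UtilityInputs().as_vector()
        expected = sum(
            float(trace.occupancy[c - 1] @ u) * settings.cycle_years
            for c in range(1, settings.horizon_cycles + 1)
        )
        assert outcome.qaly == pytest.approx(expected)

    def test_qaly_bounded_by_horizon_years(self, table_params, default_settings):
        ecp, _ = table_params
        trace = run_cohort(ecp, default_settings)
        outcome = accrue(trace, CostInputs(), UtilityInputs(), default_settings, "ECP", ecp)
        horizon_years = default_settings.horizon_cycles * default_settings.cycle_years
        assert 0 < outcome.qaly <= horizon_years

    def test_lower_utility_lowers_qaly(self, table_params, default_settings):
        ecp, _ = table_params
        trace = run_cohort(ecp, default_settings)
        hi = accrue(trace, CostInputs(), UtilityInputs(), default_settings, "ECP", ecp)
        lo = accrue(
            trace,
            CostInputs(),
            UtilityInputs(u_progressed=0.5),
            default_settings,
            "ECP",
            ecp,
        )
        assert lo.qaly < hi.qaly

    def test_cost_linear_in_unit_cost(self, table_params, default_settings):
        """Doubling one unit cost shifts the total by exactly its accrued exposure."""
        ecp, _ = table_params
        trace = run_cohort(ecp, default_settings)
        base_costs = CostInputs()
        doubled = CostInputs(management_progressed=2 * base_costs.management_progressed)
        a = accrue(trace, base_costs, UtilityInputs(), default_settings, "ECP", ecp)
        b = accrue(trace, doubled, UtilityInputs(), default_settings, "ECP", ecp)
        exposure = sum(
            discount * occ
            for discount, occ in zip(
                (
                    (1 + default_settings.annual_discount_rate)
                    ** (-(c - 1) * default_settings.cycle_years)
                    for c in range(1, default_settings.horizon_cycles + 1)
                ),
                0.5 * (trace.occupancy[:-1, PROG] + trace.occupancy[1:, PROG]),
            )
        )
        assert b.cost - a.cost == pytest.approx(
            base_costs.management_progressed * exposure
        )

    def test_horizon_mismatch_rejected(self, table_params, default_settings):
        ecp, _ = table_params
        trace = run_cohort(ecp, RunSettings(horizon_cycles=10))
        with pytest.raises(ValueError, match="horizon"):
            accrue(trace, CostInputs(), UtilityInputs(), default_settings, "ECP", ecp)


class TestCompare:
    def test_dominant_with_published_deltas(self, default_settings):
        res = compare(
            ArmOutcome("ECP", 180_020.0, 4.31),
            ArmOutcome("SoC", 204_019.0, 3.21),
            default_settings,
        )
        assert res.classification == "dominant"
        assert res.icer is None
        assert res.delta_cost == pytest.approx(-23_999.0)
        assert res.nmb_at_wtp == pytest.approx(50_000 * 1.10 + 23_999.0)

    def test_tradeoff_quadrant_reports_icer(self, default_settings):
        res = compare(
            ArmOutcome("A", 110_000.0, 2.5), ArmOutcome("B", 100_000.0, 2.0), default_settings
        )
        assert res.classification == "icer"
        assert res.icer == pytest.approx(20_000.0)

    def test_dominated(self, default_settings):
        res = compare(
            ArmOutcome("A", 110_000.0, 1.5), ArmOutcome("B", 100_000.0, 2.0), default_settings
        )
        assert res.classification == "dominated"
        assert res.icer is None

    def test_identical_arms(self, default_settings):
        res = compare(
            ArmOutcome("A", 100_000.0, 2.0), ArmOutcome("B", 100_000.0, 2.0), default_settings
        )
        assert res.classification == "equal_effects"
        assert res.icer is None
        assert res.delta_cost == 0.0 and res.delta_qaly == 0.0
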