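import numpy as np
import pytest

from ra_cea import run_cohort_trace, run_strategy
from ra_cea.markov_engine import resolve_dynamics
from ra_cea.outcomes import (
    HEALTHCARE_SYSTEM,
    accumulate_discounted,
    apply_haq_floor,
    cycle_cost,
    discount_weights,
    floored_utility_and_haq,
    haq_to_utility,
    load_perspectives,
    perspectives_from,
    utility_to_haq,
)
from ra_cea.defaults import data_path


class TestHaqUtilityMapping:
    def test_intercept_at_zero_haq(self):
        assert haq_to_utility(0.0, 0.9, -0.25) == pytest.approx(0.9)

    def test_mapping_round_trip_is_identity(self):
        haq = np.linspace(0.0, 3.0, 13)
        u = 0.95 + (-0.25) * haq  # stay inside the clamp
        back = utility_to_haq(haq_to_utility(haq, 0.95, -0.25), 0.95, -0.25)
        np.testing.assert_allclose(back, haq, rtol=0, atol=1e-12)
        np.testing.assert_allclose(haq_to_utility(haq, 0.95, -0.25), u, atol=1e-12)

    def test_fixture_mapping_recovers_baseline_utility(self, params):
        """The shipped coefficients are back-solved so the worst observed
        disability maps to the baseline utility."""
        s = params.settings
        haq_base = utility_to_haq(0.193193, s.haq_map_intercept, s.haq_map_slope)
        assert haq_base == pytest.approx(s.haq_max, abs=1e-4)
        assert haq_to_utility(haq_base, s.haq_map_intercept, s.haq_map_slope) == pytest.approx(
            0.193193, abs=1e-9)

    def test_clamped_to_unit_interval(self):
        assert haq_to_utility(0.0, 1.2, -0.3) == 1.0
        assert haq_to_utility(3.0, 0.3, -0.2) == 0.0

    def test_positive_slope_rejected(self):
        with pytest.raises(ValueError):
            haq_to_utility(1.0, 0.9, 0.1)


class TestHaqFloor:
    @pytest.mark.parametrize("haq, floor, expected", [
        (2.0, 1.5, 2.0),
        (0.8, 1.5, 1.5),
        (1.5, 1.5, 1.5),
    ])
    def test_floor_rule(self, haq, floor, expected):
        assert apply_haq_floor(haq, floor) == expected

    def test_floor_caps_state_utility_from_above_only(self, params):
        s = params.settings
        cap = float(haq_to_utility(s.haq_floor, s.haq_map_intercept, s.haq_map_slope))
        high, haq_high = floored_utility_and_haq(0.737562, s)
        low, haq_low = floored_utility_and_haq(0.37967, s)
        assert float(high) == pytest.approx(cap)  # above the cap: floored
        assert float(low) == pytest.approx(0.37967)  # below the cap: as printed
        assert float(haq_high) == s.haq_floor
        assert float(haq_low) > s.haq_floor


class TestCycleCost:
    def test_dead_state_accrues_nothing(self, params):
        assert cycle_cost("dead", None, params, HEALTHCARE_SYSTEM) == 0.0

    def test_palliative_half_year_share_of_annual_cost(self, params, strategies):
        pall = strategies[0].palliative
        assert cycle_cost("palliative", pall, params, HEALTHCARE_SYSTEM) == pytest.approx(
            20985.50)

    def test_perspective_fractions_split_every_state_cost(self, params, strategies):
        persp = load_perspectives(data_path("perspectives.yaml"))
        strategy = strategies[0]
        for line in [*strategy.lines, strategy.palliative]:
            full = cycle_cost("on_line_responder", line, params, persp["healthcare_system"])
            patient = cycle_cost("on_line_responder", line, params, persp["patient_oop"])
            insurer = cycle_cost("on_line_responder", line, params, persp["insurance"])
            assert patient + insurer == pytest.approx(full, abs=1e-9)

    def test_perspective_file_matches_reimbursement_map(self, params):
        from_file = load_perspectives(data_path("perspectives.yaml"))
        derived = perspectives_from(params)
        for name in ("patient_oop", "insurance"):
            for cat in params.reimbursement["patient_oop"]:
                assert from_file[name].fraction(cat) == pytest.approx(
                    derived[name].fraction(cat))


class TestDiscounting:
    def test_weight_at_cycle_two_with_half_year_cycles(self):
        w = discount_weights(3, 0.05, 0.5)
        assert w[2] == pytest.approx(1.0 / 1.05, rel=1e-12)
        assert w[0] == 1.0

    def test_zero_rate_equals_undiscounted_sums(self, params, strategies, life_table):
        trace = run_cohort_trace(strategies[0], params, life_table)
        res0 = accumulate_discounted(trace, annual_rate=0.0)
        assert res0.total_cost_discounted == pytest.approx(float(trace.cycle_cost.sum()))
        assert res0.total_qaly_discounted == pytest.approx(float(trace.cycle_qaly.sum()))

    def test_discounting_shrinks_totals(self, params, strategies, life_table):
        trace = run_cohort_trace(strategies[0], params, life_table)
        res = accumulate_discounted(trace)
        assert res.total_cost_discounted < float(trace.cycle_cost.sum())
        assert res.total_qaly_discounted < float(trace.cycle_qaly.sum())

    def test_negative_rate_is_fatal(self, params, strategies, life_table):
        trace = run_cohort_trace(strategies[0], params, life_table)
        with pytest.raises(ValueError):
            accumulate_discounted(trace, annual_rate=-0.01)

    def test_cost_totals_are_linear_in_unit_prices(self, params, strategies, life_table):
        doubled = params.model_copy(deep=True)
        for row in doubled.costs:
            row.unit_price *= 2
            row.lower *= 2
            row.upper *= 2
        base = run_strategy(strategies[0], params, life_table)
        twice = run_strategy(strategies[0], doubled, life_table)
        assert twice.total_cost_discounted == pytest.approx(
            2.0 * base.total_cost_discounted, rel=1e-12)
        assert twice.total_qaly_discounted == pytest.approx(
            base.total_qaly_discounted, rel=1e-12)

    def test_lifetime_qalys_bounded_by_horizon(self, params, strategies, life_table):
        for strategy in strategies:
            res = run_strategy(strategy, params, life_table)
            horizon_years = params.settings.max_age - params.settings.start_age
            assert 0.0 < res.total_qaly_discounted <= horizon_years


class TestPerspectiveAdditivity:
    def test_patient_plus_insurance_equals_system_totals(self, params, strategies,
                                                         life_table):
        persp = load_perspectives(data_path("perspectives.yaml"))
        for strategy in strategies:
            full = run_strategy(strategy, params, life_table, persp["healthcare_system"])
            patient = run_strategy(strategy, params, life_table, persp["patient_oop"])
            insurer = run_strategy(strategy, params, life_table, persp["insurance"])
            assert patient.total_cost_discounted + insurer.total_cost_discounted == (
                pytest.approx(full.total_cost_discounted, abs=1e-6))
            # QALYs are perspective-independent
            assert patient.total_qaly_discounted == pytest.approx(
                full.total_qaly_discounted, rel=1e-12)
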