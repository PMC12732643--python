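import numpy as np
import pytest

from ra_cea import run_cohort_trace, run_strategy, run_totals
from ra_cea.markov_engine import (
    background_mortality_prob,
    build_cycle_update,
    resolve_dynamics,
    state_space,
)
from ra_cea.parameters import LifeTable


def _zero_response_overrides(params):
    return {row.name: 0.0 for row in params.probabilities if "response" in row.name}


class TestBackgroundMortality:
    def test_no_adjustment_at_zero_haq(self, life_table):
        d = background_mortality_prob(60, 0.0, life_table, hr_per_haq=1.33,
                                      cycle_length_years=1.0)
        assert d == pytest.approx(life_table.annual_qx(60), rel=1e-12)

    def test_unit_hazard_ratio_is_identity(self, life_table):
        d = background_mortality_prob(60, 2.5, life_table, hr_per_haq=1.0,
                                      cycle_length_years=1.0)
        assert d == pytest.approx(life_table.annual_qx(60), rel=1e-12)

    def test_closed_form_adjustment(self):
        # qx = 0.01, haq = 1.5, hr = 1.33: annual q_adj = 1 - 0.99**(1.33**1.5)
        table = LifeTable(ages=np.arange(0, 111), qx=np.full(111, 0.01))
        annual = background_mortality_prob(50, 1.5, table, 1.33, cycle_length_years=1.0)
        expected_annual = 1.0 - 0.99 ** (1.33**1.5)
        assert annual == pytest.approx(expected_annual, rel=1e-12)
        assert expected_annual == pytest.approx(0.0153, abs=5e-4)
        half = background_mortality_prob(50, 1.5, table, 1.33, cycle_length_years=0.5)
        assert half == pytest.approx(1.0 - (1.0 - expected_annual) ** 0.5, rel=1e-12)


class TestCycleUpdate:
    @pytest.mark.parametrize("cycle", [0, 1, 17, 101])
    def test_rows_are_stochastic_on_the_fixture(self, params, strategies, life_table, cycle):
        for strategy in strategies:
            M = build_cycle_update(strategy, cycle, params, life_table)
            np.testing.assert_allclose(M.sum(axis=1), 1.0, rtol=0, atol=1e-12)
            assert np.all(M >= 0)

    def test_matrix_iteration_matches_cohort_kernel(self, params, strategies, life_table):
        """The dense transition operator and the vectorized kernel are
        independent constructions of the same chain."""
        strategy = strategies[0]
        trace = run_cohort_trace(strategy, params, life_table)
        occ = trace.occupancy[0]
        for k in range(trace.n_cycles):
            occ = occ @ build_cycle_update(strategy, k, params, life_table)
            np.testing.assert_allclose(occ, trace.occupancy[k + 1], rtol=0, atol=1e-12)

    def test_absorbing_responder_with_no_exits(self, params, strategies, life_table,
                                               zero_mortality_table):
        overrides = {row.name: (1.0 if "response" in row.name else 0.0)
                     for row in params.probabilities}
        trace = run_cohort_trace(strategies[0], params, zero_mortality_table,
                                 overrides=overrides)
        assert np.all(trace.occupancy[:, 0] == 1.0)

    def test_universal_nonresponse_reaches_palliative_after_line_count_cycles(
            self, params, strategies, life_table, zero_mortality_table):
        strategy = strategies[0]
        L = strategy.n_lines
        trace = run_cohort_trace(strategy, params, zero_mortality_table,
                                 overrides=_zero_response_overrides(params))
        # one on-drug trial cycle per line, then palliative absorbs everyone
        pall = trace.occupancy[:, -2]
        assert pall[L - 1] == pytest.approx(0.0, abs=1e-12)
        assert pall[L] == pytest.approx(1.0, abs=1e-12)


class TestCohortTrace:
    def test_occupancy_conserved_and_death_monotone(self, params, strategies, life_table):
        for strategy in strategies:
            trace = run_cohort_trace(strategy, params, life_table)
            assert trace.occupancy.shape == (103, 2 * strategy.n_lines + 2)
            np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, rtol=0, atol=1e-10)
            assert np.all(trace.occupancy >= 0)
            assert np.all(np.diff(trace.dead_fraction) >= -1e-15)

    def test_flat_hazard_lifetime_matches_geometric_closed_form(
            self, params, strategies, flat_qx_table):
        settings = params.settings.model_copy(update={"mortality_haq_hr": 1.0})
        p = params.model_copy(update={"settings": settings})
        trace = run_cohort_trace(strategies[0], p, flat_qx_table)
        d = 1.0 - 0.95**0.5  # per-cycle death probability
        K = trace.n_cycles
        alive = 1.0 - trace.occupancy[:K, -1]
        lifetime = 0.5 * float(alive.sum())
        expected = 0.5 * (1.0 - (1.0 - d) ** K) / d
        assert lifetime == pytest.approx(expected, abs=1e-6)

    def test_higher_response_never_reduces_lifetime_qalys(self, params, strategies,
                                                          life_table):
        """Response utilities exceed the non-response utility throughout the
        fixture, so better response can only help."""
        strategy = strategies[0]
        _, q0 = run_totals(strategy, params, life_table)
        for row in params.probabilities:
            if "response" not in row.name:
                continue
            bumped = min(row.base + 0.05, 1.0)
            _, q1 = run_totals(strategy, params, life_table, overrides={row.name: bumped})
            assert q1 >= q0 - 1e-9, row.name

    def test_batched_kernel_agrees_with_scalar_runs(self, params, strategies, life_table):
        rng = np.random.default_rng(5)
        name = "u Adalimumab (MTX group)"
        draws = rng.uniform(0.5, 0.8, size=4)
        c_b, q_b = run_totals(strategies[1], params, life_table, overrides={name: draws})
        for i, v in enumerate(draws):
            c_s, q_s = run_totals(strategies[1], params, life_table, overrides={name: v})
            assert c_b[i] == pytest.approx(float(c_s), rel=1e-14)
            assert q_b[i] == pytest.approx(float(q_s), rel=1e-14)

    def test_totals_equal_trace_increment_sums(self, params, strategies, life_table):
        res = run_strategy(strategies[0], params, life_table)
        trace = res.trace
        assert res.total_cost_discounted == pytest.approx(
            float(np.sum(trace.cycle_cost_discounted)), rel=1e-15)
        assert res.total_qaly_discounted == pytest.approx(
            float(np.sum(trace.cycle_qaly_discounted)), rel=1e-15)


class TestStateSpace:
    def test_state_order_and_labels(self, strategies):
        states = state_space(strategies[0])
        assert states[0].label() == "line0_responder"
        assert states[1].label() == "line0_nonresponder"
        assert states[-2].kind == "palliative"
        assert states[-1].kind == "dead"

    def test_dangling_cost_reference_is_fatal(self, params, strategies, life_table):
        bad = strategies[0].model_copy(deep=True)
        bad.lines[0].costs[0].item = "c Nonexistent"
        with pytest.raises(KeyError, match="c Nonexistent"):
            resolve_dynamics(bad, params)
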