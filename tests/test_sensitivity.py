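"""One-way sweeps, tornado ordering, break-even search, scenarios."""

import copy

import numpy as np
import pytest

import dentalcua as d
from dentalcua.model_config import ConfigError
from dentalcua.sensitivity import (get_param, make_param_ref,
                                   numeric_leaf_paths, set_param)

TORNADO_PARAMS = ["costs.FDP.initial", "utilities.DIB", "costs.ISC.initial",
                  "costs.DIB.initial", "utilities.ISC", "utilities.FDP"]


@pytest.fixture(scope="module")
def base_cea(reference_config):
    return d.evaluate_config(reference_config)


class TestParamRef:
    def test_resolves_numeric_leaf(self, reference_config):
        ref = make_param_ref(reference_config, "utilities.ISC")
        assert ref.base_value == 74.75

    def test_materialized_cost_leaf(self, reference_config):
        cfg = d.materialize_initial_costs(reference_config)
        assert make_param_ref(cfg, "costs.FDP.initial").base_value == 40161

    def test_non_numeric_leaf_rejected(self, reference_config):
        with pytest.raises(ConfigError, match="numeric"):
            make_param_ref(reference_config, "comparison.evaluated")

    def test_unknown_path_rejected(self, reference_config):
        with pytest.raises(ConfigError, match="nonsense"):
            make_param_ref(reference_config, "utilities.nonsense")

    def test_set_then_get_roundtrip(self, reference_config):
        cfg = copy.deepcopy(reference_config)
        set_param(cfg, "utilities.ISC", 50.0)
        assert get_param(cfg, "utilities.ISC") == 50.0

    def test_leaf_enumeration_contains_study_parameters(self, reference_config):
        cfg = d.materialize_initial_costs(reference_config)
        leaves = numeric_leaf_paths(cfg)
        for path in TORNADO_PARAMS + ["economics.discount_rate"]:
            assert path in leaves


class TestOneWaySweep:
    def test_base_point_reproduces_base_case(self, reference_config, base_cea):
        series = d.one_way_sweep(reference_config, "utilities.ISC",
                                 rel_low=0.0, rel_high=0.0, n_points=1)
        value, result = series[0]
        assert value == 74.75
        assert result == base_cea

    def test_grid_contains_base_multiplier(self, reference_config, base_cea):
        series = d.one_way_sweep(reference_config, "utilities.ISC", n_points=13)
        values = [v for v, _ in series]
        assert len(series) == 13
        assert any(v == pytest.approx(74.75) for v in values)
        base_idx = int(np.argmin(np.abs(np.array(values) - 74.75)))
        assert series[base_idx][1] == base_cea

    def test_minus_thirty_percent_crown_utility_point(self, reference_config):
        series = d.one_way_sweep(reference_config, "utilities.ISC", n_points=13)
        low_value = series[0][0]
        # on the 0-1 utility scale the -30% point is 0.52325
        assert low_value / 100.0 == pytest.approx(0.52325, abs=1e-12)

    def test_lowered_crown_utility_breaks_dominance(self, reference_config):
        series = d.one_way_sweep(reference_config, "utilities.ISC", n_points=13)
        low = series[0][1]
        assert low.incremental_utility < 0
        assert low.icur > 0  # cheaper but less effective: trade-off
        assert low.dominance is d.Dominance.TRADEOFF_SW

    def test_no_effect_parameter_constant_series(self, reference_config):
        # the USD display constant plays no role in the CZK comparison
        series = d.one_way_sweep(reference_config, "environment.czk_to_usd",
                                 n_points=5)
        results = [r for _, r in series]
        assert all(r == results[0] for r in results)


class TestTornado:
    def test_bridge_cost_bounds_are_pm_thirty_percent(self, reference_config):
        entries = d.tornado(reference_config, ["costs.FDP.initial"])
        entry = entries[0]
        assert entry.value_low == pytest.approx(28112.7, abs=0.5)
        assert entry.value_high == pytest.approx(52209.3, abs=0.5)

    def test_single_no_effect_parameter_zero_span(self, reference_config):
        entries = d.tornado(reference_config, ["environment.czk_to_usd"])
        assert len(entries) == 1
        assert entries[0].span == 0.0

    def test_spans_sorted_descending_and_order_invariant(self, reference_config):
        fwd = d.tornado(reference_config, TORNADO_PARAMS)
        rev = d.tornado(reference_config, TORNADO_PARAMS[::-1])
        spans = [e.span for e in fwd]
        assert spans == sorted(spans, reverse=True)
        assert [e.param.path for e in fwd] == [e.param.path for e in rev]

    def test_toy_linear_model_ordering(self):
        # ICUR responds linearly to each arm's initial cost with slope
        # 1/ΔE, so the parameter with the larger base value has the larger
        # ±30% span; verify the analytic ordering
        cfg = d.materialize_initial_costs(d.reference_config_dict())
        entries = d.tornado(cfg, ["costs.FDP.initial", "costs.ISC.initial"])
        base = d.evaluate_config(cfg)
        d_util = base.incremental_utility
        exp_fdp = abs(2 * 0.3 * 40161 / d_util)
        by_path = {e.param.path: e for e in entries}
        # the comparator's initial cost enters ΔC more than once (the arm
        # pays it again on replacement), so its span must be at least the
        # single-payment analytic value
        assert by_path["costs.FDP.initial"].span >= exp_fdp * 0.99
        assert entries[0].param.path == "costs.FDP.initial"


class TestThresholdSearch:
    def test_identical_verdicts_return_none(self, reference_config):
        assert d.threshold_search(reference_config, "utilities.ISC",
                                  (74.0, 76.0)) is None

    def test_crown_utility_break_even_located(self, reference_config):
        # dominance flips somewhere below the base crown utility
        value = d.threshold_search(reference_config, "utilities.ISC",
                                   (0.52325 * 100, 74.75), tol=1e-6)
        assert value is not None
        assert 52.325 < value < 74.75
        # verify the verdict differs just either side of the crossing
        lo = d.one_way_sweep(reference_config, "utilities.ISC",
                             rel_low=(value - 0.01) / 74.75 - 1,
                             rel_high=(value - 0.01) / 74.75 - 1, n_points=1)
        hi = d.one_way_sweep(reference_config, "utilities.ISC",
                             rel_low=(value + 0.01) / 74.75 - 1,
                             rel_high=(value + 0.01) / 74.75 - 1, n_points=1)
        assert lo[0][1].dominance is not d.Dominance.EVALUATED_DOMINANT
        assert hi[0][1].dominance is d.Dominance.EVALUATED_DOMINANT

    def test_analytic_linear_root(self, reference_config):
        # ICUR is linear in the evaluated arm's one-off initial cost while
        # ΔE > 0 stays fixed: ΔC(x) = x + (base ΔC − base value); the
        # dominance flip is at x* = base − ΔC_base exactly
        cfg = d.materialize_initial_costs(reference_config)
        base = d.evaluate_config(cfg)
        x_base = get_param(cfg, "costs.ISC.initial")
        # the crown's initial cost is paid once up front and again (scaled
        # and discounted) on re-entry; measure the effective linear slope
        probe = copy.deepcopy(cfg)
        set_param(probe, "costs.ISC.initial", x_base + 1000.0)
        slope = (d.evaluate_config(probe).incremental_cost
                 - base.incremental_cost) / 1000.0
        root = x_base - base.incremental_cost / slope
        found = d.threshold_search(cfg, "costs.ISC.initial",
                                   (x_base, 2 * root), tol=1e-5)
        assert found == pytest.approx(root, abs=1e-2)

    def test_bisection_contract(self, reference_config):
        tol = 1e-7
        value = d.threshold_search(reference_config, "utilities.ISC",
                                   (52.0, 75.0), tol=tol)
        tighter = d.threshold_search(reference_config, "utilities.ISC",
                                     (value - 1e-3, value + 1e-3), tol=tol)
        assert abs(tighter - value) < 2e-3

    def test_bad_inputs_rejected(self, reference_config):
        with pytest.raises(ValueError, match="tolerance"):
            d.threshold_search(reference_config, "utilities.ISC",
                               (1.0, 2.0), tol=0.0)
        with pytest.raises(ValueError, match="bracket"):
            d.threshold_search(reference_config, "utilities.ISC", (2.0, 1.0))


class TestScenariosAndHorizons:
    def test_discount_monotonicity(self, reference_config):
        results = d.scenario_discounts(reference_config)
        assert set(results) == {0.0, 0.03, 0.05}
        assert results[0.0].evaluated_utility >= results[0.03].evaluated_utility
        assert results[0.03].evaluated_utility >= results[0.05].evaluated_utility
        assert results[0.0].evaluated_cost >= results[0.03].evaluated_cost

    def test_base_rate_scenario_equals_base_case(self, reference_config,
                                                 base_cea):
        results = d.scenario_discounts(reference_config, rates=[0.03])
        assert results[0.03] == base_cea

    def test_equal_utilities_zero_rate_effect_from_terminal_occupancy(self):
        # with every in-place state at the same weight and no discounting,
        # ΔE is exactly the difference of time spent with a prosthesis
        cfg = d.reference_config_dict()
        for key in ("ISC", "FDP", "DIB"):
            cfg["utilities"][key] = 100.0
        cfg["economics"]["discount_rate"] = 0.0
        model = d.build_model(cfg)
        outcome = d.run_cua(model)
        in_place_diff = (
            sum(d.in_place_survival(outcome.evaluated)[:-1])
            - sum(d.in_place_survival(outcome.comparator)[:-1])
        )
        assert outcome.cea.incremental_utility == pytest.approx(in_place_diff,
                                                                abs=1e-12)

    def test_horizon_sweep_rows_and_monotone_costs(self, reference_config,
                                                   base_cea):
        results = d.horizon_sweep(reference_config)
        horizons = sorted(results)
        assert horizons == list(range(5, 56, 5))
        costs_e = [results[h].evaluated_cost for h in horizons]
        costs_c = [results[h].comparator_cost for h in horizons]
        assert all(b >= a for a, b in zip(costs_e, costs_e[1:]))
        assert all(b >= a for a, b in zip(costs_c, costs_c[1:]))
        assert results[30] == base_cea

    def test_horizon_sweep_geometric_oracle(self):
        from conftest import geometric_utility_oracle

        cfg = d.reference_config_dict()
        for h in (5, 10, 20):
            arm, survivals = d.make_toy_geometric_model(0.1, utility=80.0)
            econ = d.EconSettings(discount_rate=0.03, horizon=h)
            result = d.run_cohort(arm, survivals, econ)
            assert result.cumulative_utility == pytest.approx(
                geometric_utility_oracle(0.1, 80.0, h, 0.03), abs=1e-10)
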