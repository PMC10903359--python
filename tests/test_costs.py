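import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import surveycost as sc
from surveycost.costs import ScenarioError


class TestCostEquations:
    @pytest.mark.parametrize(
        "method, expected_fixed",
        [("goby_seine", 37.0), ("goby_metabarcode", 7.5)],
    )
    def test_fixed_cost_worked_examples(self, table1, unit_design, method, expected_fixed):
        assert sc.fixed_cost(table1[method], unit_design) == pytest.approx(expected_fixed)

    @pytest.mark.parametrize(
        "method, expected_variable",
        [("goby_seine", 4.9), ("goby_metabarcode", 4.5)],
    )
    def test_variable_cost_worked_examples(self, table1, unit_design, method, expected_variable):
        assert sc.variable_cost(table1[method], unit_design) == pytest.approx(expected_variable)

    def test_seine_total_single_sample(self, table1, unit_design):
        total = sc.total_cost(table1["goby_seine"], unit_design)
        assert total == pytest.approx(41.9)
        assert round(total) == 42

    def test_fixed_cost_shared_across_locations(self, table1):
        total = sc.total_cost(table1["goby_seine"], sc.EffortDesign(L=10, k=1, n=1))
        assert total == pytest.approx(25.7)

    def test_zero_params_zero_cost(self, unit_design):
        zero = sc.CostParams()
        assert sc.total_cost(zero, unit_design) == 0.0

    def test_no_sites_no_variable_cost(self, table1):
        design = sc.EffortDesign(L=1, k=0, n=3)
        assert sc.variable_cost(table1["goby_seine"], design) == 0.0
        assert sc.total_cost(table1["goby_seine"], design) == sc.fixed_cost(
            table1["goby_seine"], design
        )


class TestCostProperties:
    @given(L1=st.integers(1, 1000), L2=st.integers(1, 1000))
    @settings(derandomize=True)
    def test_fixed_cost_nonincreasing_in_locations(self, table1, L1, L2):
        params = table1["fish_seine"]
        lo, hi = sorted((L1, L2))
        assert sc.fixed_cost(params, sc.EffortDesign(L=hi)) <= sc.fixed_cost(
            params, sc.EffortDesign(L=lo)
        ) + 1e-12

    def test_fixed_share_vanishes_at_many_locations(self, table1):
        params = table1["goby_seine"]
        base = params.B + params.W * params.V + params.R
        assert sc.fixed_cost(params, sc.EffortDesign(L=10**9)) == pytest.approx(base)

    @given(k=st.integers(0, 50), n=st.integers(0, 50), dn=st.integers(1, 10))
    @settings(derandomize=True)
    def test_sample_increment_is_exact(self, table1, k, n, dn):
        params = table1["qPCR"]
        slope = params.t * params.W + params.E + params.D + params.q
        c0 = sc.total_cost(params, sc.EffortDesign(L=1, k=k, n=n))
        c1 = sc.total_cost(params, sc.EffortDesign(L=1, k=k, n=n + dn))
        assert c1 - c0 == pytest.approx(k * dn * slope)

    def test_total_strictly_increasing_in_effort(self, table1):
        params = table1["goby_metabarcode"]
        costs_k = [sc.total_cost(params, sc.EffortDesign(k=k, n=1)) for k in range(1, 6)]
        costs_n = [sc.total_cost(params, sc.EffortDesign(k=1, n=n)) for n in range(1, 6)]
        assert all(b > a for a, b in zip(costs_k, costs_k[1:]))
        assert all(b > a for a, b in zip(costs_n, costs_n[1:]))


class TestValidationAndScenarios:
    def test_zero_locations_rejected(self):
        with pytest.raises(ValueError, match="L"):
            sc.EffortDesign(L=0)

    def test_negative_effort_rejected(self):
        with pytest.raises(ValueError):
            sc.EffortDesign(L=1, k=-1, n=1)
        with pytest.raises(ValueError):
            sc.EffortDesign(L=1, k=1, n=-2)

    def test_negative_parameter_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            sc.CostParams(E=-1.0)

    def test_worker_multiplier_at_least_one(self):
        with pytest.raises(ValueError, match="W"):
            sc.CostParams(W=0.5)

    def test_no_environment_scenario(self, table1, unit_design):
        scenario = sc.CostScenario(label="no_E", param_overrides={"E": 0.0})
        params, design = sc.apply_scenario(table1["goby_seine"], unit_design, scenario)
        assert params.E == 0.0
        assert params.P == table1["goby_seine"].P  # everything else unchanged
        assert table1["goby_seine"].E == 3.0  # original untouched

    def test_validated_assay_scenario(self, table1, unit_design):
        scenario = sc.CostScenario(label="validated", param_overrides={"A": 0.0})
        params, _ = sc.apply_scenario(
            sc.CostParams(A=85.0, method_label="qPCR"), unit_design, scenario
        )
        assert params.A == 0.0

    def test_empty_scenario_is_identity(self, table1, unit_design):
        params, design = sc.apply_scenario(
            table1["qPCR"], unit_design, sc.CostScenario(label="noop")
        )
        assert params == table1["qPCR"]
        assert design == unit_design

    def test_scenario_idempotent(self, table1, unit_design):
        scenario = sc.CostScenario(
            label="s", param_overrides={"E": 0.0, "P": 0.0}, design_overrides={"L": 10}
        )
        once = sc.apply_scenario(table1["goby_seine"], unit_design, scenario)
        twice = sc.apply_scenario(*once, scenario)
        assert once == twice

    def test_unknown_override_field_rejected(self):
        with pytest.raises(ScenarioError, match="unknown"):
            sc.CostScenario(label="bad", param_overrides={"X": 1.0})

    def test_dollar_conversion(self):
        assert sc.hours_to_dollars(2.0) == 60.0


class TestIO:
    def test_packaged_table_has_all_methods(self, table1):
        assert set(table1) == {
            "qPCR", "goby_metabarcode", "fish_metabarcode", "goby_seine", "fish_seine"
        }
        assert table1["fish_seine"].D == 0.4
        assert table1["qPCR"].q == 1.8

    def test_scenario_json_round_trip(self, tmp_path):
        path = tmp_path / "scenario.json"
        path.write_text(json.dumps(
            {"label": "many_sites", "overrides": {"E": 0, "L": 100},
             "design": {"L": 1, "k": 5, "n": 1}}
        ))
        scenario, design = sc.load_scenario(path)
        assert scenario.param_overrides == {"E": 0}
        assert scenario.design_overrides == {"L": 100}
        assert design == sc.EffortDesign(L=1, k=5, n=1)

    def test_params_csv_round_trip(self, tmp_path, table1):
        path = tmp_path / "params.csv"
        with open(path, "w") as fh:
            fh.write("method_label,P,B,G,A,W,V,v,t,E,q,D,R,r\n")
            fh.write("custom,1,2,3,4,5,6,0.5,0.3,0,0,0.1,2,0\n")
        loaded = sc.load_cost_params(path)["custom"]
        assert loaded.P == 1 and loaded.W == 5 and loaded.D == 0.1
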