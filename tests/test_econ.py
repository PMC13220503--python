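"""Economics: ICER/iNMB identities, severity modifier, scenario battery,
relative-ICER transfer and probabilistic sensitivity analysis."""

import numpy as np
import pytest

from survhta.econ import (DOMINANT, DOMINATED, UNDEFINED, TransferError,
                          general_population_qalys, icer, qaly_shortfall,
                          transfer_relative_icer)
from survhta.partsa import ConfigurationError


class TestICER:
    def test_ratio_and_inmb_identity(self):
        r = icer((5000.0, 0.25, 0.3), thresholds=[20000.0])
        assert r.icer == pytest.approx(20000.0)
        assert r.inmb[20000.0] == pytest.approx(0.0)

    def test_cost_saving_more_effective_is_dominant(self):
        assert icer((-100.0, 0.1, 0.1)).icer == DOMINANT

    def test_more_costly_less_effective_is_dominated(self):
        assert icer((100.0, -0.1, -0.1)).icer == DOMINATED

    def test_zero_qaly_gain_with_cost_is_undefined_but_inmb_computed(self):
        r = icer((100.0, 0.0, 0.0), thresholds=[20000.0])
        assert r.icer == UNDEFINED
        assert r.inmb[20000.0] == pytest.approx(-100.0)

    def test_severity_weight_enters_inmb_and_icer(self):
        dc, dq = 4000.0, 0.25
        r = icer((dc, dq, 0.3), thresholds=[20000.0], severity_weight=1.2)
        assert r.inmb[20000.0] == pytest.approx(20000.0 * 1.2 * dq - dc)
        assert r.icer == pytest.approx(dc / (1.2 * dq))


class TestGeneralPopulationQALYs:
    def test_matches_product_sum_oracle_constant_mortality(self):
        q = 0.02
        got = general_population_qalys(60.0, 0.4,
                                       {"constant_annual_death_prob": q},
                                       1.0, 0.0, max_age=1000.0)
        s, total = 1.0, 0.0
        for _ in range(940):
            s_next = s * (1 - q)
            total += 0.5 * (s + s_next)
            s = s_next
        assert got == pytest.approx(total, abs=1e-9)

    def test_zero_utility_norm_gives_zero(self):
        assert general_population_qalys(
            60.0, 0.4, {"constant_annual_death_prob": 0.02}, 0.0) == 0.0

    def test_discounting_strictly_decreases_expectation(self):
        kw = dict(start_age=60.0, proportion_female=0.4,
                  life_table={"constant_annual_death_prob": 0.02},
                  utility_norm=0.8)
        assert general_population_qalys(**kw, discount_rate=0.035) < \
            general_population_qalys(**kw, discount_rate=0.0)

    def test_missing_life_table_age_rejected(self):
        with pytest.raises(ConfigurationError):
            general_population_qalys(60.0, 0.4, {"table": {60: 0.02}}, 1.0,
                                     max_age=70.0)


class TestQALYShortfall:
    def test_worked_example_weight_one(self):
        sf = qaly_shortfall(1.0, 1.0, 10.0)
        assert sf.absolute_shortfall == 8.0
        assert sf.proportional_shortfall == pytest.approx(0.80)
        assert sf.weight == 1.0

    def test_absolute_rule_triggers_1_2(self):
        sf = qaly_shortfall(1.5, 0.0, 15.0)  # absolute 13.5 >= 12
        assert sf.weight == 1.2

    def test_boundaries_on_each_threshold(self):
        # proportional boundary at 0.85
        assert qaly_shortfall(1.5, 0.0, 10.0).weight == 1.2    # 0.85 exactly
        assert qaly_shortfall(1.51, 0.0, 10.0).weight == 1.0   # just below
        # absolute boundary at 12
        assert qaly_shortfall(8.0, 0.0, 20.0).weight == 1.2    # 12 exactly
        assert qaly_shortfall(8.01, 0.0, 20.0).weight == 1.0   # just below
        # 1.7 boundaries: proportional 0.95 and absolute 18
        assert qaly_shortfall(1.0, 0.0, 20.0).weight == 1.7    # prop 0.95
        assert qaly_shortfall(2.0, 0.0, 20.0).weight == 1.7    # abs 18
        assert qaly_shortfall(2.5, 0.0, 20.0).weight == 1.2    # abs 17.5

    def test_subsequent_addition_reduces_shortfall(self):
        without = qaly_shortfall(1.0, 0.0, 14.0)
        with_add = qaly_shortfall(1.0, 1.5, 14.0)
        assert with_add.absolute_shortfall < without.absolute_shortfall
        assert with_add.weight <= without.weight

    def test_weight_monotone_in_shortfall(self):
        weights = [qaly_shortfall(soc, 0.0, 20.0).weight
                   for soc in np.linspace(19.0, 0.5, 30)]
        assert all(b >= a for a, b in zip(weights, weights[1:]))

    def test_negative_adjusted_soc_rejected(self):
        with pytest.raises(ConfigurationError):
            qaly_shortfall(-2.0, 1.0, 10.0)


class TestTransfer:
    def test_unit_ratio_returns_anchor(self):
        assert transfer_relative_icer(15000.0, 15000.0, 12000.0) == 12000.0

    def test_worked_arithmetic(self):
        # first line: anchor 20k, other 10k; second-line anchor 15k -> 7.5k
        assert transfer_relative_icer(20000.0, 10000.0, 15000.0) == \
            pytest.approx(7500.0)

    def test_dominance_tag_makes_transfer_undefined(self):
        with pytest.raises(TransferError):
            transfer_relative_icer(DOMINANT, 10000.0, 15000.0)
        with pytest.raises(TransferError):
            transfer_relative_icer(20000.0, -5000.0, 15000.0)


class TestScenarios:
    def test_table_has_base_case_first_and_all_rows(self, decision_model):
        table = decision_model.run_scenarios(
            ["base", "alternative_distribution", "hazard_ratio",
             "weighted_median_price", "vial_sharing"])
        assert list(table["scenario"])[0] == "base"
        assert len(table) == 5
        assert "skipped" not in table.columns or table["skipped"].isna().all()

    def test_unit_hazard_ratio_scenario_zeroes_health_increments(
            self, decision_model):
        from dataclasses import replace
        from survhta.partsa import UtilitySpec
        # neutralize the designed adverse-event disutility asymmetry so the
        # only health difference can come from the curves themselves
        utils = {arm: replace(u, ae_events=())
                 for arm, u in decision_model.utilities.items()}
        model = replace(decision_model, utilities=utils,
                        hr_scenario={"os_hr": 1.0, "pfs_hr": 1.0})
        res = model._scenario("hazard_ratio")
        assert abs(res.delta_qaly) < 1e-9
        assert abs(res.delta_ly) < 1e-9

    def test_alternative_distribution_changes_increments(self, decision_model):
        base = decision_model.run_deterministic("base")
        alt = decision_model.run_deterministic("sensitivity")
        assert alt.delta_ly != base.delta_ly

    def test_scenario_runner_is_pure(self, decision_model):
        a = decision_model.run_scenarios(["base", "vial_sharing"])
        b = decision_model.run_scenarios(["base", "vial_sharing"])
        assert a.equals(b)


class TestPSA:
    def test_zero_variance_draws_reproduce_deterministic(self, decision_model):
        det = decision_model.run_deterministic("base")
        psa = decision_model.run_psa(n_draws=5, seed=3, se_fraction=0.0,
                                     survival_vcov_scale=0.0,
                                     sample_costs=False)
        assert np.allclose(psa.draws["delta_qaly"], det.delta_qaly, atol=1e-12)
        assert np.allclose(psa.draws["delta_cost"], det.delta_cost, atol=1e-9)

    def test_same_seed_identical_ceac(self, decision_model):
        a = decision_model.run_psa(n_draws=40, seed=11)
        b = decision_model.run_psa(n_draws=40, seed=11)
        assert a.ceac.equals(b.ceac)

    def test_ceac_probabilities_valid_and_monotone_tendency(self, decision_model):
        psa = decision_model.run_psa(n_draws=60, seed=13)
        p = psa.ceac["p_cost_effective"].to_numpy()
        assert np.all((p >= 0) & (p <= 1))
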