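"""Partitioned survival engine: occupancy arithmetic, conservation,
half-cycle accumulation and linearity."""

import numpy as np
import pytest

from survhta.distributions import get_family
from survhta.fitting import ParametricSurvival, restricted_mean
from survhta.partsa import (ArmCosts, ConfigurationError, PartSASpec,
                            UtilitySpec, accumulate_costs, accumulate_qalys,
                            build_traces, make_age_index, run_comparison)

WEEK = 7.0 / 365.25


def surv(family, **params):
    fam = get_family(family)
    return ParametricSurvival(fam, fam.validate(params))


def spec(os_s, pfs_s, r=0.0, **kw):
    return PartSASpec(os_model=os_s, pfs_model=pfs_s, cycle_length=WEEK,
                      horizon=40.0, discount_rate_qaly=r, discount_rate_cost=r,
                      **kw)


EXP02 = surv("exponential", rate=0.2)


class TestBuildTraces:
    def test_identical_curves_leave_progressed_state_empty(self):
        tr = build_traces(spec(EXP02, EXP02))
        assert np.all(tr.pd == 0.0)

    def test_occupancies_conserve_and_dead_monotone(self):
        tr = build_traces(spec(surv("weibull", shape=1.3, scale=2.0),
                               surv("weibull", shape=1.3, scale=1.0)))
        assert np.max(np.abs(tr.pf + tr.pd + tr.dead - 1.0)) <= 1e-9
        assert np.all(np.diff(tr.dead) >= -1e-12)

    def test_total_ly_matches_closed_form(self):
        tr = build_traces(spec(EXP02, EXP02))
        q = accumulate_qalys(tr, UtilitySpec(1.0, 1.0), 0.0)
        closed = (1 - np.exp(-8)) / 0.2
        assert abs(q.ly_undiscounted - closed) / closed < 0.005

    def test_pfs_above_os_clipped_with_conservation(self):
        # PFS "survival" above OS everywhere: clipping keeps PF = OS
        tr = build_traces(spec(surv("exponential", rate=0.3),
                               surv("exponential", rate=0.2)))
        assert tr.clip_warnings > 0
        assert np.all(tr.pd == 0.0)
        assert np.max(np.abs(tr.pf + tr.pd + tr.dead - 1.0)) <= 1e-9

    def test_fixed_duration_ttd_caps_exposure(self):
        s = spec(EXP02, EXP02, ttd=0.5)
        tr = build_traces(s)
        on = tr.on_treatment
        assert np.all(on[tr.times < 0.5] == tr.pf[tr.times < 0.5])
        assert np.all(on[tr.times >= 0.5] == 0.0)

    def test_km_ttd_capped_by_progression_free(self):
        s = spec(EXP02, surv("exponential", rate=0.4),
                 ttd=surv("exponential", rate=0.3))
        tr = build_traces(s)
        assert np.all(tr.on_treatment <= tr.pf + 1e-12)


class TestAccumulateQALYs:
    def test_unit_utilities_equal_life_years(self):
        tr = build_traces(spec(EXP02, surv("exponential", rate=0.4)))
        q = accumulate_qalys(tr, UtilitySpec(1.0, 1.0), 0.0)
        assert q.qalys_discounted == pytest.approx(q.ly_discounted, abs=1e-12)

    def test_discounted_qalys_match_quadrature_oracle(self):
        u = 0.77
        tr = build_traces(spec(EXP02, EXP02, r=0.035))
        q = accumulate_qalys(tr, UtilitySpec(u, u), 0.035)
        oracle = u * restricted_mean(EXP02, 40.0, 0.035)
        assert abs(q.qalys_discounted - oracle) / oracle < 0.005

    def test_discounting_never_increases_output(self):
        tr = build_traces(spec(EXP02, EXP02))
        util = UtilitySpec(0.77, 0.68)
        q0 = accumulate_qalys(tr, util, 0.0)
        q35 = accumulate_qalys(tr, util, 0.035)
        assert q35.qalys_discounted <= q0.qalys_discounted
        assert q35.ly_discounted <= q0.ly_discounted == q0.ly_undiscounted

    def test_age_decrement_reduces_qalys(self):
        idx = make_age_index({"intercept": 0.95, "age": -0.0003,
                              "age_squared": -0.00003}, 60.0, 0.4)
        tr = build_traces(spec(EXP02, EXP02))
        with_dec = accumulate_qalys(tr, UtilitySpec(0.77, 0.68, age_index=idx),
                                    0.0)
        without = accumulate_qalys(tr, UtilitySpec(0.77, 0.68), 0.0)
        assert with_dec.qalys_discounted < without.qalys_discounted

    def test_utility_order_enforced(self):
        with pytest.raises(ConfigurationError):
            UtilitySpec(u_pf=0.5, u_pd=0.9)

    def test_cycle_refinement_converges(self):
        s1 = spec(EXP02, EXP02, r=0.035)
        s2 = PartSASpec(os_model=EXP02, pfs_model=EXP02, cycle_length=WEEK / 2,
                        horizon=40.0, discount_rate_qaly=0.035,
                        discount_rate_cost=0.035)
        q1 = accumulate_qalys(build_traces(s1), UtilitySpec(1, 1), 0.035)
        q2 = accumulate_qalys(build_traces(s2), UtilitySpec(1, 1), 0.035)
        assert abs(q1.ly_discounted - q2.ly_discounted) / q2.ly_discounted \
            < 0.002


class TestAccumulateCosts:
    def test_terminal_cost_conserved_when_everyone_dies(self):
        s = PartSASpec(os_model=surv("exponential", rate=0.5),
                       pfs_model=surv("exponential", rate=0.5),
                       cycle_length=WEEK, horizon=200.0,
                       discount_rate_qaly=0.0, discount_rate_cost=0.0)
        items = accumulate_costs(build_traces(s), ArmCosts(terminal_cost=6265.0),
                                 0.0)
        assert items["terminal"] == pytest.approx(6265.0, rel=1e-9)

    def test_state_costs_follow_occupancy(self):
        # identical OS/PFS -> no progressed occupancy -> only PF state cost
        tr = build_traces(spec(EXP02, EXP02))
        items = accumulate_costs(
            tr, ArmCosts(state_cost_pf_monthly=133.0,
                         state_cost_pd_monthly=273.0), 0.0)
        pf_months = (1 - np.exp(-8)) / 0.2 * 12.0
        assert items["state"] == pytest.approx(133.0 * pf_months, rel=0.005)

    def test_doubling_unit_costs_doubles_total(self):
        tr = build_traces(spec(EXP02, surv("exponential", rate=0.4), ttd=0.4))
        base = ArmCosts(acquisition_per_cycle=50.0,
                        admin_monitoring_monthly=819.0,
                        state_cost_pf_monthly=133.0,
                        state_cost_pd_monthly=273.0, terminal_cost=6265.0,
                        ae_events=((0.3, 400.0),))
        double = ArmCosts(acquisition_per_cycle=100.0,
                          admin_monitoring_monthly=1638.0,
                          state_cost_pf_monthly=266.0,
                          state_cost_pd_monthly=546.0, terminal_cost=12530.0,
                          ae_events=((0.3, 800.0),))
        a = accumulate_costs(tr, base, 0.035)
        b = accumulate_costs(tr, double, 0.035)
        assert b["total"] == pytest.approx(2 * a["total"], rel=1e-12)


class TestRunComparison:
    def test_identical_arms_zero_increments(self):
        s = spec(EXP02, surv("exponential", rate=0.4), ttd=0.4)
        util = UtilitySpec(0.77, 0.68)
        costs = ArmCosts(acquisition_per_cycle=10.0, terminal_cost=6265.0)
        res = run_comparison(s, s, util, util, costs, costs)
        assert res.delta_ly == 0.0
        assert res.delta_qaly == 0.0
        assert res.delta_cost == 0.0

    def test_increments_continuous_in_effect_size(self):
        base_os = surv("exponential", rate=0.2)
        from survhta.fitting import apply_hazard_ratio
        nearly = apply_hazard_ratio(base_os, 0.999)
        s_c = spec(base_os, base_os)
        s_i = spec(nearly, nearly)
        util = UtilitySpec(0.77, 0.68)
        res = run_comparison(s_i, s_c, util, util, ArmCosts(), ArmCosts())
        assert 0 < res.delta_qaly < 0.01

    def test_mismatched_cycle_structure_rejected(self):
        s1 = spec(EXP02, EXP02)
        s2 = PartSASpec(os_model=EXP02, pfs_model=EXP02, cycle_length=WEEK,
                        horizon=30.0)
        util = UtilitySpec(0.77, 0.68)
        with pytest.raises(ConfigurationError):
            run_comparison(s1, s2, util, util, ArmCosts(), ArmCosts())
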