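"""Parametric fitting: likelihood correctness, information criteria,
hazard-shape classification, selection policy and survival utilities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from survhta.datatypes import SurvivalDataset
from survhta.distributions import FAMILY_NAMES, ParameterError, get_family
from survhta.fitting import (ParametricSurvival, apply_hazard_ratio,
                             classify_hazard_shape, fit_all, fit_parametric,
                             restricted_mean, select_family_joint)
from survhta.km import EstimationError
from survhta.synthetic import CensoringSpec, TrueArmModel, simulate_arm

NO_CENS = CensoringSpec(admin_time=1e9)


def surv(family, **params):
    fam = get_family(family)
    return ParametricSurvival(fam, fam.validate(params))


class TestFitParametric:
    def test_exponential_rate_is_events_over_person_time_exactly(self):
        # 10 events, total person-time 100 -> rate 0.10 exactly
        d = SurvivalDataset(np.full(10, 10.0), np.ones(10, int))
        fit = fit_parametric(d, "exponential")
        assert fit.params["rate"] == 0.1

    def test_exponential_aic_identity(self):
        d = SurvivalDataset(np.full(10, 10.0), np.ones(10, int))
        fit = fit_parametric(d, "exponential")
        assert fit.aic == pytest.approx(2 - 2 * fit.loglik, abs=1e-12)

    def test_weibull_shape_recovered_under_censoring(self):
        truth = TrueArmModel("weibull", {"shape": 1.3, "scale": 2.0})
        cens = CensoringSpec(admin_time=float(truth.isf(0.25)))  # 25% admin
        d = simulate_arm(truth, cens, 1000, seed=21)
        fit = fit_parametric(d, "weibull")
        assert abs(fit.params["shape"] - 1.3) / 1.3 < 0.10

    @pytest.mark.parametrize("family", FAMILY_NAMES)
    def test_information_criterion_identities(self, family):
        truth = TrueArmModel("weibull", {"shape": 1.2, "scale": 2.0})
        d = simulate_arm(truth, CensoringSpec(admin_time=4.0), 300, seed=13)
        fit = fit_parametric(d, family)
        k = fit.k
        assert fit.aic == pytest.approx(2 * k - 2 * fit.loglik, abs=1e-9)
        assert fit.bic == pytest.approx(k * np.log(fit.n) - 2 * fit.loglik,
                                        abs=1e-9)
        w = np.linalg.eigvalsh(0.5 * (fit.vcov + fit.vcov.T))
        assert w.min() >= -1e-10  # positive semi-definite

    def test_matches_lifelines_weibull(self):
        from lifelines import WeibullFitter
        truth = TrueArmModel("weibull", {"shape": 1.4, "scale": 2.2})
        d = simulate_arm(truth, CensoringSpec(admin_time=3.0), 500, seed=17)
        ours = fit_parametric(d, "weibull")
        ll = WeibullFitter().fit(d.times, d.events)
        assert ours.loglik == pytest.approx(ll.log_likelihood_, abs=1e-3)
        assert ours.params["scale"] == pytest.approx(ll.lambda_, rel=1e-3)
        assert ours.params["shape"] == pytest.approx(ll.rho_, rel=1e-3)

    def test_all_censored_rejected(self):
        d = SurvivalDataset([1.0, 2.0, 3.0], [0, 0, 0])
        with pytest.raises(EstimationError):
            fit_parametric(d, "weibull")

    def test_gengamma_nests_weibull_and_lognormal(self):
        for family, params in [("weibull", {"shape": 1.3, "scale": 2.0}),
                               ("lognormal", {"meanlog": 0.4, "sdlog": 0.7})]:
            d = simulate_arm(TrueArmModel(family, params),
                             CensoringSpec(admin_time=6.0), 800, seed=23)
            sub = fit_parametric(d, family)
            gg = fit_parametric(d, "gengamma")
            assert gg.loglik >= sub.loglik - 0.5

    def test_fit_deterministic(self):
        d = simulate_arm(TrueArmModel("gamma", {"shape": 1.5, "rate": 0.8}),
                         CensoringSpec(admin_time=4.0), 400, seed=29)
        a = fit_parametric(d, "gengamma")
        b = fit_parametric(d, "gengamma")
        assert a.params == b.params and a.loglik == b.loglik


class TestDistributions:
    @pytest.mark.parametrize("family,params", [
        ("exponential", {"rate": 0.3}),
        ("weibull", {"shape": 1.5, "scale": 2.0}),
        ("gompertz", {"shape": 0.4, "rate": 0.2}),
        ("gompertz", {"shape": -0.3, "rate": 0.2}),  # improper plateau
        ("lognormal", {"meanlog": 0.5, "sdlog": 0.8}),
        ("loglogistic", {"shape": 1.8, "scale": 1.7}),
        ("gamma", {"shape": 1.5, "rate": 0.8}),
        ("gengamma", {"mu": 0.8, "sigma": 0.6, "Q": 1.2}),
        ("gengamma", {"mu": 0.8, "sigma": 0.6, "Q": -0.7}),
    ])
    def test_survival_function_invariants(self, family, params):
        s = surv(family, **params)
        t = np.linspace(0.0, 50.0, 400)
        vals = np.asarray(s.sf(t))
        assert vals[0] == pytest.approx(1.0)
        assert np.all(np.diff(vals) <= 1e-12)
        assert np.all((vals >= 0) & (vals <= 1))
        # inverse survival really inverts (where not at a plateau)
        u = np.array([0.9, 0.5, 0.2])
        tt = np.asarray(s.isf(u))
        finite = np.isfinite(tt)
        assert np.allclose(np.asarray(s.sf(tt[finite])), u[finite], atol=1e-8)

    @given(st.floats(0.5, 3.0), st.floats(0.5, 4.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_weibull_hazard_matches_analytic(self, shape, scale):
        s = surv("weibull", shape=shape, scale=scale)
        t = np.array([0.5, 1.0, 2.0])
        analytic = (shape / scale) * (t / scale) ** (shape - 1)
        assert np.allclose(s.hazard(t), analytic, rtol=1e-8)


class TestHazardShape:
    def test_exponential_constant(self):
        assert classify_hazard_shape(surv("exponential", rate=0.2)) == "constant"

    def test_weibull_and_gompertz_increasing(self):
        assert classify_hazard_shape(surv("weibull", shape=2, scale=2)) == \
            "increasing"
        assert classify_hazard_shape(surv("gompertz", shape=0.5, rate=0.2)) == \
            "increasing"

    def test_weibull_shape_below_one_decreasing(self):
        assert classify_hazard_shape(surv("weibull", shape=0.7, scale=2)) == \
            "decreasing"

    def test_lognormal_unimodal(self):
        s = surv("lognormal", meanlog=1.0, sdlog=0.5)
        assert classify_hazard_shape(s, horizon=40.0) == "unimodal"


class TestFitAll:
    def test_ranking_lists_all_seven_with_flags(self):
        d = simulate_arm(TrueArmModel("weibull", {"shape": 1.3, "scale": 2.0}),
                         CensoringSpec(admin_time=4.0), 500, seed=31)
        rk = fit_all(d)
        assert len(rk.table) == 7
        assert {"family", "aic", "bic", "converged",
                "hazard_shape"} <= set(rk.table.columns)
        assert rk.sensitivity_family != rk.base_family
        crit = rk.table["aic"].to_numpy()
        assert np.all(np.diff(crit[np.isfinite(crit)]) >= -1e-9)

    def test_exponential_truth_weibull_aic_close(self):
        # Weibull nests exponential with one extra parameter: AIC gap <= 2.5
        d = simulate_arm(TrueArmModel("exponential", {"rate": 0.4}),
                         NO_CENS, 1000, seed=37)
        rk = fit_all(d)
        t = rk.table.set_index("family")
        assert t.loc["weibull", "aic"] - t.loc["exponential", "aic"] <= 2.5

    def test_joint_selection_returns_common_family(self):
        truth = TrueArmModel("weibull", {"shape": 1.4, "scale": 2.0})
        ranks = [fit_all(simulate_arm(truth, CensoringSpec(admin_time=4.0),
                                      500, seed=s)) for s in (41, 43)]
        fam = select_family_joint(ranks)
        assert fam in FAMILY_NAMES
        assert all(fam in r.fits for r in ranks)


class TestHazardRatioAndRMST:
    def test_unit_hazard_ratio_is_identity(self):
        base = surv("weibull", shape=1.3, scale=2.0)
        t = np.linspace(0, 10, 50)
        assert np.allclose(apply_hazard_ratio(base, 1.0).sf(t), base.sf(t))

    def test_exponential_half_hazard_doubles_median(self):
        ph = apply_hazard_ratio(surv("exponential", rate=0.1), 0.5)
        median = np.log(2) / 0.05
        assert float(ph.sf(median)) == pytest.approx(0.5, abs=1e-10)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ParameterError):
            apply_hazard_ratio(surv("exponential", rate=0.1), 0.0)

    def test_monotone_in_hazard_ratio(self):
        base = surv("weibull", shape=1.3, scale=2.0)
        t = np.linspace(0.1, 10, 30)
        lower = apply_hazard_ratio(base, 0.75)
        higher = apply_hazard_ratio(base, 1.25)
        assert np.all(np.asarray(lower.sf(t)) > np.asarray(base.sf(t)))
        assert np.all(np.asarray(higher.sf(t)) < np.asarray(base.sf(t)))

    def test_restricted_mean_closed_forms(self):
        s = surv("exponential", rate=0.2)
        assert restricted_mean(s, 40.0) == pytest.approx((1 - np.exp(-8)) / 0.2,
                                                         rel=1e-8)
        expect = 1.0 / (0.2 + np.log(1.035))
        assert restricted_mean(s, 1000.0, 0.035) == pytest.approx(expect,
                                                                  rel=1e-6)

    def test_discounting_reduces_restricted_mean(self):
        s = surv("weibull", shape=1.3, scale=2.0)
        assert restricted_mean(s, 40.0, 0.035) < restricted_mean(s, 40.0, 0.0)
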