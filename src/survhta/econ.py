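"""Decision economics: ICER and incremental net monetary benefit, the
QALY-shortfall severity modifier (with the subsequent-treatment QALY
adjustment applied inside the shortfall only), the deterministic scenario
battery, and probabilistic sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .costing import BodyMetricDistribution, CostSpec, regimen_cycle_cost
from .fitting import (ParametricModel, ProportionalHazardsSurvival,
                      apply_hazard_ratio, nearest_psd)
from .partsa import (ArmCosts, ComparisonResult, ConfigurationError, PartSASpec,
                     UtilitySpec, run_comparison)

ARMS = ("intervention", "comparator")

DOMINANT = "dominant"
DOMINATED = "dominated"
UNDEFINED = "undefined"


class TransferError(ValueError):
    """Relative-ICER transfer undefined (dominance or non-positive inputs)."""


@dataclass
class EconResult:
    """Increments, ICER (or a dominance tag) and iNMB per threshold."""

    delta_cost: float
    delta_qaly: float
    delta_ly: float
    icer: Union[float, str]
    inmb: Dict[float, float]
    severity_weight: float = 1.0
    comparison: Optional[ComparisonResult] = None

    def as_row(self) -> Dict[str, float]:
        row = {"delta_ly": self.delta_ly, "delta_qaly": self.delta_qaly,
               "delta_cost": self.delta_cost, "icer": self.icer,
               "severity_weight": self.severity_weight}
        for lam, v in self.inmb.items():
            row[f"inmb_{int(lam)}"] = v
        return row


def icer(increments, thresholds: Sequence[float] = (20000.0, 30000.0),
         severity_weight: float = 1.0) -> EconResult:
    """ICER = ΔC/ΔQ and iNMB(λ) = λ·(w·ΔQ) − ΔC.

    ``increments`` is either a :class:`ComparisonResult` or a
    (ΔC, ΔQ, ΔLY) triple. Sign conventions: more QALYs at no extra cost is
    ``dominant``; fewer QALYs at no saving is ``dominated``; ΔQ = 0 with
    ΔC ≠ 0 leaves the ICER ``undefined`` (iNMB is still computed).
    """
    comparison = None
    if isinstance(increments, ComparisonResult):
        comparison = increments
        dc, dq, dly = (increments.delta_cost, increments.delta_qaly,
                       increments.delta_ly)
    else:
        dc, dq, dly = increments
    if not all(np.isfinite([dc, dq, dly])):
        raise ConfigurationError("increments must be finite")
    wq = severity_weight * dq
    inmb = {float(lam): float(lam * wq - dc) for lam in thresholds}
    if dq == 0.0:
        ratio: Union[float, str] = UNDEFINED if dc != 0.0 else 0.0
    elif dq > 0 and dc <= 0:
        ratio = DOMINANT
    elif dq < 0 and dc >= 0:
        ratio = DOMINATED
    else:
        ratio = float(dc / wq)
    return EconResult(delta_cost=float(dc), delta_qaly=float(dq),
                      delta_ly=float(dly), icer=ratio, inmb=inmb,
                      severity_weight=severity_weight, comparison=comparison)


# ---------------------------------------------------------------------------
# Severity modifier
# ---------------------------------------------------------------------------

@dataclass
class ShortfallResult:
    genpop_qalys: float
    soc_qalys_adjusted: float
    absolute_shortfall: float
    proportional_shortfall: float
    weight: float


DEFAULT_SEVERITY_THRESHOLDS = {
    "weight_1_2": {"proportional": 0.85, "absolute": 12.0},
    "weight_1_7": {"proportional": 0.95, "absolute": 18.0},
}


def general_population_qalys(start_age: float, proportion_female: float,
                             life_table, utility_norm,
                             discount_rate: float = 0.035,
                             max_age: float = 110.0) -> float:
    """Discounted QALY expectation of the matched general population.

    Annual life-table survival is accumulated as a product of (1 − q(age));
    each year contributes mid-year survival × the age/sex utility norm ×
    the mid-year discount factor (half-year convention).

    ``life_table`` is either ``{"constant_annual_death_prob": q}`` or
    ``{"table": {age: q, ...}}`` covering every integer age from
    ``floor(start_age)`` up to ``max_age``.
    """
    if isinstance(life_table, dict) and "constant_annual_death_prob" in life_table:
        q_of = lambda age: float(life_table["constant_annual_death_prob"])
    elif isinstance(life_table, dict) and "table" in life_table:
        tab = {int(a): float(q) for a, q in life_table["table"].items()}

        def q_of(age):
            a = int(np.floor(age))
            if a not in tab:
                raise ConfigurationError(f"life table missing age {a}")
            return tab[a]
    else:
        raise ConfigurationError("life_table must provide a constant rate or a table")

    if callable(utility_norm):
        u_of = utility_norm
    else:
        u_of = lambda age: float(utility_norm)

    total, s = 0.0, 1.0
    age = float(start_age)
    k = 0
    while age < max_age and s > 1e-12:
        q = q_of(age)
        if not (0 <= q <= 1):
            raise ConfigurationError("death probabilities must lie in [0, 1]")
        s_next = s * (1.0 - q)
        mid = 0.5 * (s + s_next)
        total += mid * u_of(age + 0.5) * (1.0 + discount_rate) ** (-(k + 0.5))
        s = s_next
        age += 1.0
        k += 1
    return float(total)


def qaly_shortfall(soc_qalys: float, subsequent_addition: float,
                   genpop_qalys: float,
                   thresholds: Optional[dict] = None) -> ShortfallResult:
    """Absolute and proportional QALY shortfall of standard care versus the
    matched general population, and the resulting severity weight.

    ``subsequent_addition`` is the QALY credit for treatment lines excluded
    from the partitioned survival model; it is added to the standard-care
    QALYs *before* the shortfall is computed (and nowhere else), so the
    modifier is not inflated by the model's deliberate exclusion of
    subsequent treatments.
    """
    if genpop_qalys <= 0:
        raise ConfigurationError("general-population QALYs must be positive")
    adjusted = soc_qalys + subsequent_addition
    if adjusted < 0:
        raise ConfigurationError("adjusted standard-care QALYs are negative")
    absolute = genpop_qalys - adjusted
    proportional = absolute / genpop_qalys
    th = thresholds or DEFAULT_SEVERITY_THRESHOLDS
    weight = 1.0
    t12, t17 = th["weight_1_2"], th["weight_1_7"]
    if proportional >= t12["proportional"] or absolute >= t12["absolute"]:
        weight = 1.2
    if proportional >= t17["proportional"] or absolute >= t17["absolute"]:
        weight = 1.7
    return ShortfallResult(genpop_qalys=float(genpop_qalys),
                           soc_qalys_adjusted=float(adjusted),
                           absolute_shortfall=float(absolute),
                           proportional_shortfall=float(proportional),
                           weight=weight)


def transfer_relative_icer(icer_anchor_first: Union[float, str],
                           icer_other_first: Union[float, str],
                           icer_anchor_second: Union[float, str]) -> float:
    """Transfer the first-line relative ICER to the second line: the inferred
    second-line ICER for the comparison without direct evidence equals
    anchor₂ × (other₁ / anchor₁). All inputs must be finite positive ICERs;
    dominance tags make the transfer undefined."""
    vals = (icer_anchor_first, icer_other_first, icer_anchor_second)
    for v in vals:
        if isinstance(v, str):
            raise TransferError(f"transfer undefined for ICER tag {v!r}")
        if not np.isfinite(v) or v <= 0:
            raise TransferError("transfer requires finite positive ICERs")
    return float(icer_anchor_second * (icer_other_first / icer_anchor_first))


# ---------------------------------------------------------------------------
# The assembled decision model: deterministic runs, scenarios, PSA
# ---------------------------------------------------------------------------

@dataclass
class DecisionModel:
    """Everything needed to run the appraisal deterministically or
    probabilistically: the base-case and sensitivity survival fits per arm
    and endpoint, treatment-duration inputs, utilities, costs and engine
    settings."""

    os_base: Dict[str, ParametricModel]
    pfs_base: Dict[str, ParametricModel]
    os_sens: Dict[str, ParametricModel]
    pfs_sens: Dict[str, ParametricModel]
    ttd: Dict[str, Union[float, object]]
    utilities: Dict[str, UtilitySpec]
    cost_specs: Dict[str, CostSpec]
    bodies: Optional[BodyMetricDistribution]
    cycle_length: float = 7.0 / 365.25
    horizon: float = 40.0
    discount_rate_qaly: float = 0.035
    discount_rate_cost: float = 0.035
    start_age: float = 60.0
    proportion_female: float = 0.40
    wtp_thresholds: Tuple[float, ...] = (20000.0, 30000.0)
    severity_weight: float = 1.0
    hr_scenario: Optional[Dict[str, float]] = None

    # -- plumbing -----------------------------------------------------------
    def _surv(self, model):
        return model.survival() if isinstance(model, ParametricModel) else model

    def _spec(self, arm: str, os_obj, pfs_obj) -> PartSASpec:
        return PartSASpec(
            os_model=self._surv(os_obj), pfs_model=self._surv(pfs_obj),
            cycle_length=self.cycle_length, horizon=self.horizon,
            discount_rate_qaly=self.discount_rate_qaly,
            discount_rate_cost=self.discount_rate_cost, ttd=self.ttd.get(arm),
            start_age=self.start_age, proportion_female=self.proportion_female)

    def _arm_costs(self, arm: str, statistic: Optional[str],
                   sharing: Optional[bool],
                   mult: Optional[Dict[str, float]] = None) -> ArmCosts:
        cs = self.cost_specs[arm]
        if statistic is not None:
            cs = replace(cs, price_statistic=statistic)
        cycle_items = regimen_cycle_cost(cs, self.bodies, self.cycle_length,
                                         sharing=sharing)
        m = mult or {}
        return ArmCosts(
            acquisition_per_cycle=cycle_items["acquisition_total"]
            * m.get("acquisition", 1.0),
            admin_monitoring_monthly=cs.admin_monitoring_monthly
            * m.get("admin", 1.0),
            state_cost_pf_monthly=cs.state_cost_pf_monthly * m.get("state", 1.0),
            state_cost_pd_monthly=cs.state_cost_pd_monthly * m.get("state", 1.0),
            terminal_cost=cs.terminal_cost * m.get("terminal", 1.0),
            ae_events=tuple((p, c * m.get("ae", 1.0)) for p, c in cs.ae_events))

    def run_deterministic(self, which: str = "base",
                          statistic: Optional[str] = None,
                          sharing: Optional[bool] = None,
                          surv_override: Optional[dict] = None,
                          utilities: Optional[Dict[str, UtilitySpec]] = None,
                          cost_mult: Optional[Dict[str, float]] = None,
                          severity_weight: Optional[float] = None) -> EconResult:
        """One full model evaluation. ``which`` selects base or sensitivity
        fits; ``surv_override`` maps (arm, endpoint) to a survival object."""
        os_src = self.os_base if which == "base" else self.os_sens
        pfs_src = self.pfs_base if which == "base" else self.pfs_sens
        ov = surv_override or {}
        specs = {}
        for arm in ARMS:
            os_obj = ov.get((arm, "OS"), os_src[arm])
            pfs_obj = ov.get((arm, "PFS"), pfs_src[arm])
            specs[arm] = self._spec(arm, os_obj, pfs_obj)
        utils = utilities or self.utilities
        comp = run_comparison(
            specs["intervention"], specs["comparator"],
            utils["intervention"], utils["comparator"],
            self._arm_costs("intervention", statistic, sharing, cost_mult),
            self._arm_costs("comparator", statistic, sharing, cost_mult))
        return icer(comp, self.wtp_thresholds,
                    severity_weight if severity_weight is not None
                    else self.severity_weight)

    # -- scenarios ----------------------------------------------------------
    def run_scenarios(self, names: Optional[Sequence[str]] = None) -> pd.DataFrame:
        """Deterministic scenario battery; base case first. A scenario that
        references an unavailable fit is skipped with a log row."""
        names = list(names) if names is not None else [
            "base", "alternative_distribution", "hazard_ratio",
            "weighted_median_price", "vial_sharing"]
        if "base" in names:
            names.remove("base")
        rows = [dict(scenario="base",
                     **self.run_deterministic("base").as_row())]
        for name in names:
            try:
                rows.append(dict(scenario=name, **self._scenario(name).as_row()))
            except (KeyError, ConfigurationError) as exc:
                rows.append(dict(scenario=name, skipped=str(exc)))
        return pd.DataFrame(rows)

    def _scenario(self, name: str) -> EconResult:
        if name == "alternative_distribution":
            return self.run_deterministic("sensitivity")
        if name == "hazard_ratio":
            if not self.hr_scenario:
                raise ConfigurationError("no hazard-ratio scenario configured")
            ov = {
                ("intervention", "OS"): apply_hazard_ratio(
                    self.os_base["comparator"], self.hr_scenario["os_hr"]),
                ("intervention", "PFS"): apply_hazard_ratio(
                    self.pfs_base["comparator"], self.hr_scenario["pfs_hr"]),
            }
            return self.run_deterministic("base", surv_override=ov)
        if name == "weighted_median_price":
            return self.run_deterministic("base", statistic="median")
        if name == "vial_sharing":
            return self.run_deterministic("base", sharing=True)
        raise ConfigurationError(f"unknown scenario {name!r}")

    # -- PSA ----------------------------------------------------------------
    def run_psa(self, n_draws: int, seed: int, se_fraction: float = 0.10,
                survival_vcov_scale: float = 1.0,
                sample_costs: bool = True,
                ceac_grid: Optional[np.ndarray] = None) -> "PSAResult":
        """Probabilistic sensitivity analysis.

        Survival parameters are drawn multivariate-normal on the transformed
        scale from each fit's covariance (scaled by
        ``survival_vcov_scale``; 0 freezes them); utilities are drawn Beta
        and cost multipliers Gamma by method of moments with standard errors
        of ``se_fraction`` × mean. Prices enter through the (fixed)
        acquisition cost unless cost sampling is on, in which case a common
        Gamma multiplier is applied per cost category.
        """
        if n_draws < 1:
            raise ConfigurationError("n_draws must be at least 1")
        rng = np.random.default_rng(seed)
        if ceac_grid is None:
            ceac_grid = np.arange(0.0, 50001.0, 1000.0)

        chol: Dict[Tuple[str, str], Optional[np.ndarray]] = {}
        fits = {("OS", a): self.os_base[a] for a in ARMS}
        fits.update({("PFS", a): self.pfs_base[a] for a in ARMS})
        for key, m in fits.items():
            if survival_vcov_scale > 0 and np.all(np.isfinite(m.vcov)):
                chol[key] = np.linalg.cholesky(
                    nearest_psd(m.vcov * survival_vcov_scale) +
                    1e-14 * np.eye(m.vcov.shape[0]))
            else:
                chol[key] = None

        draws = []
        for _ in range(n_draws):
            ov = {}
            for (ep, arm), m in fits.items():
                L = chol[(ep, arm)]
                if L is None:
                    continue
                theta = m.theta() + L @ rng.standard_normal(L.shape[0])
                ov[(arm, ep)] = m.with_theta(theta)
            utils = {arm: self._draw_utilities(self.utilities[arm], rng,
                                               se_fraction)
                     for arm in ARMS}
            mult = None
            if sample_costs and se_fraction > 0:
                mult = {k: _gamma_mult(rng, se_fraction)
                        for k in ("admin", "state", "terminal", "ae")}
            res = self.run_deterministic("base", surv_override=ov,
                                         utilities=utils, cost_mult=mult)
            draws.append((res.delta_cost, res.delta_qaly, res.delta_ly))
        arr = np.asarray(draws)
        det = self.run_deterministic("base")
        w = self.severity_weight
        ceac = np.array([(lam * w * arr[:, 1] - arr[:, 0] > 0).mean()
                         for lam in ceac_grid])
        return PSAResult(
            n_draws=n_draws, seed=seed,
            mean_delta_cost=float(arr[:, 0].mean()),
            mean_delta_qaly=float(arr[:, 1].mean()),
            mean_delta_ly=float(arr[:, 2].mean()),
            deterministic=det,
            ceac=pd.DataFrame({"threshold": ceac_grid,
                               "p_cost_effective": ceac}),
            draws=pd.DataFrame(arr, columns=["delta_cost", "delta_qaly",
                                             "delta_ly"]))

    @staticmethod
    def _draw_utilities(u: UtilitySpec, rng, se_fraction: float) -> UtilitySpec:
        if se_fraction <= 0:
            return u
        return UtilitySpec(
            u_pf=_beta_draw(rng, u.u_pf, se_fraction * u.u_pf),
            u_pd=_beta_draw(rng, u.u_pd, se_fraction * u.u_pd),
            age_index=u.age_index, ae_events=u.ae_events, enforce_order=False)


def _beta_draw(rng, mean: float, se: float) -> float:
    """Method-of-moments Beta draw; degenerate at the mean when se == 0 or
    the moments are infeasible."""
    if se <= 0 or mean <= 0 or mean >= 1:
        return float(np.clip(mean, 0.0, 1.0))
    var = min(se * se, mean * (1 - mean) * 0.99)
    nu = mean * (1 - mean) / var - 1.0
    return float(rng.beta(mean * nu, (1 - mean) * nu))


def _gamma_mult(rng, se_fraction: float) -> float:
    """Unit-mean Gamma multiplier with CV = se_fraction."""
    shape = 1.0 / se_fraction ** 2
    return float(rng.gamma(shape, 1.0 / shape))


@dataclass
class PSAResult:
    n_draws: int
    seed: int
    mean_delta_cost: float
    mean_delta_qaly: float
    mean_delta_ly: float
    deterministic: EconResult
    ceac: pd.DataFrame
    draws: pd.DataFrame
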