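"""Three-state partitioned survival engine.

State occupancy is read directly off the OS and PFS curves at each cycle
boundary: dead = 1 − S_OS(t), progression-free = min(S_PFS(t), S_OS(t)) (a
digitized or independently fitted PFS curve may cross OS and is clipped with
a warning count), progressed = the remainder. Life-years, QALYs and costs
accumulate per cycle with trapezoidal (half-cycle corrected) occupancies and
discrete discounting 1/(1+r)^t applied at cycle midpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Union

import numpy as np
import pandas as pd

from .datatypes import WEEKS_PER_YEAR


class ConfigurationError(ValueError):
    """Inconsistent engine configuration."""


SurvivalLike = object  # anything exposing .sf(t)
TTDInput = Union[object, float, None]  # survival object, fixed mean (years), or none


@dataclass
class PartSASpec:
    """Configuration of one arm of the partitioned survival model."""

    os_model: SurvivalLike
    pfs_model: SurvivalLike
    cycle_length: float = 7.0 / 365.25   # years (default one week)
    horizon: float = 40.0                # years
    discount_rate_qaly: float = 0.035
    discount_rate_cost: float = 0.035
    ttd: TTDInput = None
    start_age: float = 60.0
    proportion_female: float = 0.40

    def __post_init__(self):
        if not (0 < self.cycle_length <= self.horizon):
            raise ConfigurationError("cycle_length must be in (0, horizon]")
        for r in (self.discount_rate_qaly, self.discount_rate_cost):
            if not (0 <= r < 1):
                raise ConfigurationError("discount rates must be in [0, 1)")

    def grid_signature(self):
        return (round(self.cycle_length, 12), round(self.horizon, 12),
                self.discount_rate_qaly, self.discount_rate_cost)


@dataclass
class StateTrace:
    """Per-cycle-boundary occupancy of the three states plus treatment
    exposure; occupancies sum to one at every boundary."""

    times: np.ndarray
    pf: np.ndarray
    pd: np.ndarray
    dead: np.ndarray
    on_treatment: np.ndarray
    age: np.ndarray
    cycle_length: float
    clip_warnings: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times, "progression_free": self.pf,
            "progressed": self.pd, "dead": self.dead,
            "on_treatment": self.on_treatment, "age": self.age,
        })


def make_age_index(coeffs: Optional[Dict[str, float]], start_age: float,
                   proportion_female: float) -> Callable[[np.ndarray], np.ndarray]:
    """Multiplicative utility index over age, normalized to 1 at baseline.

    ``coeffs`` are quadratic utility-norm regression coefficients
    (intercept, female, age, age_squared) supplied by configuration; with no
    coefficients the index is identically 1.
    """
    if not coeffs:
        return lambda age: np.ones_like(np.asarray(age, float))
    c0 = coeffs.get("intercept", 1.0)
    cf = coeffs.get("female", 0.0)
    ca = coeffs.get("age", 0.0)
    c2 = coeffs.get("age_squared", 0.0)

    def norm(age):
        age = np.asarray(age, float)
        return c0 + cf * proportion_female + ca * age + c2 * age ** 2

    base = float(norm(start_age))
    if base <= 0:
        raise ConfigurationError("age-decrement norm non-positive at baseline age")

    def index(age):
        return np.clip(norm(age) / base, 0.0, 1.0)

    return index


@dataclass
class UtilitySpec:
    """Health-state utilities with an age decrement and adverse-event losses.

    ``ae_events`` is a list of (probability, QALY loss) pairs for this arm,
    applied once on model entry.
    """

    u_pf: float
    u_pd: float
    age_index: Optional[Callable] = None
    ae_events: tuple = ()
    enforce_order: bool = True

    def __post_init__(self):
        for u in (self.u_pf, self.u_pd):
            if not (0 <= u <= 1):
                raise ConfigurationError("utilities must lie in [0, 1]")
        if self.enforce_order and self.u_pd > self.u_pf + 1e-12:
            raise ConfigurationError(
                "progressed utility exceeds progression-free utility")

    @property
    def ae_expected_loss(self) -> float:
        return float(sum(p * d for p, d in self.ae_events))


@dataclass
class ArmCosts:
    """Per-arm cost inputs on the engine's native units (GBP; monthly costs
    are converted with 12 months/year)."""

    acquisition_per_cycle: float = 0.0   # while on treatment, per model cycle
    admin_monitoring_monthly: float = 0.0
    state_cost_pf_monthly: float = 0.0
    state_cost_pd_monthly: float = 0.0
    terminal_cost: float = 0.0
    ae_events: tuple = ()                # (probability, cost) pairs, once at entry

    @property
    def ae_expected_cost(self) -> float:
        return float(sum(p * c for p, c in self.ae_events))


def build_traces(spec: PartSASpec) -> StateTrace:
    """Evaluate state occupancy at every cycle boundary.

    PFS above OS (possible with independently fitted or digitized curves) is
    clipped to OS; the number of clipped boundaries is recorded, not raised.
    """
    n_cycles = int(np.floor(spec.horizon / spec.cycle_length + 1e-9))
    t = np.arange(n_cycles + 1) * spec.cycle_length
    s_os = np.clip(np.asarray(spec.os_model.sf(t), float), 0.0, 1.0)
    s_pfs = np.clip(np.asarray(spec.pfs_model.sf(t), float), 0.0, 1.0)
    s_os[0] = s_pfs[0] = 1.0
    # survival curves must be non-increasing; enforce against numeric noise
    s_os = np.minimum.accumulate(s_os)
    s_pfs = np.minimum.accumulate(s_pfs)
    clips = int(np.sum(s_pfs > s_os + 1e-12))
    pf = np.minimum(s_pfs, s_os)
    dead = 1.0 - s_os
    pd_ = s_os - pf

    if spec.ttd is None:
        on_trt = np.zeros_like(t)
    elif isinstance(spec.ttd, (int, float)):
        # fixed mean duration: full exposure of the progression-free cohort
        # until the mean duration, zero after
        on_trt = np.where(t < float(spec.ttd), pf, 0.0)
    else:
        s_ttd = np.clip(np.asarray(spec.ttd.sf(t), float), 0.0, 1.0)
        on_trt = np.minimum(s_ttd, pf)

    return StateTrace(times=t, pf=pf, pd=pd_, dead=dead, on_treatment=on_trt,
                      age=spec.start_age + t, cycle_length=spec.cycle_length,
                      clip_warnings=clips)


def _cycle_discount(times: np.ndarray, rate: float) -> np.ndarray:
    """Discount factors at cycle midpoints."""
    t_mid = 0.5 * (times[:-1] + times[1:])
    return (1.0 + rate) ** (-t_mid)


@dataclass
class QALYResult:
    qalys_discounted: float
    ly_discounted: float
    ly_undiscounted: float


def accumulate_qalys(trace: StateTrace, utilities: UtilitySpec,
                     discount_rate: float) -> QALYResult:
    """Discounted QALYs and (discounted/undiscounted) life-years for one arm.

    Per cycle the QALY increment is cycle_length × [PF·u_pf(age) +
    PD·u_pd(age)] × discount factor at the cycle midpoint, with trapezoidal
    occupancies; adverse-event disutilities apply once at entry.
    """
    dt = np.diff(trace.times)
    avg_pf = 0.5 * (trace.pf[:-1] + trace.pf[1:])
    avg_pd = 0.5 * (trace.pd[:-1] + trace.pd[1:])
    disc = _cycle_discount(trace.times, discount_rate)
    age_mid = 0.5 * (trace.age[:-1] + trace.age[1:])
    idx = utilities.age_index(age_mid) if utilities.age_index else 1.0
    q = float(np.sum(dt * (avg_pf * utilities.u_pf + avg_pd * utilities.u_pd)
                     * idx * disc))
    q -= utilities.ae_expected_loss
    ly_d = float(np.sum(dt * (avg_pf + avg_pd) * disc))
    ly_u = float(np.sum(dt * (avg_pf + avg_pd)))
    return QALYResult(qalys_discounted=q, ly_discounted=ly_d, ly_undiscounted=ly_u)


def accumulate_costs(trace: StateTrace, costs: ArmCosts,
                     discount_rate: float) -> Dict[str, float]:
    """Discounted costs for one arm, itemized.

    State costs follow occupancy; acquisition and administration/monitoring
    follow the on-treatment proportion; the terminal cost is applied to the
    new deaths of each cycle at that cycle's discount factor; adverse-event
    costs apply once at entry.
    """
    dt = np.diff(trace.times)
    months = dt * 12.0
    avg_pf = 0.5 * (trace.pf[:-1] + trace.pf[1:])
    avg_pd = 0.5 * (trace.pd[:-1] + trace.pd[1:])
    avg_trt = 0.5 * (trace.on_treatment[:-1] + trace.on_treatment[1:])
    disc = _cycle_discount(trace.times, discount_rate)
    new_deaths = np.diff(trace.dead)

    items = {
        "state": float(np.sum(months * (avg_pf * costs.state_cost_pf_monthly
                                        + avg_pd * costs.state_cost_pd_monthly)
                              * disc)),
        "acquisition": float(np.sum(avg_trt * costs.acquisition_per_cycle * disc)),
        "admin_monitoring": float(np.sum(
            avg_trt * costs.admin_monitoring_monthly * months * disc)),
        "terminal": float(np.sum(new_deaths * costs.terminal_cost * disc)),
        "ae": costs.ae_expected_cost,
    }
    items["total"] = float(sum(items.values()))
    return items


@dataclass
class ArmOutcome:
    arm: str
    ly_discounted: float
    ly_undiscounted: float
    qalys_discounted: float
    costs: Dict[str, float]
    clip_warnings: int = 0

    @property
    def cost_total(self) -> float:
        return self.costs["total"]


@dataclass
class ComparisonResult:
    """Per-arm outcomes and increments (intervention − comparator), with
    subsequent-treatment costs and QALYs excluded by construction."""

    intervention: ArmOutcome
    comparator: ArmOutcome

    @property
    def delta_ly(self) -> float:
        return self.intervention.ly_undiscounted - self.comparator.ly_undiscounted

    @property
    def delta_ly_discounted(self) -> float:
        return self.intervention.ly_discounted - self.comparator.ly_discounted

    @property
    def delta_qaly(self) -> float:
        return self.intervention.qalys_discounted - self.comparator.qalys_discounted

    @property
    def delta_cost(self) -> float:
        return self.intervention.cost_total - self.comparator.cost_total


def run_arm(spec: PartSASpec, utilities: UtilitySpec, costs: ArmCosts,
            arm: str = "arm") -> ArmOutcome:
    trace = build_traces(spec)
    q = accumulate_qalys(trace, utilities, spec.discount_rate_qaly)
    c = accumulate_costs(trace, costs, spec.discount_rate_cost)
    return ArmOutcome(arm=arm, ly_discounted=q.ly_discounted,
                      ly_undiscounted=q.ly_undiscounted,
                      qalys_discounted=q.qalys_discounted, costs=c,
                      clip_warnings=trace.clip_warnings)


def run_comparison(spec_intervention: PartSASpec, spec_comparator: PartSASpec,
                   utilities_intervention: UtilitySpec,
                   utilities_comparator: UtilitySpec,
                   costs_intervention: ArmCosts,
                   costs_comparator: ArmCosts) -> ComparisonResult:
    """Run both arms on a shared cycle structure and report increments."""
    if spec_intervention.grid_signature() != spec_comparator.grid_signature():
        raise ConfigurationError(
            "arms must share cycle length, horizon and discount rates")
    return ComparisonResult(
        intervention=run_arm(spec_intervention, utilities_intervention,
                             costs_intervention, "intervention"),
        comparator=run_arm(spec_comparator, utilities_comparator,
                           costs_comparator, "comparator"))
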