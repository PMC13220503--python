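"""Drug acquisition costing.

Weight- or body-surface-area-based doses are converted to an expected cost
per administration by integrating over the cohort's body-metric
distribution on a deterministic quantile grid; without vial sharing the cost
of a draw is the cheapest whole-vial combination covering the required
milligrams (exact enumeration), with sharing it is the per-mg price of the
cheapest vial. Tender prices across suppliers are summarised by their
market-share-weighted mean (base case) or weighted median (sensitivity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .partsa import ConfigurationError

DOSE_RULES = ("per_kg", "per_bsa", "flat")


@dataclass(frozen=True)
class VialOption:
    size_mg: float
    price_gbp: float

    def __post_init__(self):
        if self.size_mg <= 0 or self.price_gbp < 0:
            raise ConfigurationError("vial sizes must be positive, prices >= 0")


@dataclass(frozen=True)
class DoseRule:
    """How a regimen component is dosed: mg per kg, mg per m², or flat mg,
    administered every ``interval_weeks``."""

    kind: str
    dose: float              # mg per unit of metric (or total mg if flat)
    interval_weeks: float

    def __post_init__(self):
        if self.kind not in DOSE_RULES:
            raise ConfigurationError(f"dose rule must be one of {DOSE_RULES}")
        if self.dose <= 0 or self.interval_weeks <= 0:
            raise ConfigurationError("dose and interval must be positive")


@dataclass(frozen=True)
class BodyMetricDistribution:
    """Log-normal body weight (kg) and BSA (m²) by sex, with the cohort sex
    mix; expectations use a fixed quantile grid per sex for determinism."""

    weight_meanlog: Tuple[float, float]   # (female, male)
    weight_sdlog: Tuple[float, float]
    bsa_meanlog: Tuple[float, float]
    bsa_sdlog: Tuple[float, float]
    proportion_female: float = 0.5
    n_quantiles: int = 199

    def __post_init__(self):
        if not (0 <= self.proportion_female <= 1):
            raise ConfigurationError("sex mix must lie in [0, 1]")

    def grid(self, metric: str) -> Tuple[np.ndarray, np.ndarray]:
        """(values, probability weights) over both sexes."""
        if metric == "weight":
            mean, sd = self.weight_meanlog, self.weight_sdlog
        elif metric == "bsa":
            mean, sd = self.bsa_meanlog, self.bsa_sdlog
        else:
            raise ConfigurationError(f"unknown body metric {metric!r}")
        q = (np.arange(self.n_quantiles) + 0.5) / self.n_quantiles
        vals, wts = [], []
        for sex_w, mu, sg in zip(
                (self.proportion_female, 1.0 - self.proportion_female), mean, sd):
            if sex_w <= 0:
                continue
            vals.append(np.exp(mu + sg * stats.norm.ppf(q)))
            wts.append(np.full(q.size, sex_w / self.n_quantiles))
        return np.concatenate(vals), np.concatenate(wts)


def weighted_price(tender_prices: Sequence[Tuple[float, float]],
                   statistic: str = "mean") -> float:
    """Market-share-weighted mean or median of tender prices.

    The weighted median is the smallest price whose cumulative market share
    (ascending in price) reaches 0.5.
    """
    if not len(tender_prices):
        raise ConfigurationError("tender price list is empty")
    prices = np.array([p for p, _ in tender_prices], float)
    shares = np.array([s for _, s in tender_prices], float)
    if np.any(shares < 0) or abs(shares.sum() - 1.0) > 1e-9:
        raise ConfigurationError("tender market shares must sum to 1")
    if statistic == "mean":
        return float(np.sum(prices * shares))
    if statistic == "median":
        order = np.argsort(prices, kind="stable")
        cum = np.cumsum(shares[order])
        return float(prices[order][np.searchsorted(cum, 0.5 - 1e-12)])
    raise ConfigurationError("statistic must be 'mean' or 'median'")


def min_vial_cost(required_mg: float,
                  vials: Sequence[VialOption]) -> Tuple[float, Tuple[int, ...]]:
    """Cheapest whole-vial combination with total contents >= required_mg.

    Exact enumeration with branch-and-bound pruning; the objective is cost
    minimisation (not waste minimisation).
    """
    if not vials:
        raise ConfigurationError("at least one vial option is required")
    if required_mg <= 0:
        return 0.0, tuple(0 for _ in vials)
    sizes = np.array([v.size_mg for v in vials])
    prices = np.array([v.price_gbp for v in vials])
    n = len(vials)
    best = [np.inf, None]
    min_ppm = float(np.min(prices / sizes))

    def recurse(idx, remaining, cost, counts):
        if cost >= best[0]:
            return
        if remaining <= 1e-9:
            best[0], best[1] = cost, tuple(counts)
            return
        if idx == n:
            return
        # lower bound: remaining mg at the best per-mg rate
        if cost + remaining * min_ppm >= best[0]:
            return
        max_ct = int(np.ceil(remaining / sizes[idx]))
        for ct in range(max_ct, -1, -1):
            counts[idx] = ct
            recurse(idx + 1, remaining - ct * sizes[idx], cost + ct * prices[idx],
                    counts)
        counts[idx] = 0

    recurse(0, float(required_mg), 0.0, [0] * n)
    return float(best[0]), best[1]


def sharing_cost(required_mg: float, vials: Sequence[VialOption]) -> float:
    """With vial sharing, drug is charged per mg at the cheapest per-mg rate."""
    if not vials:
        raise ConfigurationError("at least one vial option is required")
    ppm = min(v.price_gbp / v.size_mg for v in vials)
    return float(max(required_mg, 0.0) * ppm)


@dataclass
class VialCostResult:
    expected_cost: float                       # GBP per administration
    vial_count_distribution: pd.DataFrame      # columns: total_vials, probability


def expected_vial_cost(dose_rule: DoseRule, bodies: Optional[BodyMetricDistribution],
                       rdi: float, vial_options: Sequence[VialOption],
                       sharing: bool = False) -> VialCostResult:
    """Expected acquisition cost of one administration, integrating the
    required dose over the body-metric distribution.

    Required mg per draw = dose × body metric × relative dose intensity
    (flat dosing ignores body metrics entirely).
    """
    if not (0 < rdi <= 1):
        raise ConfigurationError("relative dose intensity must be in (0, 1]")
    if not vial_options:
        raise ConfigurationError("at least one vial option is required")
    if dose_rule.kind == "flat":
        values, weights = np.array([1.0]), np.array([1.0])
        req = np.array([dose_rule.dose * rdi])
    else:
        if bodies is None:
            raise ConfigurationError("body-metric distribution required for "
                                     f"{dose_rule.kind} dosing")
        metric = "weight" if dose_rule.kind == "per_kg" else "bsa"
        values, weights = bodies.grid(metric)
        req = dose_rule.dose * values * rdi

    if sharing:
        costs = np.array([sharing_cost(r, vial_options) for r in req])
        counts = np.zeros(req.size, int)  # fractional vials; not tabulated
    else:
        out = [min_vial_cost(r, vial_options) for r in req]
        costs = np.array([c for c, _ in out])
        counts = np.array([sum(ct) for _, ct in out])

    dist = (pd.DataFrame({"total_vials": counts, "probability": weights})
            .groupby("total_vials", as_index=False)["probability"].sum())
    return VialCostResult(expected_cost=float(np.sum(costs * weights)),
                          vial_count_distribution=dist)


@dataclass
class RegimenComponent:
    name: str
    dose_rule: DoseRule
    rdi: float
    vial_options: Tuple[VialOption, ...]


@dataclass
class CostSpec:
    """Everything needed to cost an arm: the drug regimen, tender prices,
    administration/monitoring, state, terminal and adverse-event costs."""

    components: Tuple[RegimenComponent, ...] = ()
    tender_prices: Tuple[Tuple[float, float], ...] = ()
    price_statistic: str = "mean"
    admin_monitoring_monthly: float = 0.0
    state_cost_pf_monthly: float = 0.0
    state_cost_pd_monthly: float = 0.0
    terminal_cost: float = 0.0
    ae_events: Tuple[Tuple[float, float], ...] = ()
    vial_sharing: bool = False


def scaled_vials(component: RegimenComponent, cost_spec: CostSpec
                 ) -> Tuple[VialOption, ...]:
    """Apply the tender-price statistic to the component's vial menu: every
    vial price is scaled by the ratio of the weighted tender price to the
    menu's reference (first-listed) vial price."""
    if not cost_spec.tender_prices:
        return component.vial_options
    ref = component.vial_options[0].price_gbp
    if ref <= 0:
        return component.vial_options
    mult = weighted_price(cost_spec.tender_prices, cost_spec.price_statistic) / ref
    return tuple(VialOption(v.size_mg, v.price_gbp * mult)
                 for v in component.vial_options)


def regimen_cycle_cost(cost_spec: CostSpec, bodies: Optional[BodyMetricDistribution],
                       cycle_length_years: float,
                       sharing: Optional[bool] = None) -> Dict[str, float]:
    """Acquisition cost per model cycle while on treatment, itemized by
    regimen component, plus the prorated administration/monitoring cost."""
    if sharing is None:
        sharing = cost_spec.vial_sharing
    items: Dict[str, float] = {}
    weeks_per_cycle = cycle_length_years * 52.0
    for comp in cost_spec.components:
        per_admin = expected_vial_cost(
            comp.dose_rule, bodies, comp.rdi,
            scaled_vials(comp, cost_spec), sharing=sharing).expected_cost
        admins_per_cycle = weeks_per_cycle / comp.dose_rule.interval_weeks
        items[comp.name] = per_admin * admins_per_cycle
    items["admin_monitoring"] = (cost_spec.admin_monitoring_monthly
                                 * 12.0 * cycle_length_years)
    items["acquisition_total"] = float(
        sum(v for k, v in items.items() if k != "admin_monitoring"))
    return items
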