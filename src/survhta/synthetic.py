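"""Synthetic two-arm trial generator and figure-digitization emulator.

The pipeline's real-world inputs are digitized Kaplan-Meier figures from
trial publications; those figures (and the tender prices) are confidential
or external. This module generates two-arm trials with known ground truth —
proportional or crossing hazards, administrative plus random dropout
censoring — and simulates the digitization step (coordinate grid + numbers-
at-risk table), so every pipeline stage runs end to end with no download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .datatypes import DigitizedCurve, SurvivalDataset
from .distributions import Family, ParameterError, get_family
from .km import km_estimate


class ConsistencyError(ValueError):
    """Endpoint marginals incompatible (PFS survival above OS survival)."""


@dataclass(frozen=True)
class TrueArmModel:
    """Ground-truth event-time distribution for one arm/endpoint."""

    family: str
    params: Dict[str, float]
    label: str = "arm"

    def _dist(self):
        fam = get_family(self.family)
        return fam, fam.validate(self.params)

    def sf(self, t):
        fam, vec = self._dist()
        return fam.sf(t, vec)

    def isf(self, u):
        fam, vec = self._dist()
        return fam.isf(u, vec)

    def mean(self, horizon: float = 200.0) -> float:
        from .fitting import restricted_mean
        return restricted_mean(self, horizon)


@dataclass(frozen=True)
class CensoringSpec:
    """Administrative cutoff plus exponential random dropout (per year)."""

    admin_time: float
    dropout_rate: float = 0.0

    def __post_init__(self):
        if not (self.admin_time > 0):
            raise ParameterError("admin_time must be positive")
        if self.dropout_rate < 0:
            raise ParameterError("dropout_rate must be non-negative")


def _event_times_from_uniform(model: TrueArmModel, u: np.ndarray) -> np.ndarray:
    """Inverse-transform sampling: t = S^{-1}(u). Improper survival mass
    (negative-shape Gompertz plateau) maps to +inf and is later absorbed by
    administrative censoring."""
    return np.asarray(model.isf(u), float)


def simulate_arm(model: TrueArmModel, censoring: CensoringSpec, n: int,
                 seed: int, endpoint: str = "OS") -> SurvivalDataset:
    """Simulate one right-censored arm.

    Recorded time is min(event, dropout, admin cutoff); the event flag is 1
    iff the event time is the minimum. Identical seeds reproduce identical
    datasets.
    """
    if n < 1:
        raise ParameterError("n must be at least 1")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n)
    t_event = _event_times_from_uniform(model, u)
    if censoring.dropout_rate > 0:
        t_drop = rng.exponential(1.0 / censoring.dropout_rate, size=n)
    else:
        t_drop = np.full(n, np.inf)
    t_cens = np.minimum(t_drop, censoring.admin_time)
    times = np.minimum(t_event, t_cens)
    events = (t_event <= t_cens).astype(int)
    times = np.clip(times, 1e-12, None)
    return SurvivalDataset(times, events, arm=model.label, endpoint=endpoint)


def simulate_linked_endpoints(os_model: TrueArmModel, pfs_model: TrueArmModel,
                              censoring: CensoringSpec, n: int, seed: int,
                              n_check: int = 201
                              ) -> Tuple[SurvivalDataset, SurvivalDataset]:
    """Simulate per-subject (OS, PFS) pairs with PFS ≤ OS guaranteed.

    A common uniform draw per subject (comonotone coupling) yields ordered
    event times whenever the marginal survival functions are ordered; the
    marginals are validated numerically on a grid over [0, admin_time] and a
    crossing raises :class:`ConsistencyError`. Censoring (dropout draw and
    administrative cutoff) is shared per subject.
    """
    grid = np.linspace(0.0, censoring.admin_time, n_check)
    s_os = np.asarray(os_model.sf(grid), float)
    s_pfs = np.asarray(pfs_model.sf(grid), float)
    bad = s_pfs > s_os + 1e-9
    if bad.any():
        t_bad = grid[bad][0]
        raise ConsistencyError(
            f"PFS survival exceeds OS survival at t={t_bad:.4g} "
            f"({s_pfs[bad][0]:.4f} > {s_os[bad][0]:.4f})")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n)
    t_os = _event_times_from_uniform(os_model, u)
    t_pfs = np.minimum(_event_times_from_uniform(pfs_model, u), t_os)
    if censoring.dropout_rate > 0:
        t_drop = rng.exponential(1.0 / censoring.dropout_rate, size=n)
    else:
        t_drop = np.full(n, np.inf)
    t_cens = np.minimum(t_drop, censoring.admin_time)

    def pack(t_ev, endpoint):
        times = np.clip(np.minimum(t_ev, t_cens), 1e-12, None)
        events = (t_ev <= t_cens).astype(int)
        return SurvivalDataset(times, events, arm=os_model.label, endpoint=endpoint)

    return pack(t_os, "OS"), pack(t_pfs, "PFS")


def digitize(dataset: SurvivalDataset, grid_points: int = 100,
             risk_table_interval: float = 0.5, jitter: float = 0.0,
             seed: Optional[int] = None,
             include_total_events: bool = True) -> DigitizedCurve:
    """Emulate figure digitization of a KM curve.

    The KM estimate is sampled at ``grid_points`` regular grid times, so the
    survival value at every grid time is exact and drop locations are
    preserved to grid resolution (a drop between two grid times lands on the
    later one). Numbers at risk are reported at multiples of
    ``risk_table_interval``. Optional uniform jitter on the survival
    coordinates emulates digitization error; a running-minimum isotonic
    correction restores monotonicity afterwards.
    """
    if grid_points < 2:
        raise ParameterError("grid_points must be at least 2")
    if risk_table_interval <= 0:
        raise ParameterError("risk_table_interval must be positive")
    kmres = km_estimate(dataset)
    t_max = float(dataset.times.max())
    grid = np.linspace(0.0, t_max, grid_points)
    surv = np.asarray(kmres.sf(grid), float)
    surv[0] = 1.0
    if jitter > 0:
        rng = np.random.default_rng(seed)
        surv = surv + rng.uniform(-jitter, jitter, size=surv.size)
        surv[0] = 1.0
        surv = np.minimum.accumulate(np.clip(surv, 0.0, 1.0))
    risk_times = np.arange(0.0, t_max + 1e-12, risk_table_interval)
    if risk_times[-1] >= t_max:
        risk_times = risk_times[risk_times < t_max]
    if risk_times.size == 0:
        risk_times = np.array([0.0])
    n_risk = (dataset.times[None, :] > risk_times[:, None]).sum(axis=1)
    # trim trailing zero-at-risk rows except the first entry
    keep = (n_risk > 0) | (risk_times == 0.0)
    risk_times, n_risk = risk_times[keep], n_risk[keep]
    n_risk[risk_times == 0.0] = dataset.n  # t=0 reports the full sample
    total = dataset.n_events if include_total_events else None
    return DigitizedCurve(grid, surv, risk_times, n_risk, total_events=total,
                          arm=dataset.arm, endpoint=dataset.endpoint)


# ---------------------------------------------------------------------------
# Reference scenario
# ---------------------------------------------------------------------------

#: Ground truth of the shipped reference scenario: a first-line-like two-arm
#: trial. Weibull marginals with a common shape so the comparator/intervention
#: and OS/PFS pairs are proportional-hazards ordered; medians are in the range
#: typical of metastatic colorectal cancer (OS ≈ 20 months, PFS ≈ 9 months)
#: and the intervention effect mirrors reported first-line hazard ratios
#: (OS HR 0.8, PFS HR 0.66).
REFERENCE_TRUTH = {
    "os_hr": 0.80,
    "pfs_hr": 0.66,
    "weibull_shape": 1.3,
    "os_scale_comparator": 2.2,    # years
    "pfs_scale_comparator": 1.0,   # years
    "n_per_arm": 400,
    "admin_time": 3.0,             # years of trial follow-up
    "dropout_rate": 0.05,          # per year
}


@dataclass
class ReferenceScenario:
    """A complete runnable configuration plus its simulated evidence."""

    datasets: Dict[Tuple[str, str], SurvivalDataset]
    true_models: Dict[Tuple[str, str], TrueArmModel]
    config: dict
    seed: int


def make_reference_scenario(seed: int = 0) -> ReferenceScenario:
    """Two-arm OS/PFS evidence with hazard ratio < 1 favouring the
    intervention, plus a fully populated economic configuration.

    Utilities (0.77 / 0.68), state costs (£133 / £273 per month), terminal
    cost (£6,265) and fixed treatment durations (5 and 4 months) use the
    published non-confidential appraisal inputs; tender prices and vial
    menus are synthetic stand-ins for the confidential ones.
    """
    tr = REFERENCE_TRUTH
    shape = tr["weibull_shape"]
    cens = CensoringSpec(admin_time=tr["admin_time"],
                         dropout_rate=tr["dropout_rate"])

    def wb(scale, label):
        return TrueArmModel("weibull", {"shape": shape, "scale": scale}, label)

    # PH on a Weibull with common shape k: S^hr is Weibull with scale·hr^(-1/k)
    os_c = wb(tr["os_scale_comparator"], "comparator")
    pfs_c = wb(tr["pfs_scale_comparator"], "comparator")
    os_i = wb(tr["os_scale_comparator"] * tr["os_hr"] ** (-1.0 / shape),
              "intervention")
    pfs_i = wb(tr["pfs_scale_comparator"] * tr["pfs_hr"] ** (-1.0 / shape),
               "intervention")

    n = tr["n_per_arm"]
    seed = int(seed)
    os_c_data, pfs_c_data = simulate_linked_endpoints(os_c, pfs_c, cens, n,
                                                      seed=seed * 2 + 11)
    os_i_data, pfs_i_data = simulate_linked_endpoints(os_i, pfs_i, cens, n,
                                                      seed=seed * 2 + 12)
    datasets = {
        ("comparator", "OS"): os_c_data, ("comparator", "PFS"): pfs_c_data,
        ("intervention", "OS"): os_i_data, ("intervention", "PFS"): pfs_i_data,
    }
    true_models = {
        ("comparator", "OS"): os_c, ("comparator", "PFS"): pfs_c,
        ("intervention", "OS"): os_i, ("intervention", "PFS"): pfs_i,
    }

    config = {
        "seed": seed,
        "cohort": {"start_age": 60.0, "proportion_female": 0.40},
        "engine": {
            "cycle_length_weeks": 1.0,
            "horizon_years": 40.0,
            "discount_rate_qaly": 0.035,
            "discount_rate_cost": 0.035,
        },
        "fit_policy": {
            "clinical_shape": "increasing",
            "criterion": "aic",
            "same_family_across_arms": True,
        },
        "utilities": {
            "progression_free": 0.77,
            "progressed": 0.68,
            "age_decrement": {
                # quadratic utility norm in age; index normalized at baseline
                "intercept": 0.9508566, "female": -0.0212126,
                "age": -0.0002587, "age_squared": -0.0000332,
            },
            "ae_disutility_intervention": 0.012,
            "ae_disutility_comparator": 0.008,
        },
        "costs": {
            "currency_year": "GBP-2024",
            "state_cost_pf_monthly": 133.0,
            "state_cost_pd_monthly": 273.0,
            "terminal_cost": 6265.0,
            "admin_monitoring_monthly": {
                "intervention": 1527.0,  # extra pharmacy/nursing resource
                "comparator": 819.0,
            },
            "ae_cost_intervention": 420.0,
            "ae_cost_comparator": 260.0,
        },
        "treatment": {
            # fixed mean durations (months): the second-line convention
            "ttd_mean_months": {"intervention": 5.0, "comparator": 4.0},
            "drug": {
                "name": "bevacizumab-biosimilar",
                "dose_rule": "per_kg",
                "dose_mg": 5.0,
                "admin_interval_weeks": 2.0,
                "relative_dose_intensity": 0.88,
                "vial_options": [
                    {"size_mg": 100.0, "price_gbp": 55.0},
                    {"size_mg": 400.0, "price_gbp": 200.0},
                ],
                "arms": ["intervention"],
            },
            "vial_sharing": False,
        },
        "prices": {
            # synthetic tender prices per 100 mg equivalent with market shares
            "tender": [
                {"price_gbp": 70.0, "market_share": 0.15},
                {"price_gbp": 55.0, "market_share": 0.40},
                {"price_gbp": 48.0, "market_share": 0.30},
                {"price_gbp": 40.0, "market_share": 0.15},
            ],
            "statistic": "mean",
        },
        "bodies": {
            "weight_kg": {"dist": "lognormal", "meanlog_female": 4.20,
                          "sdlog_female": 0.18, "meanlog_male": 4.38,
                          "sdlog_male": 0.16},
            "bsa_m2": {"dist": "lognormal", "meanlog_female": 0.56,
                       "sdlog_female": 0.09, "meanlog_male": 0.66,
                       "sdlog_male": 0.08},
            "n_quantiles": 199,
        },
        "severity": {
            "subsequent_qaly_addition": 1.2,
            "thresholds": {
                "weight_1_2": {"proportional": 0.85, "absolute": 12.0},
                "weight_1_7": {"proportional": 0.95, "absolute": 18.0},
            },
            "utility_norm": 0.80,
            "life_table": {"constant_annual_death_prob": 0.025},
        },
        "econ": {
            "wtp_thresholds": [20000.0, 30000.0],
            "severity_weight": 1.0,
            "ceac_grid_max": 50000.0,
            "ceac_grid_step": 1000.0,
        },
        "scenarios": ["base", "alternative_distribution", "hazard_ratio",
                      "weighted_median_price", "vial_sharing"],
        "hr_scenario": {"os_hr": 0.75, "pfs_hr": 0.61},  # E3200 meta-analysis values
        "psa": {"n_draws": 500, "se_fraction": 0.10,
                "sample_ttd": True, "sample_price": False},
    }
    return ReferenceScenario(datasets=datasets, true_models=true_models,
                             config=config, seed=seed)
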