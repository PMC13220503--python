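"""Pipeline configuration: a nested YAML file validated against a schema.

Unknown keys are rejected (catching typos early), referenced files must
exist, and month-denominated inputs are normalized to years on load
(months / 12). Money is GBP tagged with a currency-year string.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Any, Dict, Optional

import yaml

from .partsa import ConfigurationError

MONTHS_PER_YEAR = 12.0

# schema: nested dict of allowed keys; None marks a free-form leaf,
# dict recurses, "*" allows arbitrary child keys under a validated subtree
_SCHEMA: Dict[str, Any] = {
    "seed": None,
    "evidence": {"ipd": None, "digitized": None},
    "cohort": {"start_age": None, "proportion_female": None},
    "engine": {"cycle_length_weeks": None, "horizon_years": None,
               "discount_rate_qaly": None, "discount_rate_cost": None},
    "fit_policy": {"clinical_shape": None, "criterion": None,
                   "same_family_across_arms": None},
    "utilities": {"progression_free": None, "progressed": None,
                  "age_decrement": {"intercept": None, "female": None,
                                    "age": None, "age_squared": None},
                  "ae_disutility_intervention": None,
                  "ae_disutility_comparator": None},
    "costs": {"currency_year": None, "state_cost_pf_monthly": None,
              "state_cost_pd_monthly": None, "terminal_cost": None,
              "admin_monitoring_monthly": {"intervention": None,
                                           "comparator": None},
              "ae_cost_intervention": None, "ae_cost_comparator": None},
    "treatment": {"ttd_mean_months": {"intervention": None, "comparator": None},
                  "ttd_from_km": None,
                  "drug": {"name": None, "dose_rule": None, "dose_mg": None,
                           "admin_interval_weeks": None,
                           "relative_dose_intensity": None,
                           "vial_options": None, "arms": None},
                  "vial_sharing": None},
    "prices": {"tender": None, "statistic": None},
    "bodies": {"weight_kg": None, "bsa_m2": None, "n_quantiles": None},
    "severity": {"subsequent_qaly_addition": None, "thresholds": None,
                 "utility_norm": None, "life_table": None},
    "econ": {"wtp_thresholds": None, "severity_weight": None,
             "ceac_grid_max": None, "ceac_grid_step": None},
    "scenarios": None,
    "hr_scenario": {"os_hr": None, "pfs_hr": None},
    "psa": {"n_draws": None, "se_fraction": None, "sample_ttd": None,
            "sample_price": None, "survival_vcov_scale": None},
}


def _check_keys(node: Any, schema: Any, path: str = "") -> None:
    if schema is None or not isinstance(node, dict):
        return
    for key, val in node.items():
        where = f"{path}.{key}" if path else key
        if key not in schema:
            raise ConfigurationError(f"unknown configuration key: {where}")
        _check_keys(val, schema[key], where)


def validate_config(cfg: Dict[str, Any], base_dir: Optional[Path] = None
                    ) -> Dict[str, Any]:
    """Validate a configuration dict in place and return it.

    Checks the key schema, basic value constraints (rates, utilities,
    shares), and that every referenced evidence file exists.
    """
    _check_keys(cfg, _SCHEMA)

    eng = cfg.get("engine", {})
    for key in ("discount_rate_qaly", "discount_rate_cost"):
        r = eng.get(key, 0.035)
        if not (0 <= r < 1):
            raise ConfigurationError(f"engine.{key} must lie in [0, 1)")
    if eng.get("horizon_years", 40.0) <= 0:
        raise ConfigurationError("engine.horizon_years must be positive")
    if eng.get("cycle_length_weeks", 1.0) <= 0:
        raise ConfigurationError("engine.cycle_length_weeks must be positive")

    utils = cfg.get("utilities", {})
    for key in ("progression_free", "progressed"):
        if key in utils and not (0 <= utils[key] <= 1):
            raise ConfigurationError(f"utilities.{key} must lie in [0, 1]")

    tender = cfg.get("prices", {}).get("tender")
    if tender:
        total = sum(t["market_share"] for t in tender)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"prices.tender market shares sum to {total:.6g}, not 1")

    drug = cfg.get("treatment", {}).get("drug")
    if drug:
        rdi = drug.get("relative_dose_intensity", 1.0)
        if not (0 < rdi <= 1):
            raise ConfigurationError(
                "treatment.drug.relative_dose_intensity must be in (0, 1]")

    ev = cfg.get("evidence", {})
    base = Path(base_dir) if base_dir else Path(".")
    if "ipd" in ev and ev["ipd"]:
        p = base / ev["ipd"]
        if not p.exists():
            raise ConfigurationError(f"evidence.ipd file not found: {p}")
    for entry in ev.get("digitized") or []:
        for key in ("coords", "risk_table"):
            p = base / entry[key]
            if not p.exists():
                raise ConfigurationError(f"digitized evidence file not found: {p}")
    return cfg


def load_config(path) -> Dict[str, Any]:
    """Load and validate a YAML pipeline configuration."""
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{path} does not contain a mapping")
    return validate_config(cfg, base_dir=path.parent)


def save_config(cfg: Dict[str, Any], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def config_hash(cfg: Dict[str, Any]) -> str:
    """Stable hash of a configuration for provenance stamping."""
    canon = yaml.safe_dump(cfg, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def ttd_years(cfg: Dict[str, Any], arm: str):
    months = cfg.get("treatment", {}).get("ttd_mean_months", {})
    if arm in months:
        return float(months[arm]) / MONTHS_PER_YEAR
    return None
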