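"""End-to-end pipeline: evidence → reconstruction → fits → family selection →
partitioned survival model → costing → economics → scenarios → PSA, with every
artifact written to a run directory stamped with the configuration hash."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from . import config as cfgmod
from .costing import (BodyMetricDistribution, CostSpec, DoseRule,
                      RegimenComponent, VialOption)
from .datatypes import SurvivalDataset
from .econ import (ARMS, DecisionModel, EconResult, general_population_qalys,
                   qaly_shortfall)
from .fitting import ModelRanking, fit_all, select_family_joint
from .io import read_curve, read_ipd
from .km import km_estimate, reconstruct_ipd
from .partsa import ConfigurationError, UtilitySpec, build_traces, make_age_index


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is attached."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_evidence(config: dict, base_dir: Optional[Path] = None
                  ) -> Dict[Tuple[str, str], SurvivalDataset]:
    """Read raw IPD and/or reconstruct digitized curves per the config.

    Digitized inputs are reconstructed to pseudo-IPD; raw IPD is used as-is
    (reconstruction is skipped when only raw IPD is supplied).
    """
    base = Path(base_dir) if base_dir else Path(".")
    ev = config.get("evidence", {})
    datasets: Dict[Tuple[str, str], SurvivalDataset] = {}
    if ev.get("ipd"):
        datasets.update(read_ipd(base / ev["ipd"]))
    for entry in ev.get("digitized") or []:
        curve = read_curve(base / entry["coords"], base / entry["risk_table"],
                           total_events=entry.get("total_events"),
                           arm=entry["arm"], endpoint=entry["endpoint"])
        datasets[(entry["arm"], entry["endpoint"])] = reconstruct_ipd(curve)
    if not datasets:
        raise ConfigurationError("no evidence inputs configured")
    return datasets


def fit_evidence(config: dict,
                 datasets: Dict[Tuple[str, str], SurvivalDataset]
                 ) -> Dict[Tuple[str, str], ModelRanking]:
    policy = config.get("fit_policy", {})
    shape = policy.get("clinical_shape", "increasing")
    criterion = policy.get("criterion", "aic")
    horizon = config.get("engine", {}).get("horizon_years", 40.0)
    out = {}
    for (arm, ep), data in datasets.items():
        if ep in ("OS", "PFS"):
            out[(arm, ep)] = fit_all(data, clinical_shape=shape,
                                     horizon=horizon, criterion=criterion)
    return out


def _select_families(config: dict,
                     rankings: Dict[Tuple[str, str], ModelRanking]
                     ) -> Dict[str, Dict[str, str]]:
    """Base and sensitivity family per endpoint, enforced jointly across arms
    when the policy asks for it: base = shape-matching family with the best
    summed AIC; sensitivity = the jointly converged family whose modelled
    survival at the horizon differs most from the base case."""
    policy = config.get("fit_policy", {})
    joint = policy.get("same_family_across_arms", True)
    shape = policy.get("clinical_shape", "increasing")
    horizon = config.get("engine", {}).get("horizon_years", 40.0)
    out = {}
    for ep in ("OS", "PFS"):
        ranks = [rankings[(arm, ep)] for arm in ARMS]
        if joint:
            base = select_family_joint(ranks, clinical_shape=shape)
        else:
            base = ranks[0].base_family
        common = set.intersection(*(set(r.fits) for r in ranks)) - {base}
        scores = {}
        for fam in common:
            if not all(r.fits[fam].converged for r in ranks):
                continue
            scores[fam] = sum(
                abs(float(r.fits[fam].sf(horizon)) -
                    float(r.fits[base].sf(horizon))) for r in ranks)
        sens = max(scores, key=scores.get) if scores else base
        out[ep] = {"base": base, "sensitivity": sens}
    return out


def build_decision_model(config: dict,
                         datasets: Dict[Tuple[str, str], SurvivalDataset],
                         rankings: Optional[Dict] = None
                         ) -> Tuple[DecisionModel, dict]:
    """Assemble the runnable decision model from configuration, evidence and
    (optionally precomputed) fits; returns the model plus selection metadata."""
    if rankings is None:
        rankings = fit_evidence(config, datasets)
    families = _select_families(config, rankings)

    cohort = config.get("cohort", {})
    start_age = cohort.get("start_age", 60.0)
    prop_female = cohort.get("proportion_female", 0.40)
    eng = config.get("engine", {})
    cycle = eng.get("cycle_length_weeks", 1.0) * 7.0 / 365.25
    horizon = eng.get("horizon_years", 40.0)

    ucfg = config.get("utilities", {})
    age_idx = make_age_index(ucfg.get("age_decrement"), start_age, prop_female)
    utilities = {}
    for arm in ARMS:
        ae = ucfg.get(f"ae_disutility_{arm}", 0.0)
        utilities[arm] = UtilitySpec(
            u_pf=ucfg.get("progression_free", 0.77),
            u_pd=ucfg.get("progressed", 0.68),
            age_index=age_idx, ae_events=((1.0, ae),) if ae else ())

    ccfg = config.get("costs", {})
    tcfg = config.get("treatment", {})
    pcfg = config.get("prices", {})
    drug = tcfg.get("drug")
    tender = tuple((t["price_gbp"], t["market_share"])
                   for t in (pcfg.get("tender") or []))
    cost_specs = {}
    for arm in ARMS:
        components = ()
        if drug and arm in (drug.get("arms") or []):
            components = (RegimenComponent(
                name=drug.get("name", "drug"),
                dose_rule=DoseRule(drug["dose_rule"], drug["dose_mg"],
                                   drug["admin_interval_weeks"]),
                rdi=drug.get("relative_dose_intensity", 1.0),
                vial_options=tuple(VialOption(v["size_mg"], v["price_gbp"])
                                   for v in drug["vial_options"])),)
        ae_cost = ccfg.get(f"ae_cost_{arm}", 0.0)
        cost_specs[arm] = CostSpec(
            components=components, tender_prices=tender,
            price_statistic=pcfg.get("statistic", "mean"),
            admin_monitoring_monthly=ccfg.get("admin_monitoring_monthly", {})
            .get(arm, 0.0),
            state_cost_pf_monthly=ccfg.get("state_cost_pf_monthly", 0.0),
            state_cost_pd_monthly=ccfg.get("state_cost_pd_monthly", 0.0),
            terminal_cost=ccfg.get("terminal_cost", 0.0),
            ae_events=((1.0, ae_cost),) if ae_cost else (),
            vial_sharing=tcfg.get("vial_sharing", False))

    bcfg = config.get("bodies")
    bodies = None
    if bcfg:
        w, b = bcfg["weight_kg"], bcfg["bsa_m2"]
        bodies = BodyMetricDistribution(
            weight_meanlog=(w["meanlog_female"], w["meanlog_male"]),
            weight_sdlog=(w["sdlog_female"], w["sdlog_male"]),
            bsa_meanlog=(b["meanlog_female"], b["meanlog_male"]),
            bsa_sdlog=(b["sdlog_female"], b["sdlog_male"]),
            proportion_female=prop_female,
            n_quantiles=bcfg.get("n_quantiles", 199))

    ttd = {}
    for arm in ARMS:
        if (arm, "TTD") in datasets and tcfg.get("ttd_from_km", True):
            ttd[arm] = km_estimate(datasets[(arm, "TTD")]).survival
        else:
            years = cfgmod.ttd_years(config, arm)
            if years is not None:
                ttd[arm] = years

    ecfg = config.get("econ", {})
    model = DecisionModel(
        os_base={a: rankings[(a, "OS")].fits[families["OS"]["base"]] for a in ARMS},
        pfs_base={a: rankings[(a, "PFS")].fits[families["PFS"]["base"]]
                  for a in ARMS},
        os_sens={a: rankings[(a, "OS")].fits[families["OS"]["sensitivity"]]
                 for a in ARMS},
        pfs_sens={a: rankings[(a, "PFS")].fits[families["PFS"]["sensitivity"]]
                  for a in ARMS},
        ttd=ttd, utilities=utilities, cost_specs=cost_specs, bodies=bodies,
        cycle_length=cycle, horizon=horizon,
        discount_rate_qaly=eng.get("discount_rate_qaly", 0.035),
        discount_rate_cost=eng.get("discount_rate_cost", 0.035),
        start_age=start_age, proportion_female=prop_female,
        wtp_thresholds=tuple(ecfg.get("wtp_thresholds", (20000.0, 30000.0))),
        severity_weight=ecfg.get("severity_weight", 1.0),
        hr_scenario=config.get("hr_scenario"))
    meta = {"families": families,
            "rankings": {f"{arm}_{ep}": rankings[(arm, ep)].table
                         for (arm, ep) in rankings}}
    return model, meta


def severity_assessment(config: dict, model: DecisionModel,
                        soc_qalys: float):
    """Shortfall of the comparator (standard-care) arm versus the matched
    general population, using the configured life table and utility norm."""
    scfg = config.get("severity", {})
    if not scfg:
        return None
    genpop = general_population_qalys(
        start_age=model.start_age, proportion_female=model.proportion_female,
        life_table=scfg.get("life_table",
                            {"constant_annual_death_prob": 0.02}),
        utility_norm=scfg.get("utility_norm", 0.8),
        discount_rate=model.discount_rate_qaly)
    return qaly_shortfall(
        soc_qalys, scfg.get("subsequent_qaly_addition", 0.0), genpop,
        thresholds=scfg.get("thresholds"))


def run_pipeline(config: dict, outdir,
                 datasets: Optional[Dict[Tuple[str, str], SurvivalDataset]] = None,
                 base_dir: Optional[Path] = None) -> Path:
    """Execute the whole pipeline and persist every artifact under ``outdir``.

    Idempotent given the configured seed: re-running the same configuration
    reproduces identical tables. Any stage error aborts with the stage name,
    leaving the partial log on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = cfgmod.config_hash(config)
    seed = int(config.get("seed", 0))
    log: list = [f"config_hash={chash}", f"seed={seed}"]

    def stage(name):
        log.append(f"stage:{name}")

    def fail(name, exc):
        log.append(f"error in stage {name}: {exc}")
        (outdir / "log.txt").write_text("\n".join(log) + "\n")
        raise PipelineError(name, exc)

    try:
        stage("evidence")
        if datasets is None:
            datasets = load_evidence(config, base_dir)
    except PipelineError:
        raise
    except Exception as exc:
        fail("evidence", exc)

    try:
        stage("fit")
        rankings = fit_evidence(config, datasets)
        model, meta = build_decision_model(config, datasets, rankings)
        for (arm, ep), rk in rankings.items():
            rk.table.to_csv(outdir / f"fits_{arm}_{ep}.csv", index=False)
    except Exception as exc:
        fail("fit", exc)

    try:
        stage("partsa")
        base = model.run_deterministic("base")
        for arm in ARMS:
            spec = model._spec(arm, model.os_base[arm], model.pfs_base[arm])
            trace = build_traces(spec)
            trace.to_frame().to_csv(outdir / f"trace_{arm}.csv", index=False)
            if trace.clip_warnings:
                log.append(f"warning: {trace.clip_warnings} PFS/OS clips in {arm}")
    except Exception as exc:
        fail("partsa", exc)

    try:
        stage("scenarios")
        scen = model.run_scenarios(config.get("scenarios"))
        scen.to_csv(outdir / "scenarios.csv", index=False)
    except Exception as exc:
        fail("scenarios", exc)

    try:
        stage("psa")
        pcfg = config.get("psa", {})
        psa = model.run_psa(
            n_draws=int(pcfg.get("n_draws", 500)), seed=seed,
            se_fraction=pcfg.get("se_fraction", 0.10),
            survival_vcov_scale=pcfg.get("survival_vcov_scale", 1.0))
        psa.ceac.to_csv(outdir / "psa_ceac.csv", index=False)
        psa.draws.to_csv(outdir / "psa_draws.csv", index=False)
    except Exception as exc:
        fail("psa", exc)

    try:
        stage("severity")
        shortfall = severity_assessment(
            config, model, base.comparison.comparator.qalys_discounted)
    except Exception as exc:
        fail("severity", exc)

    stage("summary")
    summary = {
        "config_hash": chash,
        "seed": seed,
        "families": meta["families"],
        "per_arm": {
            arm: {
                "ly_discounted": getattr(base.comparison, arm).ly_discounted,
                "ly_undiscounted": getattr(base.comparison, arm).ly_undiscounted,
                "qalys_discounted": getattr(base.comparison, arm).qalys_discounted,
                "cost_total": getattr(base.comparison, arm).cost_total,
                "cost_items": getattr(base.comparison, arm).costs,
            } for arm in ARMS},
        "base_case": base.as_row(),
        "psa": {"n_draws": psa.n_draws,
                "mean_delta_qaly": psa.mean_delta_qaly,
                "mean_delta_cost": psa.mean_delta_cost,
                "mean_delta_ly": psa.mean_delta_ly},
        "severity": None if shortfall is None else {
            "genpop_qalys": shortfall.genpop_qalys,
            "soc_qalys_adjusted": shortfall.soc_qalys_adjusted,
            "absolute_shortfall": shortfall.absolute_shortfall,
            "proportional_shortfall": shortfall.proportional_shortfall,
            "weight": shortfall.weight},
    }
    (outdir / "run_summary.json").write_text(json.dumps(summary, indent=2))
    (outdir / "log.txt").write_text("\n".join(log) + "\n")
    return outdir


REQUIRED_ARTIFACTS = ("run_summary.json", "scenarios.csv", "psa_ceac.csv",
                      "log.txt")


def report(run_dir, redacted: bool = False) -> str:
    """Human-readable summary of a completed run.

    In redacted mode (mirroring confidential-price handling) only the
    incremental life-years and QALYs are shown — no cost, price, ICER or
    iNMB figures. In full mode the iNMB identity is re-verified at render
    time.
    """
    run_dir = Path(run_dir)
    missing = [a for a in REQUIRED_ARTIFACTS if not (run_dir / a).exists()]
    if missing:
        raise FileNotFoundError(
            f"incomplete run in {run_dir}: missing {', '.join(missing)}")
    summary = json.loads((run_dir / "run_summary.json").read_text())
    scen = pd.read_csv(run_dir / "scenarios.csv")
    lines = [f"run {summary['config_hash']} (seed {summary['seed']})",
             f"selected families: {summary['families']}"]
    base = summary["base_case"]
    lines.append(f"incremental LYG: {base['delta_ly']:.3f}   "
                 f"incremental QALYs (discounted): {base['delta_qaly']:.3f}")
    if not redacted:
        w = base["severity_weight"]
        for key, val in base.items():
            if key.startswith("inmb_"):
                lam = float(key.split("_")[1])
                expect = lam * w * base["delta_qaly"] - base["delta_cost"]
                if abs(expect - val) > 1e-6 * max(1.0, abs(expect)):
                    raise ValueError("iNMB identity violated in stored summary")
        lines.append(f"incremental cost: {base['delta_cost']:.2f}   "
                     f"ICER: {base['icer']}")
        for key, val in base.items():
            if key.startswith("inmb_"):
                lines.append(f"  iNMB at {key.split('_')[1]}: {val:.2f}")
        cols = [c for c in scen.columns if c != "skipped"]
        lines.append(scen[cols].to_string(index=False))
    else:
        cols = [c for c in ("scenario", "delta_ly", "delta_qaly")
                if c in scen.columns]
        lines.append(scen[cols].to_string(index=False))
    if summary.get("severity"):
        sev = summary["severity"]
        lines.append(
            f"QALY shortfall: absolute {sev['absolute_shortfall']:.2f}, "
            f"proportional {sev['proportional_shortfall']:.2%}, "
            f"weight {sev['weight']}")
    return "\n".join(lines)
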