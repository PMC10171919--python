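"""Configuration, validation and end-to-end orchestration.

The pipeline runs the full evidence-to-decision chain on one
configuration file:

1. synthesize (or load) intervention-arm patient-level data;
2. emulate/load the comparator's digitized KM evidence and reconstruct
   pseudo-IPD from it;
3. reweight the intervention arm to the comparator's baseline moments
   (MAIC), unless disabled;
4. fit the configured survival families (mixture cure on the
   intervention OS curve);
5. floor the extrapolations with k-fold general-population mortality;
6. derive transitions, run the Markov traces, attach costs/utilities;
7. optionally run scenarios, OWSA, PSA and the CEAC.

Every stage's intermediate output can be written to an output directory
as CSV/JSON, and a run log records seeds, clamping/repair counters and
convergence diagnostics.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from oncocea import economics as econ
from oncocea.economics import AEItem, CostInputs, UtilityInputs
from oncocea.km_tools import reconstruct_ipd
from oncocea.maic import MAICResult, WeightedCohort, apply_weights, fit_weights
from oncocea.model import CEModel
from oncocea.survival_models import (
    LifeTable,
    fit_mixture_cure,
    fit_parametric,
    select_best,
)
from oncocea.synthetic_cohort import (
    CohortGenConfig,
    TrialSummary,
    generate_aggregate_trial,
    generate_ipd,
    summarize_baseline,
)
from oncocea import uncertainty as unc

__all__ = ["RunConfig", "PipelineResult", "load_config", "validate_inputs", "run_pipeline"]

_DATA = resources.files("oncocea") / "data"


class ValidationError(ValueError):
    """Fatal input-validation failure."""


def _data_path(name: str | Path) -> Path:
    """Resolve a config path against the packaged data directory."""
    p = Path(name)
    if p.is_absolute() or p.exists():
        return p
    candidate = Path(str(_DATA / str(name)))
    if candidate.exists():
        return candidate
    return p


@dataclass
class RunConfig:
    """Parsed run configuration (see ``data/default_config.yaml``)."""

    raw: dict
    seed: int
    cohorts: dict
    digitization: dict
    maic: dict
    survival: dict
    economics_path: Path
    life_table_path: Path
    published_summary_path: Path | None
    horizon: Any
    uncertainty: dict

    @property
    def maic_enabled(self) -> bool:
        return bool(self.maic.get("enabled", True))


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML run configuration (packaged default when ``path=None``)."""
    cfg_path = _data_path(path) if path is not None else Path(str(_DATA / "default_config.yaml"))
    with open(cfg_path) as fh:
        raw = yaml.safe_load(fh)
    pub = raw.get("published_summary")
    return RunConfig(
        raw=raw,
        seed=int(raw["seed"]),
        cohorts=raw["cohorts"],
        digitization=raw["digitization"],
        maic=raw.get("maic", {}),
        survival=raw["survival"],
        economics_path=_data_path(raw["economics"]),
        life_table_path=_data_path(raw["life_table"]),
        published_summary_path=_data_path(pub) if pub else None,
        horizon=raw.get("horizon", "lifetime"),
        uncertainty=raw.get("uncertainty", {}),
    )


def load_economic_inputs(path: str | Path) -> dict:
    """Parse the cost/utility/AE fixture into typed inputs.

    Returns a dict with ``cost_inputs`` (intervention/comparator ->
    :class:`CostInputs`), ``utilities`` (name -> :class:`UtilityInputs`),
    ``wtp`` and the two discount rates.
    """
    with open(_data_path(path)) as fh:
        raw = yaml.safe_load(fh)
    arms = {}
    name_map = {"serplulimab": "intervention", "regorafenib": "comparator"}
    for arm_name, a in raw["arms"].items():
        aes = [
            AEItem(
                name=x["name"],
                incidence=float(x["incidence"]),
                mgmt_cost=float(x["cost"]),
                disutility=float(x["disutility"]),
                kind=x.get("kind", "one_off"),
            )
            for x in a.get("aes", [])
        ]
        cap = a.get("drug_cap_cycles")
        arms[name_map.get(arm_name, arm_name)] = CostInputs(
            arm=arm_name,
            diagnosis_cost=float(a["diagnosis_cost"]),
            drug_cost_per_cycle=float(a["drug_cost_per_cycle"]),
            drug_cap_cycles=int(cap) if cap is not None else None,
            monitoring_pfs_y0_3=float(a["monitoring_pfs_y0_3"]),
            monitoring_pfs_y4_5=float(a["monitoring_pfs_y4_5"]),
            monitoring_pfs_gt5=float(a["monitoring_pfs_gt5"]),
            monitoring_pd=float(a["monitoring_pd"]),
            admin_pfs=float(a["admin_pfs"]),
            admin_pd=float(a["admin_pd"]),
            hosp_pfs=float(a["hosp_pfs"]),
            hosp_pd=float(a["hosp_pd"]),
            subsequent_tx_pd=float(a["subsequent_tx_pd"]),
            eol_cost=float(a["eol_cost"]),
            ae_list=aes,
            ae_rate_horizon_months=float(a.get("ae_rate_horizon_months", 12.0)),
        )
    utilities = {
        name: UtilityInputs(u_pfs=float(u["u_pfs"]), u_pd=float(u["u_pd"]), source=name)
        for name, u in raw["utilities"].items()
    }
    return {
        "cost_inputs": arms,
        "utilities": utilities,
        "wtp": float(raw["wtp_per_qaly"]),
        "discount_cost": float(raw["discount_rate_costs"]),
        "discount_outcome": float(raw["discount_rate_outcomes"]),
        "dosing": raw.get("dosing", {}),
    }


def load_maic_targets(path: str | Path, n: int = 136) -> TrialSummary:
    df = pd.read_csv(_data_path(path))
    return TrialSummary(
        n=n, covariate_means=dict(zip(df["covariate"], df["target_value"].astype(float)))
    )


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_inputs(config: RunConfig) -> dict:
    """Schema/domain checks over every referenced input.

    Returns ``{"fatal": [...], "warnings": [...]}``; an empty ``fatal``
    list means the configuration is runnable.
    """
    fatal: list[str] = []
    warnings: list[str] = []

    try:
        lt = pd.read_csv(config.life_table_path)
        if not {"age", "sex", "qx"}.issubset(lt.columns):
            fatal.append("life table: missing columns (need age, sex, qx)")
        else:
            if ((lt["qx"] < 0) | (lt["qx"] > 1)).any():
                fatal.append("life table: qx outside [0, 1]")
            try:
                LifeTable(lt)
            except ValueError as e:
                fatal.append(f"life table: {e}")
    except FileNotFoundError:
        fatal.append(f"life table not found: {config.life_table_path}")

    try:
        ei = load_economic_inputs(config.economics_path)
        for name, u in ei["utilities"].items():
            if not (0 <= u.u_pfs <= 1 and 0 <= u.u_pd <= 1):
                fatal.append(f"utilities[{name}]: outside [0, 1]")
    except FileNotFoundError:
        fatal.append(f"economic inputs not found: {config.economics_path}")
    except (ValueError, KeyError) as e:
        fatal.append(f"economic inputs: {e}")

    if config.maic_enabled:
        tpath = _data_path(config.maic.get("targets_csv", ""))
        try:
            tdf = pd.read_csv(tpath)
            if not {"covariate", "target_value"}.issubset(tdf.columns):
                fatal.append("MAIC targets: need columns covariate,target_value")
            else:
                bad = tdf[
                    (tdf["covariate"] != "age")
                    & ((tdf["target_value"] < 0) | (tdf["target_value"] > 1))
                ]
                if len(bad):
                    fatal.append("MAIC targets: proportions outside [0, 1]")
        except FileNotFoundError:
            fatal.append(f"MAIC targets not found: {tpath}")

    for arm, c in config.cohorts.items():
        try:
            CohortGenConfig(seed=0, **{k: v for k, v in c.items() if k != "arm"},
                            arm=c.get("arm", arm))
        except (TypeError, ValueError) as e:
            fatal.append(f"cohort config {arm!r}: {e}")

    horizon = config.horizon
    if not (horizon == "lifetime" or (isinstance(horizon, int) and horizon > 0)):
        fatal.append(f"horizon must be 'lifetime' or a positive integer, got {horizon!r}")

    k = config.survival.get("death_risk_multiplier", 2.0)
    if k < 1:
        fatal.append("death_risk_multiplier must be >= 1")
    if config.survival.get("start_age", 55.0) < 0:
        fatal.append("start_age must be nonnegative")
    if config.uncertainty.get("psa_draws", 1000) < 1:
        warnings.append("psa_draws < 1; PSA will be skipped")
    return {"fatal": fatal, "warnings": warnings}


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    """Everything the end-to-end run produced."""

    config: RunConfig
    ipd_intervention: pd.DataFrame
    digitized: dict  # endpoint -> DigitizedKM
    ipd_comparator: dict  # endpoint -> reconstructed cohort
    baseline: TrialSummary
    maic_result: MAICResult | None
    fits: dict
    rankings: dict
    model: CEModel
    model_unweighted: CEModel | None
    base_case: econ.CEResult
    scenarios: dict = field(default_factory=dict)
    owsa_table: pd.DataFrame | None = None
    psa_draws: unc.PSADraws | None = None
    ceac_curve: pd.DataFrame | None = None
    log: dict = field(default_factory=dict)


def _cohort_config(c: dict, seed: int, default_arm: str) -> CohortGenConfig:
    kw = dict(c)
    kw.setdefault("arm", default_arm)
    for key in ("latent_os_params", "pfs_params"):
        if key in kw:
            kw[key] = tuple(kw[key])
    return CohortGenConfig(seed=seed, **kw)


def _fit_arm_curves(config: RunConfig, weighted, comparator_cohorts, log: dict) -> tuple[dict, dict]:
    """Fit the configured families; return (fits, AIC/BIC rankings)."""
    fam = config.survival["families"]
    fits: dict = {}
    rankings: dict = {}

    fits["intervention_pfs"] = fit_parametric(weighted, "pfs", fam["intervention_pfs"])
    fits["intervention_os"] = fit_mixture_cure(
        weighted, "os", latent_family=fam["intervention_os_latent"]
    )
    fits["comparator_pfs"] = fit_parametric(
        comparator_cohorts["pfs"], "pfs", fam["comparator_pfs"]
    )
    fits["comparator_os"] = fit_parametric(
        comparator_cohorts["os"], "os", fam["comparator_os"]
    )

    # Full six-family comparison table for the comparator OS curve
    # (mirrors the AIC/BIC supplement structure); the configured family
    # stays the base case regardless of ranking (visual-inspection
    # override is a config choice).
    all_fits = []
    for family in ("exponential", "gamma", "weibull", "lognormal", "loglogistic", "gompertz"):
        try:
            all_fits.append(fit_parametric(comparator_cohorts["os"], "os", family))
        except Exception as e:  # pragma: no cover - diagnostic only
            log.setdefault("fit_failures", []).append(f"comparator_os/{family}: {e}")
    if all_fits:
        _, rankings["comparator_os"] = select_best(all_fits)
    return fits, rankings


def run_pipeline(
    config: RunConfig | None = None,
    outdir: str | Path | None = None,
    run_uncertainty: bool = True,
    run_scenarios: bool = True,
    psa_draws: int | None = None,
) -> PipelineResult:
    """Execute the full analysis described by ``config``.

    ``run_uncertainty=False`` skips OWSA/PSA/CEAC (used by quick smoke
    runs); ``psa_draws`` overrides the configured draw count.
    """
    if config is None:
        config = load_config()
    report = validate_inputs(config)
    if report["fatal"]:
        raise ValidationError("; ".join(report["fatal"]))

    log: dict = {"seed": config.seed, "validation_warnings": report["warnings"]}

    # Stage 1: synthesize intervention IPD
    seed_int = config.seed % (2**31)
    seed_comp = (config.seed + 1) % (2**31)
    cfg_int = _cohort_config(config.cohorts["intervention"], seed_int, "serplulimab")
    ipd_int = generate_ipd(cfg_int)
    log["seed_intervention"] = seed_int
    log["seed_comparator"] = seed_comp

    # Stage 2: comparator digitized evidence -> pseudo-IPD
    cfg_comp = _cohort_config(config.cohorts["comparator"], seed_comp, "regorafenib")
    dig = config.digitization
    readoff = np.arange(
        0.0, dig["curve_max_months"] + 1e-9, dig["curve_step_months"]
    ).tolist()
    risk_times = np.arange(
        0.0, dig["curve_max_months"] + 1e-9, dig["risk_table_step_months"]
    ).tolist()
    digitized = {}
    ipd_comp = {}
    for endpoint in ("os", "pfs"):
        dk = generate_aggregate_trial(
            cfg_comp, readoff, risk_times, endpoint=endpoint, clip=True
        )
        digitized[endpoint] = dk
        ipd_comp[endpoint] = reconstruct_ipd(dk, arm="regorafenib", endpoint=endpoint)
        log[f"digitized_{endpoint}_repairs"] = dk.repairs

    # Stage 3: MAIC
    baseline = summarize_baseline(ipd_int)
    maic_result = None
    if config.maic_enabled:
        targets = load_maic_targets(
            config.maic["targets_csv"], n=cfg_comp.n
        )
        maic_result = fit_weights(ipd_int, targets, config.maic["covariates"])
        weighted = apply_weights(ipd_int, maic_result)
        log["maic_ess"] = maic_result.ess
        log["maic_grad_norm"] = maic_result.grad_norm
    else:
        weighted = WeightedCohort(records=ipd_int, weights=np.ones(len(ipd_int)))

    # Stage 4: survival fits
    fits, rankings = _fit_arm_curves(config, weighted, ipd_comp, log)

    # Stages 5-7 are wrapped by CEModel
    ei = load_economic_inputs(config.economics_path)
    life_table = LifeTable.from_csv(config.life_table_path)
    model = CEModel(
        fits=fits,
        life_table=life_table,
        start_age=float(config.survival.get("start_age", 55.0)),
        male_prop=float(config.survival.get("male_prop", 0.6)),
        death_risk_multiplier=float(config.survival.get("death_risk_multiplier", 2.0)),
        max_cycles=int(config.survival.get("max_cycles", 800)),
        cost_inputs=ei["cost_inputs"],
        utilities=ei["utilities"]["base"],
        discount_cost=ei["discount_cost"],
        discount_outcome=ei["discount_outcome"],
        wtp=ei["wtp"],
    )
    horizon = config.horizon
    base_case = model.evaluate(horizon=horizon)

    for arm in ("intervention", "comparator"):
        _, schedule = model.trace(arm)
        log[f"{arm}_pfs_clamped_cycles"] = schedule.pfs_clamped
        log[f"{arm}_prog_floored_cycles"] = schedule.prog_clamped

    # Unweighted (direct-comparison) model for scenario 1
    model_unweighted = None
    if config.maic_enabled:
        unweighted = WeightedCohort(records=ipd_int, weights=np.ones(len(ipd_int)))
        fits_unw, _ = _fit_arm_curves(config, unweighted, ipd_comp, log)
        model_unweighted = dataclasses.replace(model, fits=fits_unw)

    result = PipelineResult(
        config=config,
        ipd_intervention=ipd_int,
        digitized=digitized,
        ipd_comparator=ipd_comp,
        baseline=baseline,
        maic_result=maic_result,
        fits=fits,
        rankings=rankings,
        model=model,
        model_unweighted=model_unweighted,
        base_case=base_case,
        log=log,
    )

    if run_scenarios:
        for sid in unc.SCENARIO_IDS:
            if sid == "no_maic" and model_unweighted is None:
                continue
            result.scenarios[sid] = unc.run_scenario(
                sid, model, utilities_bank=ei["utilities"],
                no_maic_model=model_unweighted,
            )

    if run_uncertainty:
        u = config.uncertainty
        specs = unc.build_param_registry(model, u.get("owsa_variation", 0.2))
        result.owsa_table = unc.owsa(model, specs)
        n_draws = psa_draws if psa_draws is not None else int(u.get("psa_draws", 1000))
        if n_draws >= 1:
            psa_seed = (config.seed + 7) % (2**31)
            result.psa_draws = unc.psa(model, specs, n_draws=n_draws, seed=psa_seed)
            log["seed_psa"] = psa_seed
            lam = np.arange(0.0, u.get("lambda_max", 60000.0) + 1e-9,
                            u.get("lambda_step", 500.0))
            result.ceac_curve = unc.ceac(result.psa_draws, lam)

    if outdir is not None:
        _write_artifacts(result, Path(outdir))
    return result


# ---------------------------------------------------------------------------
# artifact export
# ---------------------------------------------------------------------------

def _ce_table(result: PipelineResult) -> pd.DataFrame:
    """Summary table of base case and scenarios (published-table layout)."""
    rows = []

    def add(analysis: str, ce: econ.CEResult) -> None:
        rows.append(
            {
                "analysis": analysis,
                "arm": ce.comparator.arm,
                "cost": round(ce.comparator.cost, 2),
                "ly": round(ce.comparator.ly, 2),
                "qaly": round(ce.comparator.qaly, 2),
                "icer": np.nan,
            }
        )
        rows.append(
            {
                "analysis": analysis,
                "arm": ce.intervention.arm,
                "cost": round(ce.intervention.cost, 2),
                "ly": round(ce.intervention.ly, 2),
                "qaly": round(ce.intervention.qaly, 2),
                "icer": round(ce.icer, 2) if ce.icer is not None else np.nan,
            }
        )

    add("base", result.base_case)
    for sid, ce in result.scenarios.items():
        add(sid, ce)
    return pd.DataFrame(rows)


def _write_artifacts(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.ipd_intervention.to_csv(outdir / "ipd_intervention.csv", index=False)
    for endpoint, dk in result.digitized.items():
        dk.to_csv(
            outdir / f"digitized_{endpoint}_curve.csv",
            outdir / f"digitized_{endpoint}_risk.csv",
        )
        result.ipd_comparator[endpoint].to_csv(
            outdir / f"ipd_comparator_{endpoint}.csv", index=False
        )
    if result.maic_result is not None:
        result.maic_result.to_frame(result.ipd_intervention["id"]).to_csv(
            outdir / "maic_weights.csv", index=False
        )
    with open(outdir / "fits.json", "w") as fh:
        json.dump({k: f.to_dict() for k, f in result.fits.items()}, fh, indent=2)
    for key, ranking in result.rankings.items():
        ranking.to_csv(outdir / f"ranking_{key}.csv", index=False)
    for arm in ("intervention", "comparator"):
        trace, _ = result.model.trace(arm)
        trace.to_frame().to_csv(outdir / f"trace_{arm}.csv", index=False)
    _ce_table(result).to_csv(outdir / "ce_results.csv", index=False)
    if result.owsa_table is not None:
        result.owsa_table.to_csv(outdir / "owsa_tornado.csv", index=False)
    if result.psa_draws is not None:
        result.psa_draws.frame.to_csv(outdir / "psa_draws.csv", index=False)
    if result.ceac_curve is not None:
        result.ceac_curve.to_csv(outdir / "ceac.csv", index=False)
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(result.log, fh, indent=2, default=str)
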