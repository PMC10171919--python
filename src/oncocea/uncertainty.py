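"""Sensitivity, scenario and probabilistic uncertainty analysis.

* One-way sensitivity analysis (OWSA): every economic parameter plus
  both discount rates varied one at a time to its bounds (95% CI where
  available, otherwise +/-20%), producing a tornado table of ICER ranges.
* Probabilistic sensitivity analysis (PSA): beta distributions for
  incidences/utilities/disutilities, gamma for costs (both
  moment-matched to mean = base and SD = 20% of base unless
  hyperparameters are supplied), and survival parameters drawn
  multivariate-normally on the unconstrained scale through the Cholesky
  factor of each fit's covariance — re-deriving the transition schedule
  per draw.
* Cost-effectiveness acceptability curve (CEAC): per willingness-to-pay
  threshold, the fraction of PSA draws with positive incremental net
  monetary benefit.
* Scenario analyses: direct (unweighted) comparison, a 36-month
  horizon, a fourfold background-mortality multiplier and alternative
  utility sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from oncocea.economics import AEItem, CostInputs, UtilityInputs
from oncocea.model import CEModel, with_theta

__all__ = [
    "ParamSpec",
    "PSADraws",
    "SCENARIO_IDS",
    "build_param_registry",
    "owsa",
    "psa",
    "ceac",
    "run_scenario",
]

SCENARIO_IDS = (
    "no_maic",
    "horizon_36m",
    "death_risk_4x",
    "utilities_astrum",
    "utilities_correct",
)

#: 36 months expressed in complete 28-day cycles (39*28 = 1092 d)
CYCLES_36M = 39


@dataclass
class ParamSpec:
    """One scalar model parameter with OWSA bounds and a PSA distribution."""

    name: str  # dotted path, e.g. "intervention.drug_cost_per_cycle"
    base: float
    low: float
    high: float
    psa_dist: str = "fixed"  # beta | gamma | fixed
    sd: float | None = None  # PSA standard deviation (default 20% of base)

    def __post_init__(self) -> None:
        if not (self.low <= self.base <= self.high):
            raise ValueError(f"{self.name}: bounds must bracket the base value")
        if self.psa_dist == "beta" and not (0 <= self.base <= 1):
            raise ValueError(f"{self.name}: beta requires base in [0, 1]")
        if self.psa_dist == "gamma" and self.base < 0:
            raise ValueError(f"{self.name}: gamma requires base >= 0")


@dataclass
class PSADraws:
    n_draws: int
    seed: int
    frame: pd.DataFrame  # columns: cost_int, qaly_int, cost_comp, qaly_comp

    @property
    def delta_cost(self) -> np.ndarray:
        return (self.frame["cost_int"] - self.frame["cost_comp"]).to_numpy()

    @property
    def delta_qaly(self) -> np.ndarray:
        return (self.frame["qaly_int"] - self.frame["qaly_comp"]).to_numpy()


# ---------------------------------------------------------------------------
# parameter registry and override plumbing
# ---------------------------------------------------------------------------

_COST_FIELDS = (
    "diagnosis_cost",
    "drug_cost_per_cycle",
    "monitoring_pfs_y0_3",
    "monitoring_pfs_y4_5",
    "monitoring_pfs_gt5",
    "monitoring_pd",
    "admin_pfs",
    "admin_pd",
    "hosp_pfs",
    "hosp_pd",
    "subsequent_tx_pd",
    "eol_cost",
)


def build_param_registry(model: CEModel, variation: float = 0.20) -> list[ParamSpec]:
    """Every economic parameter plus discount rates, with +/-variation bounds.

    Utilities are capped at 1.0 after perturbation.  Structural zeros
    (e.g. a zero administration cost) keep a degenerate zero-width range.
    """
    specs: list[ParamSpec] = []
    for arm in ("intervention", "comparator"):
        ci = model.cost_inputs[arm]
        for f in _COST_FIELDS:
            base = getattr(ci, f)
            specs.append(
                ParamSpec(
                    name=f"{arm}.{f}",
                    base=base,
                    low=base * (1 - variation),
                    high=base * (1 + variation),
                    psa_dist="gamma" if base > 0 else "fixed",
                )
            )
        for ae in ci.ae_list:
            specs.append(
                ParamSpec(
                    name=f"{arm}.ae.{ae.name}.incidence",
                    base=ae.incidence,
                    low=ae.incidence * (1 - variation),
                    high=min(ae.incidence * (1 + variation), 1.0),
                    psa_dist="beta" if ae.incidence > 0 else "fixed",
                )
            )
            specs.append(
                ParamSpec(
                    name=f"{arm}.ae.{ae.name}.cost",
                    base=ae.mgmt_cost,
                    low=ae.mgmt_cost * (1 - variation),
                    high=ae.mgmt_cost * (1 + variation),
                    psa_dist="gamma" if ae.mgmt_cost > 0 else "fixed",
                )
            )
            specs.append(
                ParamSpec(
                    name=f"{arm}.ae.{ae.name}.disutility",
                    base=ae.disutility,
                    low=ae.disutility * (1 - variation),
                    high=min(ae.disutility * (1 + variation), 1.0),
                    psa_dist="beta" if ae.disutility > 0 else "fixed",
                )
            )
    for uf in ("u_pfs", "u_pd"):
        base = getattr(model.utilities, uf)
        specs.append(
            ParamSpec(
                name=f"utilities.{uf}",
                base=base,
                low=base * (1 - variation),
                high=min(base * (1 + variation), 1.0),
                psa_dist="beta",
            )
        )
    for df_, base in (("cost", model.discount_cost), ("outcome", model.discount_outcome)):
        specs.append(
            ParamSpec(
                name=f"discount.{df_}",
                base=base,
                low=base * (1 - variation),
                high=base * (1 + variation),
                psa_dist="fixed",
            )
        )
    return specs


def registry_to_frame(specs: Sequence[ParamSpec]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"name": s.name, "base": s.base, "low": s.low, "high": s.high,
             "psa_dist": s.psa_dist}
            for s in specs
        ]
    )


def _apply_overrides(model: CEModel, overrides: dict[str, float]) -> dict:
    """Translate named parameter values into evaluate() keyword arguments."""
    cost_inputs = {arm: model.cost_inputs[arm] for arm in model.cost_inputs}
    utilities = model.utilities
    kwargs: dict = {}
    ae_patches: dict[str, dict[str, dict[str, float]]] = {}
    for name, value in overrides.items():
        parts = name.split(".")
        if parts[0] in ("intervention", "comparator"):
            arm = parts[0]
            if parts[1] == "ae":
                ae_patches.setdefault(arm, {}).setdefault(parts[2], {})[parts[3]] = value
            else:
                cost_inputs[arm] = replace(cost_inputs[arm], **{parts[1]: value})
        elif parts[0] == "utilities":
            utilities = replace(utilities, **{parts[1]: value})
        elif parts[0] == "discount":
            kwargs[f"discount_{parts[1]}"] = value
        else:
            raise KeyError(f"unknown parameter {name!r}")
    for arm, patches in ae_patches.items():
        new_aes = []
        for ae in cost_inputs[arm].ae_list:
            if ae.name in patches:
                p = patches[ae.name]
                new_aes.append(
                    AEItem(
                        name=ae.name,
                        incidence=p.get("incidence", ae.incidence),
                        mgmt_cost=p.get("cost", ae.mgmt_cost),
                        disutility=p.get("disutility", ae.disutility),
                        kind=ae.kind,
                    )
                )
            else:
                new_aes.append(ae)
        cost_inputs[arm] = replace(cost_inputs[arm], ae_list=new_aes)
    kwargs["cost_inputs"] = cost_inputs
    kwargs["utilities"] = utilities
    return kwargs


# ---------------------------------------------------------------------------
# OWSA
# ---------------------------------------------------------------------------

def owsa(model: CEModel, specs: Sequence[ParamSpec]) -> pd.DataFrame:
    """Tornado table: ICER at each parameter's low/high bound.

    Rows are sorted by decreasing |ICER range|.  A bound at which the
    incremental QALYs vanish is flagged (``degenerate=True``) rather
    than dropped.
    """
    base = model.evaluate()
    rows = []
    for spec in specs:
        vals = {}
        degenerate = False
        for side, v in (("low", spec.low), ("high", spec.high)):
            res = model.evaluate(**_apply_overrides(model, {spec.name: v}))
            if res.icer is None:
                degenerate = True
                vals[side] = np.nan
            else:
                vals[side] = res.icer
        rows.append(
            {
                "name": spec.name,
                "base_icer": base.icer,
                "icer_low": vals["low"],
                "icer_high": vals["high"],
                "range": abs(vals["high"] - vals["low"]),
                "degenerate": degenerate,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values("range", ascending=False, ignore_index=True)


# ---------------------------------------------------------------------------
# PSA
# ---------------------------------------------------------------------------

def _beta_hyper(mean: float, sd: float) -> tuple[float, float]:
    if mean <= 0 or mean >= 1:
        raise ValueError("beta moment matching needs mean strictly in (0, 1)")
    max_sd = np.sqrt(mean * (1 - mean))
    if sd >= max_sd:
        raise ValueError(
            f"beta moment matching infeasible: sd {sd:.4g} >= bound {max_sd:.4g}"
        )
    nu = mean * (1 - mean) / sd**2 - 1.0
    return mean * nu, (1 - mean) * nu


def _gamma_hyper(mean: float, sd: float) -> tuple[float, float]:
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return shape, scale


def psa(
    model: CEModel,
    specs: Sequence[ParamSpec],
    n_draws: int = 1000,
    seed: int = 0,
    include_survival: bool = True,
) -> PSADraws:
    """Monte Carlo over all parameter distributions; seeded, reproducible.

    Survival-parameter uncertainty enters through one multivariate
    normal block per fitted curve (Cholesky factor of the fit's
    covariance on the unconstrained scale); transition schedules are
    re-derived from the drawn parameters on every draw.
    """
    rng = np.random.default_rng(seed)
    econ_draws: dict[str, np.ndarray] = {}
    for spec in specs:
        sd = spec.sd if spec.sd is not None else 0.2 * spec.base
        if spec.psa_dist == "fixed" or spec.base == 0 or sd == 0:
            econ_draws[spec.name] = np.full(n_draws, spec.base)
        elif spec.psa_dist == "beta":
            a, b = _beta_hyper(spec.base, sd)
            econ_draws[spec.name] = rng.beta(a, b, n_draws)
        elif spec.psa_dist == "gamma":
            shape, scale = _gamma_hyper(spec.base, sd)
            econ_draws[spec.name] = rng.gamma(shape, scale, n_draws)
        else:
            raise ValueError(f"{spec.name}: unknown PSA distribution {spec.psa_dist!r}")

    theta_draws: dict[str, np.ndarray] = {}
    if include_survival:
        for key, fit in model.fits.items():
            vcov = np.asarray(fit.vcov, dtype=float)
            try:
                chol = np.linalg.cholesky(
                    vcov + 1e-12 * np.eye(len(vcov))
                )
            except np.linalg.LinAlgError as e:
                raise ValueError(
                    f"survival block {key!r}: covariance not positive semidefinite"
                ) from e
            z = rng.standard_normal((n_draws, len(vcov)))
            theta_draws[key] = fit.theta + z @ chol.T

    rows = np.empty((n_draws, 4))
    for i in range(n_draws):
        overrides = {name: float(vals[i]) for name, vals in econ_draws.items()}
        kwargs = _apply_overrides(model, overrides)
        fits = None
        if include_survival:
            fits = {
                key: with_theta(model.fits[key], theta_draws[key][i])
                for key in model.fits
            }
        res = model.evaluate(fits=fits, **kwargs)
        rows[i] = (
            res.intervention.cost,
            res.intervention.qaly,
            res.comparator.cost,
            res.comparator.qaly,
        )
    frame = pd.DataFrame(rows, columns=["cost_int", "qaly_int", "cost_comp", "qaly_comp"])
    return PSADraws(n_draws=n_draws, seed=seed, frame=frame)


def ceac(draws: PSADraws, lambda_grid: Sequence[float]) -> pd.DataFrame:
    """P(intervention cost-effective) over willingness-to-pay thresholds.

    For each threshold the probability is the exact fraction of draws
    with positive incremental net monetary benefit.
    """
    dq = draws.delta_qaly
    dc = draws.delta_cost
    rows = [
        {"wtp": lam, "p_cost_effective": float(np.mean(lam * dq - dc > 0))}
        for lam in lambda_grid
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

def run_scenario(
    scenario_id: str,
    model: CEModel,
    utilities_bank: dict[str, UtilityInputs] | None = None,
    no_maic_model: CEModel | None = None,
):
    """Evaluate one named scenario against the base-case model.

    ``no_maic`` needs the alternative model whose intervention-arm
    curves were refit with unit weights (supplied by the pipeline);
    ``horizon_36m`` runs 39 complete 28-day cycles; ``death_risk_4x``
    raises the background-mortality multiplier to 4; the utility
    scenarios swap in the alternative utility sets.
    """
    if scenario_id not in SCENARIO_IDS:
        raise ValueError(f"unknown scenario {scenario_id!r}")
    if scenario_id == "no_maic":
        if no_maic_model is None:
            raise ValueError("no_maic scenario requires the unweighted model")
        return no_maic_model.evaluate()
    if scenario_id == "horizon_36m":
        return model.evaluate(horizon=CYCLES_36M)
    if scenario_id == "death_risk_4x":
        return model.evaluate(k=4.0)
    key = scenario_id.removeprefix("utilities_")
    if utilities_bank is None or key not in utilities_bank:
        raise ValueError(f"utility set {key!r} not available")
    return model.evaluate(utilities=utilities_bank[key])
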