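"""Composition of the decision model: extrapolated curves in, ICER out.

:class:`CEModel` holds everything needed to evaluate the economic model —
the four fitted survival objects (intervention/comparator x PFS/OS), the
life table, floor multiplier, cohort demographics, cost and utility
inputs — and re-evaluates the full chain (discretize -> mortality floor
-> transitions -> trace -> costs/QALYs -> ICER) for any perturbation of
those inputs.  The sensitivity-analysis machinery in
:mod:`oncocea.uncertainty` works entirely through this class.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from oncocea import economics as econ
from oncocea.economics import CEResult, CostInputs, UtilityInputs
from oncocea.markov_engine import derive_transitions, run_cohort
from oncocea.survival_models import (
    FAMILIES,
    CureFit,
    LifeTable,
    SurvivalFit,
    apply_mortality_floor,
    discretize,
)

__all__ = ["CEModel", "with_theta"]


def with_theta(fit, theta: np.ndarray):
    """A copy of a fitted survival object with new unconstrained parameters.

    Used by the PSA to propagate multivariate-normal parameter draws;
    natural-scale parameters are recomputed through the family's
    back-transform.
    """
    theta = np.asarray(theta, dtype=float)
    if isinstance(fit, CureFit):
        from scipy.special import expit

        latent = with_theta(fit.latent, theta[1:])
        return replace(fit, pi=float(expit(theta[0])), latent=latent, theta=theta)
    fam = FAMILIES[fit.family]
    return replace(fit, theta=theta, params=tuple(fam.natural(theta)))


@dataclass
class CEModel:
    """The assembled cost-effectiveness model for two treatment arms."""

    fits: dict  # keys: intervention_pfs, intervention_os, comparator_pfs, comparator_os
    life_table: LifeTable
    start_age: float
    male_prop: float
    death_risk_multiplier: float
    max_cycles: int
    cost_inputs: dict  # keys: intervention, comparator -> CostInputs
    utilities: UtilityInputs
    discount_cost: float = 0.05
    discount_outcome: float = 0.05
    wtp: float = 36036.0
    arm_names: dict = field(
        default_factory=lambda: {
            "intervention": "serplulimab",
            "comparator": "regorafenib",
        }
    )

    def curves(self, arm: str, k: float | None = None, fits: dict | None = None):
        """Floored (PFS, OS) cycle-survival curves for one arm."""
        k = self.death_risk_multiplier if k is None else k
        fits = self.fits if fits is None else fits
        out = []
        for endpoint in ("pfs", "os"):
            fit = fits[f"{arm}_{endpoint}"]
            floored = apply_mortality_floor(
                fit, self.life_table, self.start_age, self.male_prop, k, self.max_cycles
            )
            out.append(floored)
        return tuple(out)

    def trace(self, arm: str, horizon="lifetime", k: float | None = None,
              fits: dict | None = None):
        s_pfs, s_os = self.curves(arm, k=k, fits=fits)
        schedule = derive_transitions(s_pfs, s_os)
        return run_cohort(schedule, horizon=horizon), schedule

    def evaluate(
        self,
        horizon="lifetime",
        k: float | None = None,
        utilities: UtilityInputs | None = None,
        cost_inputs: dict | None = None,
        fits: dict | None = None,
        discount_cost: float | None = None,
        discount_outcome: float | None = None,
    ) -> CEResult:
        """Run both arms and return the incremental result."""
        utilities = utilities or self.utilities
        cost_inputs = cost_inputs or self.cost_inputs
        dc = self.discount_cost if discount_cost is None else discount_cost
        do = self.discount_outcome if discount_outcome is None else discount_outcome
        arm_results = {}
        for arm in ("intervention", "comparator"):
            trace, _ = self.trace(arm, horizon=horizon, k=k, fits=fits)
            arm_results[arm] = econ.evaluate_arm(
                self.arm_names[arm], trace, cost_inputs[arm], utilities,
                discount_cost=dc, discount_outcome=do,
            )
        return econ.compute_icer(
            arm_results["intervention"], arm_results["comparator"], wtp=self.wtp
        )

    def copy(self) -> "CEModel":
        return copy.deepcopy(self)
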