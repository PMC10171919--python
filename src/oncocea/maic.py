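"""Unanchored matching-adjusted indirect comparison (MAIC).

When two single-arm bodies of evidence must be compared without a shared
control arm, the trial with patient-level data is reweighted so that its
baseline covariate moments match the comparator trial's published
aggregates.  Weights take the entropy-balancing / propensity-score form

    w_i = exp(alpha' (x_i - x_target)),

with ``alpha`` solving the method-of-moments condition
``sum_i w_i (x_i - x_target) = 0``.  That condition is the stationarity
condition of the strictly convex objective ``Q(alpha) = sum_i exp(alpha'
(x_i - x_target))``, which is minimized here with an analytic gradient.

The weighted sample's information content is summarized by the effective
sample size ESS = (sum w)^2 / sum w^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from oncocea.synthetic_cohort import TrialSummary, covariate_matrix

__all__ = ["MAICResult", "WeightedCohort", "fit_weights", "apply_weights"]


class MAICConvergenceError(RuntimeError):
    """Raised when the moment conditions cannot be satisfied."""


@dataclass
class MAICResult:
    alpha: np.ndarray
    weights: np.ndarray  # normalized to sum to n (frequency convention)
    ess: float
    matched_covariates: list[str]
    achieved_means: dict[str, float]
    target_means: dict[str, float]
    grad_norm: float

    def to_frame(self, ids: Sequence[str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"weight": self.weights})
        if ids is not None:
            df.insert(0, "id", list(ids))
        return df


@dataclass
class WeightedCohort:
    """A cohort plus per-subject frequency weights, consumed downstream.

    ``km_estimate`` and the survival fitters accept this handle; weights
    propagate as frequency weights into risk sets and likelihoods.
    """

    records: pd.DataFrame
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.records):
            raise ValueError("weights length must match cohort size")


def _check_support(X: np.ndarray, targets: np.ndarray, names: Sequence[str]) -> None:
    for j, name in enumerate(names):
        lo, hi = X[:, j].min(), X[:, j].max()
        if not (lo < targets[j] < hi) and not np.isclose(lo, hi):
            if targets[j] <= lo or targets[j] >= hi:
                raise MAICConvergenceError(
                    f"target mean for {name!r} ({targets[j]}) lies outside the "
                    f"open support ({lo}, {hi}) of the sample; reweighting "
                    "cannot reach it"
                )


def _check_collinearity(Z: np.ndarray, names: Sequence[str]) -> None:
    _, s, vt = np.linalg.svd(Z - Z.mean(axis=0), full_matrices=False)
    if s[-1] < 1e-10 * max(s[0], 1.0):
        dep = int(np.argmax(np.abs(vt[-1])))
        raise MAICConvergenceError(
            f"matched covariates are collinear; column {names[dep]!r} is "
            "linearly dependent on the others"
        )


def fit_weights(
    records: pd.DataFrame,
    targets: TrialSummary,
    covariates: Sequence[str],
    tol: float = 1e-8,
) -> MAICResult:
    """Solve for MAIC weights matching the comparator's baseline moments.

    Parameters
    ----------
    records:
        Intervention-arm cohort (no missing values in matched covariates).
    targets:
        Published aggregate baseline of the comparator population.
    covariates:
        Names of covariates to match (subset of the packaged encoding:
        ``age``, ``male``, ``ecog1``, ``histology_adeno``, ``liver_met``,
        ``prior_lines_ge2``, ``prior_targeted``).
    tol:
        Convergence threshold on the infinity norm of the gradient of Q
        evaluated on standardized covariates.
    """
    covariates = list(covariates)
    missing = [c for c in covariates if c not in targets.covariate_means]
    if missing:
        raise ValueError(f"targets lack covariates: {missing}")
    X = covariate_matrix(records, covariates)
    if np.isnan(X).any():
        raise ValueError("matched covariates contain missing values")
    tgt = np.array([targets.covariate_means[c] for c in covariates], dtype=float)
    _check_support(X, tgt, covariates)
    _check_collinearity(X, covariates)

    # Standardize for conditioning; alpha is mapped back afterwards.
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (X - tgt) / scale

    n = len(X)

    def objective(a: np.ndarray):
        e = np.exp(Z @ a)
        return e.sum(), Z.T @ e

    res = minimize(
        objective,
        x0=np.zeros(Z.shape[1]),
        jac=True,
        method="BFGS",
        options={"gtol": tol / 10.0, "maxiter": 1000},
    )
    grad_norm = float(np.max(np.abs(res.jac)))
    if grad_norm > max(tol, 1e-6) * n:
        raise MAICConvergenceError(
            f"moment conditions not satisfied (gradient inf-norm {grad_norm:.3g}); "
            "check that every target is attainable in this sample"
        )
    alpha = res.x / scale
    raw = np.exp((X - tgt) @ alpha)
    weights = raw * (n / raw.sum())
    ess = float(weights.sum() ** 2 / np.sum(weights**2))
    achieved = {
        c: float(np.sum(weights * X[:, j]) / weights.sum())
        for j, c in enumerate(covariates)
    }
    return MAICResult(
        alpha=alpha,
        weights=weights,
        ess=ess,
        matched_covariates=covariates,
        achieved_means=achieved,
        target_means=dict(zip(covariates, tgt)),
        grad_norm=grad_norm,
    )


def apply_weights(records: pd.DataFrame, maic: MAICResult) -> WeightedCohort:
    """Bundle a cohort with its MAIC weights for downstream estimation."""
    return WeightedCohort(records=records, weights=maic.weights)
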