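"""Seeded synthetic trial data with the structure the analysis assumes.

The real patient-level data behind the intervention arm (a single-arm
anti-PD-1 trial in MSI-H/dMMR colorectal cancer) is not public, and the
comparator evidence exists only as published Kaplan-Meier figures.  This
module generates stand-ins with the same statistical anatomy so that every
downstream stage — reconstruction, MAIC reweighting, parametric and
mixture-cure fitting, the Markov model — can be exercised and tested
end to end:

* overall survival follows a cure mixture: a Bernoulli "cured" flag
  (logistic in the baseline covariates) gives long-term survivors whose
  death time is beyond any trial horizon, while the uncured draw from a
  conventional parametric latent distribution;
* progression-free survival is drawn conditionally so that it never
  exceeds overall survival;
* censoring is administrative: uniform accrual plus a fixed follow-up
  window, with optional exponential dropout.

All times are in months.  Cohorts are plain :class:`pandas.DataFrame`
objects with one row per subject and the column convention of
:data:`IPD_COLUMNS`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortGenConfig",
    "TrialSummary",
    "IPD_COLUMNS",
    "COVARIATES",
    "generate_ipd",
    "generate_aggregate_trial",
    "summarize_baseline",
]

#: Column convention for individual patient data frames.
IPD_COLUMNS = [
    "id",
    "arm",
    "age",
    "sex",
    "ecog",
    "histology_adeno",
    "liver_met",
    "prior_lines_ge2",
    "prior_targeted",
    "pfs_time",
    "pfs_event",
    "os_time",
    "os_event",
]

#: Binary/continuous covariates available for MAIC matching.
COVARIATES = [
    "age",
    "male",
    "ecog1",
    "histology_adeno",
    "liver_met",
    "prior_lines_ge2",
    "prior_targeted",
]

# A practically-infinite event time (months); cured subjects "die" here
# so that administrative censoring always wins.
_FAR_FUTURE = 1.0e9


@dataclass
class TrialSummary:
    """Aggregate baseline description of a trial population."""

    n: int
    covariate_means: dict[str, float]

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("TrialSummary.n must be positive")
        for name, v in self.covariate_means.items():
            if name != "age" and not (0.0 <= v <= 1.0):
                raise ValueError(
                    f"proportion for covariate {name!r} outside [0, 1]: {v}"
                )


@dataclass
class CohortGenConfig:
    """Data-generating configuration for one synthetic arm.

    Parameters
    ----------
    n:
        Number of subjects.
    seed:
        Integer RNG seed; fixed seed gives byte-identical cohorts.
    cure_fraction:
        Marginal probability of belonging to the long-term-survivor
        (cured) component, in [0, 1).
    latent_os_family, latent_os_params:
        Distribution of uncured overall survival.  Families:
        ``exponential`` (rate), ``weibull`` (scale, shape),
        ``lognormal`` (mu, sigma), ``loglogistic`` (alpha, beta),
        ``gompertz`` (rate, shape).
    pfs_family, pfs_params:
        Latent progression-free survival distribution (same families).
    covariate_prevalences:
        Map covariate name -> prevalence (binary) or mean (``age``;
        spread set by ``age_sd``).
    covariate_effects:
        Map covariate name -> log-odds shift on the cure probability
        (covariates centred at their prevalence, so the marginal cure
        fraction stays near ``cure_fraction``).
    accrual_months, followup_months:
        Uniform accrual window and fixed post-accrual follow-up; subject
        i's administrative censoring time is
        ``followup + Uniform(0, accrual)``.  ``followup=inf`` disables
        censoring.
    long_pfs_prob:
        Probability that a cured subject is also a durable responder
        whose progression time exceeds follow-up (gives the PFS plateau).
    dropout_rate:
        Optional exponential dropout hazard per month (0 = none).
    """

    n: int
    seed: int
    cure_fraction: float = 0.0
    latent_os_family: str = "lognormal"
    latent_os_params: tuple[float, ...] = (2.2, 0.8)
    pfs_family: str = "weibull"
    pfs_params: tuple[float, ...] = (8.0, 1.2)
    covariate_prevalences: Mapping[str, float] = field(
        default_factory=lambda: {
            "age": 53.0,
            "male": 0.60,
            "ecog1": 0.70,
            "histology_adeno": 0.90,
            "liver_met": 0.45,
            "prior_lines_ge2": 0.55,
            "prior_targeted": 0.35,
        }
    )
    covariate_effects: Mapping[str, float] = field(default_factory=dict)
    accrual_months: float = 12.0
    followup_months: float = 36.0
    long_pfs_prob: float = 0.7
    dropout_rate: float = 0.0
    age_sd: float = 10.0
    arm: str = "serplulimab"

    def __post_init__(self) -> None:
        if not (0.0 <= self.cure_fraction < 1.0):
            raise ValueError("cure_fraction must lie in [0, 1)")
        if self.n <= 0:
            raise ValueError("n must be positive")
        for p in (*self.latent_os_params, *self.pfs_params):
            if p <= 0 and not (
                self.latent_os_family == "gompertz" or self.pfs_family == "gompertz"
            ):
                raise ValueError("distribution scale/shape parameters must be > 0")
        for name, v in self.covariate_prevalences.items():
            if name != "age" and not (0.0 <= v <= 1.0):
                raise ValueError(f"prevalence for {name!r} outside [0, 1]")
        if self.accrual_months < 0 or self.followup_months < 0:
            raise ValueError("accrual/followup must be nonnegative")
        if self.dropout_rate < 0:
            raise ValueError("dropout_rate must be nonnegative")


def _sample_times(
    rng: np.random.Generator, family: str, params: Sequence[float], size: int
) -> np.ndarray:
    """Inverse-CDF sampling for the supported latent families."""
    u = rng.uniform(size=size)
    if family == "exponential":
        (lam,) = params
        return -np.log(u) / lam
    if family == "weibull":
        scale, shape = params
        return scale * (-np.log(u)) ** (1.0 / shape)
    if family == "lognormal":
        mu, sigma = params
        from scipy.stats import norm

        return np.exp(mu + sigma * norm.ppf(1.0 - u))
    if family == "loglogistic":
        alpha, beta = params
        return alpha * ((1.0 - u) / u) ** (1.0 / beta)
    if family == "gompertz":
        lam, gamma = params
        if abs(gamma) < 1e-12:
            return -np.log(u) / lam
        inner = 1.0 - gamma * np.log(u) / lam
        t = np.where(inner > 0, np.log(np.maximum(inner, 1e-300)) / gamma, np.inf)
        return t
    raise ValueError(f"unknown latent family {family!r}")


def generate_ipd(config: CohortGenConfig) -> pd.DataFrame:
    """Generate one synthetic arm of individual patient data.

    Overall survival is drawn first (cure mixture); progression-free
    survival is then drawn truncated at the OS time, which guarantees
    ``pfs_time <= os_time`` row by row, exactly as real trial data obeys.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    prev = dict(config.covariate_prevalences)

    age = np.clip(rng.normal(prev.get("age", 53.0), config.age_sd, n), 18, 85)
    cov = {"age": age}
    for name in COVARIATES[1:]:
        cov[name] = (rng.uniform(size=n) < prev.get(name, 0.5)).astype(int)

    # Cure status: logistic with covariates centred at their prevalences.
    if config.cure_fraction > 0:
        eta = math.log(config.cure_fraction / (1 - config.cure_fraction))
    else:
        eta = -np.inf
    lin = np.full(n, eta, dtype=float)
    for name, beta in config.covariate_effects.items():
        centre = prev.get(name, 0.5)
        x = cov[name] / (50.0 if name == "age" else 1.0)
        c = centre / (50.0 if name == "age" else 1.0)
        lin = lin + beta * (x - c)
    p_cure = 1.0 / (1.0 + np.exp(-lin))
    cured = rng.uniform(size=n) < p_cure

    os_latent = _sample_times(
        rng, config.latent_os_family, config.latent_os_params, n
    )
    os_latent = np.where(cured, _FAR_FUTURE, os_latent)

    # PFS: inverse-CDF draw truncated at the subject's OS time.
    pfs_latent = np.empty(n)
    u = rng.uniform(size=n)
    for i in range(n):
        cap = os_latent[i]
        # Truncated draw via repeated inverse sampling on [0, F(cap)].
        pfs_latent[i] = _truncated_draw(
            config.pfs_family, config.pfs_params, cap, u[i]
        )
    long_pfs = cured & (rng.uniform(size=n) < config.long_pfs_prob)
    pfs_latent = np.where(long_pfs, _FAR_FUTURE, pfs_latent)

    censor = config.followup_months + rng.uniform(0, config.accrual_months, n)
    if config.dropout_rate > 0:
        dropout = rng.exponential(1.0 / config.dropout_rate, n)
        censor = np.minimum(censor, dropout)

    os_time = np.minimum(os_latent, censor)
    os_event = (os_latent <= censor).astype(int)
    pfs_time = np.minimum(pfs_latent, censor)
    pfs_event = (pfs_latent <= censor).astype(int)

    df = pd.DataFrame(
        {
            "id": [f"{config.arm[:3].upper()}-{i:04d}" for i in range(n)],
            "arm": config.arm,
            "age": np.round(age, 1),
            "sex": np.where(cov["male"] == 1, "male", "female"),
            "ecog": cov["ecog1"],
            "histology_adeno": cov["histology_adeno"],
            "liver_met": cov["liver_met"],
            "prior_lines_ge2": cov["prior_lines_ge2"],
            "prior_targeted": cov["prior_targeted"],
            "pfs_time": pfs_time,
            "pfs_event": pfs_event,
            "os_time": os_time,
            "os_event": os_event,
        }
    )
    return df


def _truncated_draw(
    family: str, params: Sequence[float], cap: float, u: float
) -> float:
    """Inverse-CDF draw from a latent family truncated to [0, cap]."""
    if not np.isfinite(cap) or cap >= _FAR_FUTURE:
        return float(_invert(family, params, u))
    f_cap = 1.0 - _survival(family, params, cap)
    if f_cap <= 0:
        return cap
    return float(_invert(family, params, u * f_cap))


def _survival(family: str, params: Sequence[float], t: float) -> float:
    if family == "exponential":
        return math.exp(-params[0] * t)
    if family == "weibull":
        scale, shape = params
        return math.exp(-((t / scale) ** shape))
    if family == "lognormal":
        from scipy.stats import norm

        mu, sigma = params
        return float(norm.sf((math.log(max(t, 1e-300)) - mu) / sigma))
    if family == "loglogistic":
        alpha, beta = params
        return 1.0 / (1.0 + (t / alpha) ** beta)
    if family == "gompertz":
        lam, gamma = params
        if abs(gamma) < 1e-12:
            return math.exp(-lam * t)
        return math.exp(-(lam / gamma) * (math.exp(gamma * t) - 1.0))
    raise ValueError(f"unknown latent family {family!r}")


def _invert(family: str, params: Sequence[float], q: float) -> float:
    """Quantile function: smallest t with F(t) = q."""
    q = min(max(q, 1e-15), 1 - 1e-15)
    if family == "exponential":
        return -math.log(1 - q) / params[0]
    if family == "weibull":
        scale, shape = params
        return scale * (-math.log(1 - q)) ** (1.0 / shape)
    if family == "lognormal":
        from scipy.stats import norm

        mu, sigma = params
        return math.exp(mu + sigma * norm.ppf(q))
    if family == "loglogistic":
        alpha, beta = params
        return alpha * (q / (1 - q)) ** (1.0 / beta)
    if family == "gompertz":
        lam, gamma = params
        if abs(gamma) < 1e-12:
            return -math.log(1 - q) / lam
        inner = 1.0 - gamma * math.log(1 - q) / lam
        if inner <= 0:
            return _FAR_FUTURE
        return math.log(inner) / gamma
    raise ValueError(f"unknown latent family {family!r}")


def generate_aggregate_trial(
    config: CohortGenConfig,
    readoff_times: Sequence[float],
    risk_table_times: Sequence[float] | None = None,
    endpoint: str = "os",
    return_hidden: bool = False,
    clip: bool = False,
):
    """Emulate published comparator evidence: digitized KM + risk table.

    A hidden cohort is simulated with :func:`generate_ipd`; its KM
    estimate is read off at ``readoff_times`` (as a curve digitizer
    would) and numbers at risk are tabulated at ``risk_table_times``.

    Returns a :class:`oncocea.km_tools.DigitizedKM`; with
    ``return_hidden=True`` the tuple ``(digitized, hidden_cohort)`` so
    tests can use the hidden cohort as ground truth.
    """
    from oncocea.km_tools import DigitizedKM, km_estimate

    hidden = generate_ipd(config)
    step = km_estimate(hidden, endpoint=endpoint)
    max_follow = float(hidden[f"{endpoint}_time"].max())
    readoff_times = np.asarray(sorted(readoff_times), dtype=float)
    if readoff_times[-1] > max_follow:
        if not clip:
            raise ValueError(
                f"readoff time {readoff_times[-1]} beyond last follow-up "
                f"{max_follow:.2f}"
            )
        # a digitizer can only read the curve where it is drawn
        readoff_times = readoff_times[readoff_times <= max_follow]
        if risk_table_times is not None:
            risk_table_times = [t for t in risk_table_times if t <= max_follow]
    surv = step.evaluate(readoff_times)

    if risk_table_times is None:
        risk_table_times = readoff_times
    risk_table_times = np.asarray(sorted(risk_table_times), dtype=float)
    times = hidden[f"{endpoint}_time"].to_numpy()
    n_risk = [(times >= t).sum() for t in risk_table_times]
    flags = hidden[f"{endpoint}_event"].to_numpy()
    # events visible within the digitized span (what a figure reports)
    events = int(flags[times <= readoff_times[-1]].sum())

    dk = DigitizedKM(
        curve_points=list(zip(readoff_times.tolist(), surv.tolist())),
        risk_table=list(zip(risk_table_times.tolist(), n_risk)),
        total_events=events,
    )
    if return_hidden:
        return dk, hidden
    return dk


def summarize_baseline(records: pd.DataFrame) -> TrialSummary:
    """Means/proportions of the MAIC covariates over non-missing values."""
    if len(records) == 0:
        raise ValueError("cannot summarize an empty cohort")
    df = records
    means: dict[str, float] = {}
    means["age"] = float(df["age"].mean())
    means["male"] = float((df["sex"] == "male").mean())
    means["ecog1"] = float((df["ecog"] == 1).mean())
    for name in ("histology_adeno", "liver_met", "prior_lines_ge2", "prior_targeted"):
        means[name] = float(df[name].mean())
    return TrialSummary(n=len(df), covariate_means=means)


def covariate_matrix(records: pd.DataFrame, covariates: Sequence[str]) -> np.ndarray:
    """Design matrix with MAIC covariate encoding (indicators for binaries)."""
    cols = []
    for name in covariates:
        if name == "age":
            cols.append(records["age"].to_numpy(dtype=float))
        elif name == "male":
            cols.append((records["sex"] == "male").to_numpy(dtype=float))
        elif name == "ecog1":
            cols.append((records["ecog"] == 1).to_numpy(dtype=float))
        else:
            cols.append(records[name].to_numpy(dtype=float))
    return np.column_stack(cols)
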