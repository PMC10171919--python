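"""Parametric survival fitting, mixture-cure extrapolation and the
background-mortality floor.

Six standard families (exponential, gamma, Weibull, log-normal,
log-logistic, Gompertz) are fitted by maximum likelihood to right-censored,
optionally frequency-weighted data, ranked by AIC/BIC, and extrapolated
over a lifetime horizon.  For an immature curve with a survivor plateau a
mixture cure model ``S(t) = pi + (1 - pi) * S_u(t)`` is available, and all
extrapolations can be floored by (a multiple of) general-population
mortality taken from a life table, which guarantees that even a cure
plateau eventually decays.

Parameterizations (t in months):

==============  =======================  ==========================
family          natural parameters       survival function
==============  =======================  ==========================
exponential     rate ``lam``             ``exp(-lam*t)``
weibull         scale ``sigma``,         ``exp(-(t/sigma)**kappa)``
                shape ``kappa``
gamma           shape ``a``, rate ``r``  regularized upper incomplete gamma
lognormal       ``mu``, ``sigma``        ``1 - Phi((ln t - mu)/sigma)``
loglogistic     scale ``alpha``,         ``1/(1 + (t/alpha)**beta)``
                shape ``beta``
gompertz        rate ``lam``,            ``exp(-(lam/gamma)*(exp(gamma*t)-1))``
                shape ``gamma``
==============  =======================  ==========================

Optimization runs on unconstrained scales (log for positive parameters,
logit for the cure probability); the parameter covariance reported in
``vcov`` is the inverse observed information on that unconstrained scale,
which is the scale on which probabilistic sensitivity analysis draws
multivariate-normal parameter vectors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import gamma as gamma_dist
from scipy.stats import norm

__all__ = [
    "FAMILIES",
    "SurvivalFit",
    "CureFit",
    "LifeTable",
    "CycleSurvival",
    "fit_parametric",
    "fit_mixture_cure",
    "select_best",
    "survival_at",
    "hazard_at",
    "apply_mortality_floor",
    "DAYS_PER_MONTH",
    "CYCLE_DAYS",
]

DAYS_PER_MONTH = 365.25 / 12.0  # 30.4375
CYCLE_DAYS = 28.0
CYCLE_MONTHS = CYCLE_DAYS / DAYS_PER_MONTH


class FitError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# family definitions on the unconstrained scale
# ---------------------------------------------------------------------------

def _exp_natural(th):
    return (math.exp(th[0]),)


def _exp_logS(t, p):
    (lam,) = p
    return -lam * t


def _exp_logf(t, p):
    (lam,) = p
    return math.log(lam) - lam * t


def _wei_natural(th):
    return (math.exp(th[0]), math.exp(th[1]))


def _wei_logS(t, p):
    sigma, kappa = p
    return -((t / sigma) ** kappa)


def _wei_logf(t, p):
    sigma, kappa = p
    lt = np.log(t / sigma)
    return math.log(kappa / sigma) + (kappa - 1.0) * lt - (t / sigma) ** kappa


def _gam_natural(th):
    return (math.exp(th[0]), math.exp(th[1]))


def _gam_logS(t, p):
    a, r = p
    return gamma_dist.logsf(t, a, scale=1.0 / r)


def _gam_logf(t, p):
    a, r = p
    return gamma_dist.logpdf(t, a, scale=1.0 / r)


def _lnorm_natural(th):
    return (th[0], math.exp(th[1]))


def _lnorm_logS(t, p):
    mu, sigma = p
    return norm.logsf((np.log(t) - mu) / sigma)


def _lnorm_logf(t, p):
    mu, sigma = p
    z = (np.log(t) - mu) / sigma
    return norm.logpdf(z) - np.log(t * sigma)


def _llog_natural(th):
    return (math.exp(th[0]), math.exp(th[1]))


def _llog_logS(t, p):
    alpha, beta = p
    return -np.log1p((t / alpha) ** beta)


def _llog_logf(t, p):
    alpha, beta = p
    lt = np.log(t / alpha)
    return (
        math.log(beta / alpha)
        + (beta - 1.0) * lt
        - 2.0 * np.log1p((t / alpha) ** beta)
    )


def _gomp_natural(th):
    return (math.exp(th[0]), th[1])


def _gomp_logS(t, p):
    lam, g = p
    if abs(g) < 1e-10:
        return -lam * t
    return -(lam / g) * np.expm1(g * t)


def _gomp_logf(t, p):
    lam, g = p
    return math.log(lam) + g * t + _gomp_logS(t, p)


@dataclass(frozen=True)
class _Family:
    name: str
    k: int
    natural: Callable
    logS: Callable
    logf: Callable
    param_names: tuple[str, ...]


FAMILIES: dict[str, _Family] = {
    "exponential": _Family("exponential", 1, _exp_natural, _exp_logS, _exp_logf, ("rate",)),
    "weibull": _Family("weibull", 2, _wei_natural, _wei_logS, _wei_logf, ("scale", "shape")),
    "gamma": _Family("gamma", 2, _gam_natural, _gam_logS, _gam_logf, ("shape", "rate")),
    "lognormal": _Family("lognormal", 2, _lnorm_natural, _lnorm_logS, _lnorm_logf, ("mu", "sigma")),
    "loglogistic": _Family("loglogistic", 2, _llog_natural, _llog_logS, _llog_logf, ("scale", "shape")),
    "gompertz": _Family("gompertz", 2, _gomp_natural, _gomp_logS, _gomp_logf, ("rate", "shape")),
}


# ---------------------------------------------------------------------------
# fit containers
# ---------------------------------------------------------------------------

@dataclass
class SurvivalFit:
    family: str
    params: tuple[float, ...]  # natural scale
    theta: np.ndarray  # unconstrained scale
    loglik: float
    aic: float
    bic: float
    vcov: np.ndarray  # on the unconstrained (theta) scale
    n_eff: float
    converged: bool = True

    @property
    def k(self) -> int:
        return len(self.theta)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "params": list(self.params),
            "theta": self.theta.tolist(),
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "vcov": self.vcov.tolist(),
            "n_eff": self.n_eff,
        }


@dataclass
class CureFit:
    """Mixture cure fit: S(t) = pi + (1 - pi) * S_latent(t)."""

    pi: float
    latent: SurvivalFit
    theta: np.ndarray  # (logit pi, latent theta)
    loglik: float
    aic: float
    bic: float
    vcov: np.ndarray
    n_eff: float
    boundary: bool = False  # pi pinned near 0 or 1

    @property
    def family(self) -> str:
        return f"curemix_{self.latent.family}"

    @property
    def k(self) -> int:
        return len(self.theta)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "pi": self.pi,
            "latent": self.latent.to_dict(),
            "theta": self.theta.tolist(),
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "vcov": self.vcov.tolist(),
            "n_eff": self.n_eff,
            "boundary": self.boundary,
        }


# ---------------------------------------------------------------------------
# data extraction
# ---------------------------------------------------------------------------

def _extract(cohort, endpoint: str):
    """(times, events, weights) from a DataFrame or WeightedCohort."""
    from oncocea.maic import WeightedCohort

    if isinstance(cohort, WeightedCohort):
        df, w = cohort.records, cohort.weights
    else:
        df, w = cohort, None
    t = df[f"{endpoint}_time"].to_numpy(dtype=float)
    d = df[f"{endpoint}_event"].to_numpy(dtype=float)
    if w is None:
        w = np.ones_like(t)
    else:
        w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    keep = w > 0
    return t[keep], d[keep], w[keep]


def _nll_factory(fam: _Family, t, d, w):
    t = np.maximum(t, 1e-8)  # guard exact zeros for log-time families

    def nll(theta):
        try:
            p = fam.natural(theta)
        except OverflowError:
            return 1e12
        with np.errstate(all="ignore"):
            ls = fam.logS(t, p)
            lf = fam.logf(t, p)
            val = -(w * (d * lf + (1 - d) * ls)).sum()
        if not np.isfinite(val):
            return 1e12
        return float(val)

    return nll


def _numeric_hessian(f, x, eps=1e-5):
    n = len(x)
    H = np.zeros((n, n))
    h = eps * (1.0 + np.abs(x))
    for i in range(n):
        for j in range(i, n):
            xpp = x.copy(); xpp[i] += h[i]; xpp[j] += h[j]
            xpm = x.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
            xmp = x.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
            xmm = x.copy(); xmm[i] -= h[i]; xmm[j] -= h[j]
            H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (
                4.0 * h[i] * h[j]
            )
    return H


def _safe_vcov(nll, theta):
    H = _numeric_hessian(nll, theta)
    H = 0.5 * (H + H.T)
    try:
        vcov = np.linalg.inv(H)
        ev = np.linalg.eigvalsh(vcov)
        if np.any(ev < 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(H)
        w_, v_ = np.linalg.eigh(0.5 * (vcov + vcov.T))
        vcov = (v_ * np.clip(w_, 0.0, None)) @ v_.T
    return 0.5 * (vcov + vcov.T)


def _starts(family: str, t, d, w) -> list[np.ndarray]:
    events = d > 0
    mt = float(np.average(t[events], weights=w[events])) if events.any() else float(
        np.average(t, weights=w)
    )
    mt = max(mt, 1e-3)
    log_rate = math.log(1.0 / mt)
    base = {
        "exponential": [np.array([log_rate])],
        "weibull": [np.array([math.log(mt), 0.0]), np.array([math.log(mt), 0.5])],
        "gamma": [np.array([0.0, log_rate]), np.array([0.5, log_rate])],
        "lognormal": [
            np.array([math.log(mt), 0.0]),
            np.array([math.log(mt), -0.5]),
        ],
        "loglogistic": [np.array([math.log(mt), 0.0]), np.array([math.log(mt), 0.7])],
        "gompertz": [
            np.array([log_rate, 0.01]),
            np.array([log_rate, -0.01]),
            np.array([log_rate, 0.1]),
        ],
    }
    return base[family]


def fit_parametric(cohort, endpoint: str, family: str) -> SurvivalFit:
    """Maximum-likelihood fit of one parametric family.

    ``cohort`` is a cohort DataFrame or a
    :class:`oncocea.maic.WeightedCohort`; weights act as frequency
    weights in the likelihood and in the effective sample size used by
    BIC.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    fam = FAMILIES[family]
    t, d, w = _extract(cohort, endpoint)
    if (d * w).sum() <= 0:
        raise FitError("no events: parametric fit is unidentified")
    nll = _nll_factory(fam, t, d, w)

    best = None
    for x0 in _starts(family, t, d, w):
        res = minimize(nll, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
        res2 = minimize(nll, res.x, method="BFGS",
                        options={"gtol": 1e-10, "maxiter": 500})
        cand = res2 if res2.fun <= res.fun else res
        if best is None or cand.fun < best.fun:
            best = cand
    if best is None or not np.isfinite(best.fun):
        raise FitError(f"fit of {family} failed to converge")

    theta = np.asarray(best.x, dtype=float)
    ll = -float(best.fun)
    n_eff = float(w.sum())
    k = fam.k
    vcov = _safe_vcov(nll, theta)
    return SurvivalFit(
        family=family,
        params=tuple(fam.natural(theta)),
        theta=theta,
        loglik=ll,
        aic=2 * k - 2 * ll,
        bic=k * math.log(n_eff) - 2 * ll,
        vcov=vcov,
        n_eff=n_eff,
        converged=bool(best.success) if hasattr(best, "success") else True,
    )


def fit_mixture_cure(
    cohort,
    endpoint: str,
    latent_family: str = "lognormal",
    pi_grid: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7),
) -> CureFit:
    """Fit the mixture cure model S(t) = pi + (1-pi) * S_u(t).

    The optimizer runs on (logit pi, latent unconstrained parameters)
    with a multi-start grid over the cure probability.  A fit whose cure
    probability is pinned at the boundary is flagged (``boundary=True``)
    rather than rejected.
    """
    if latent_family not in FAMILIES:
        raise ValueError(f"unknown family {latent_family!r}")
    fam = FAMILIES[latent_family]
    t, d, w = _extract(cohort, endpoint)
    if (d * w).sum() <= 0:
        raise FitError("no events: cure fit is unidentified")
    t = np.maximum(t, 1e-8)

    # Identifiability warning: plateau requires follow-up past most events
    last_event = t[d > 0].max()
    if last_event >= t.max() - 1e-9:
        warnings.warn(
            "longest follow-up time is an event; the cure plateau may not "
            "be identifiable",
            stacklevel=2,
        )

    def nll(theta):
        pi = expit(theta[0])
        try:
            p = fam.natural(theta[1:])
        except OverflowError:
            return 1e12
        with np.errstate(all="ignore"):
            Su = np.exp(fam.logS(t, p))
            lf = math.log(max(1.0 - pi, 1e-300)) + fam.logf(t, p)
            lS = np.log(np.maximum(pi + (1.0 - pi) * Su, 1e-300))
            val = -(w * (d * lf + (1 - d) * lS)).sum()
        if not np.isfinite(val):
            return 1e12
        return float(val)

    latent_starts = _starts(latent_family, t, d, w)
    best = None
    for pi0 in pi_grid:
        for ls in latent_starts:
            x0 = np.concatenate([[logit(pi0)], ls])
            res = minimize(nll, x0, method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 6000})
            res2 = minimize(nll, res.x, method="BFGS",
                            options={"gtol": 1e-10, "maxiter": 500})
            cand = res2 if res2.fun <= res.fun else res
            if best is None or cand.fun < best.fun:
                best = cand
    theta = np.asarray(best.x, dtype=float)
    pi = float(expit(theta[0]))
    ll = -float(best.fun)
    n_eff = float(w.sum())
    k = 1 + fam.k
    vcov = _safe_vcov(nll, theta)
    latent_theta = theta[1:]
    latent_fit = SurvivalFit(
        family=latent_family,
        params=tuple(fam.natural(latent_theta)),
        theta=latent_theta,
        loglik=float("nan"),
        aic=float("nan"),
        bic=float("nan"),
        vcov=vcov[1:, 1:],
        n_eff=n_eff,
    )
    return CureFit(
        pi=pi,
        latent=latent_fit,
        theta=theta,
        loglik=ll,
        aic=2 * k - 2 * ll,
        bic=k * math.log(n_eff) - 2 * ll,
        vcov=vcov,
        n_eff=n_eff,
        boundary=bool(pi < 1e-4 or pi > 1 - 1e-4),
    )


def select_best(fits: Sequence, override: str | None = None):
    """Rank fits by AIC (ties under 0.01 go to the smaller model).

    Returns ``(best_fit, ranking)`` where ``ranking`` is a DataFrame
    with family, k, loglik, AIC and BIC, AIC-ascending.  ``override``
    forces a named family (visual-inspection override) while still
    attaching the full ranking.
    """
    if not fits:
        raise ValueError("no fits to select from")
    rows = [
        {"family": f.family, "k": f.k, "loglik": f.loglik, "aic": f.aic, "bic": f.bic}
        for f in fits
    ]
    ranking = (
        pd.DataFrame(rows)
        .sort_values(["aic", "k"], kind="stable")
        .reset_index(drop=True)
    )
    ordered = sorted(fits, key=lambda f: (round(f.aic / 0.01) * 0.01, f.k))
    best = ordered[0]
    if override is not None:
        named = [f for f in fits if f.family == override]
        if not named:
            raise ValueError(f"override family {override!r} not among fits")
        best = named[0]
    return best, ranking


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def survival_at(fit, t):
    """S(t) for a SurvivalFit or CureFit (vectorized, S(0)=1)."""
    t = np.asarray(t, dtype=float)
    if isinstance(fit, CureFit):
        su = np.exp(FAMILIES[fit.latent.family].logS(np.maximum(t, 0.0), fit.latent.params))
        out = fit.pi + (1.0 - fit.pi) * su
    else:
        out = np.exp(FAMILIES[fit.family].logS(np.maximum(t, 0.0), fit.params))
    return np.where(t <= 0, 1.0, out)


def hazard_at(fit, t):
    """Instantaneous hazard f(t)/S(t), guarded against S underflow."""
    t = np.asarray(t, dtype=float)
    tt = np.maximum(t, 1e-12)
    if isinstance(fit, CureFit):
        fam = FAMILIES[fit.latent.family]
        fu = (1.0 - fit.pi) * np.exp(fam.logf(tt, fit.latent.params))
        S = np.maximum(survival_at(fit, tt), 1e-300)
        return fu / S
    fam = FAMILIES[fit.family]
    f = np.exp(fam.logf(tt, fit.params))
    S = np.maximum(np.exp(fam.logS(tt, fit.params)), 1e-300)
    return f / S


# ---------------------------------------------------------------------------
# life table and mortality floor
# ---------------------------------------------------------------------------

@dataclass
class LifeTable:
    """General-population annual death probabilities by age and sex."""

    table: pd.DataFrame  # columns: age, sex, qx

    def __post_init__(self) -> None:
        df = self.table
        req = {"age", "sex", "qx"}
        if not req.issubset(df.columns):
            raise ValueError(f"life table needs columns {sorted(req)}")
        if ((df["qx"] < 0) | (df["qx"] > 1)).any():
            raise ValueError("life table qx outside [0, 1]")
        for sex, grp in df.groupby("sex"):
            ages = np.sort(grp["age"].to_numpy())
            if not np.array_equal(ages, np.arange(ages[0], ages[-1] + 1)):
                raise ValueError(f"life table ages not contiguous for sex {sex!r}")
            terminal = grp.loc[grp["age"].idxmax(), "qx"]
            if terminal < 1.0:
                raise ValueError("life table must close with qx=1 at terminal age")
        self._qx = {
            sex: grp.set_index("age")["qx"].to_dict()
            for sex, grp in df.groupby("sex")
        }
        self._max_age = {sex: max(q) for sex, q in self._qx.items()}
        self._min_age = {sex: min(q) for sex, q in self._qx.items()}

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        return cls(pd.read_csv(path))

    def annual_qx(self, age: float, male_prop: float) -> float:
        """Sex-mix-averaged annual death probability at attained age."""
        out = 0.0
        for sex, share in (("male", male_prop), ("female", 1.0 - male_prop)):
            if share == 0.0:
                continue
            a = int(math.floor(age))
            if a < self._min_age[sex]:
                raise ValueError(f"age {age} below life table range")
            a = min(a, self._max_age[sex])
            out += share * self._qx[sex][a]
        return out


@dataclass
class CycleSurvival:
    """Survival evaluated on 4-week cycle boundaries; S[0] = 1."""

    values: np.ndarray
    cycle_length_days: float = CYCLE_DAYS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if abs(self.values[0] - 1.0) > 1e-12:
            raise ValueError("cycle survival must start at 1")
        if np.any(np.diff(self.values) > 1e-12):
            raise ValueError("cycle survival must be nonincreasing")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times_months(self) -> np.ndarray:
        return np.arange(len(self.values)) * (self.cycle_length_days / DAYS_PER_MONTH)


def discretize(fit_or_callable, n_cycles: int) -> CycleSurvival:
    """Evaluate a model survival function on cycle boundaries (months)."""
    tm = np.arange(n_cycles + 1) * CYCLE_MONTHS
    if callable(fit_or_callable):
        vals = np.asarray([float(fit_or_callable(t)) for t in tm])
    else:
        vals = np.asarray(survival_at(fit_or_callable, tm), dtype=float)
    vals = np.minimum.accumulate(np.clip(vals, 0.0, 1.0))
    vals[0] = 1.0
    return CycleSurvival(values=vals)


def apply_mortality_floor(
    s_model,
    life_table: LifeTable,
    start_age: float,
    male_prop: float,
    k: float,
    n_cycles: int,
) -> CycleSurvival:
    """Floor a model survival curve with k-fold general-population mortality.

    Per cycle j the model's conditional death probability
    ``1 - S(t_{j+1})/S(t_j)`` is compared with the k-fold population
    cycle death probability ``1 - (1 - d_pop)**k`` (where ``d_pop``
    converts the annual qx at the attained age to a 28-day probability);
    the larger of the two applies.  The composition acts on per-cycle
    conditional probabilities, matching the discrete grid the Markov
    model runs on.  The floored curve always reaches zero as the life
    table closes, even for cure models.
    """
    if k < 1:
        raise ValueError("mortality multiplier k must be >= 1")
    base = discretize(s_model, n_cycles) if not isinstance(s_model, CycleSurvival) else s_model
    vals = base.values
    out = np.ones(len(vals))
    frac_year = CYCLE_DAYS / 365.25
    for j in range(len(vals) - 1):
        if vals[j] <= 0:
            d_model = 1.0
        else:
            d_model = 1.0 - vals[j + 1] / vals[j]
        age = start_age + j * frac_year
        qx = life_table.annual_qx(age, male_prop)
        d_pop = 1.0 - (1.0 - qx) ** frac_year
        d_star = max(d_model, 1.0 - (1.0 - d_pop) ** k)
        out[j + 1] = out[j] * (1.0 - min(max(d_star, 0.0), 1.0))
    return CycleSurvival(values=out)
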