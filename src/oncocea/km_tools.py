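"""Kaplan-Meier estimation and pseudo-IPD reconstruction from published curves.

Indirect comparisons against older trials usually have to work from the
published survival figure rather than patient-level data.  This module
provides the two halves of that workflow:

* :func:`km_estimate` — (optionally weighted) product-limit estimation
  with Greenwood variance, built on :class:`lifelines.KaplanMeierFitter`;
* :func:`reconstruct_ipd` — the iterative algorithm of Guyot and
  colleagues that recovers pseudo individual patient data (event and
  censoring times) from digitized curve coordinates plus the
  numbers-at-risk table printed under the figure.

Times are months throughout; conversion to model cycles happens only in
:mod:`oncocea.markov_engine`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

__all__ = ["DigitizedKM", "StepSurvival", "km_estimate", "reconstruct_ipd", "median_survival"]


@dataclass
class DigitizedKM:
    """Published KM evidence: digitized curve coordinates plus risk table.

    ``curve_points`` are ``(time, survival)`` pairs as read off the
    figure; ``risk_table`` gives ``(time, n_at_risk)`` at the scheduled
    times printed under the plot; ``total_events`` is the reported event
    count, if any.
    """

    curve_points: list[tuple[float, float]]
    risk_table: list[tuple[float, int]]
    total_events: int | None = None
    #: number of survival values clamped to restore monotonicity at load
    repairs: int = 0

    def __post_init__(self) -> None:
        self.curve_points = sorted(
            [(float(t), float(s)) for t, s in self.curve_points]
        )
        self.risk_table = sorted([(float(t), int(n)) for t, n in self.risk_table])
        n_risk = [n for _, n in self.risk_table]
        if any(b > a for a, b in zip(n_risk, n_risk[1:])):
            raise ValueError("risk table numbers at risk must be nonincreasing")
        if any(n < 0 for n in n_risk):
            raise ValueError("numbers at risk must be nonnegative")
        # Digitized times are taken as exact; survival is only clamped to
        # be nonincreasing (count of repairs kept for the audit log).
        surv = [s for _, s in self.curve_points]
        repaired = 0
        for j in range(1, len(surv)):
            if surv[j] > surv[j - 1]:
                surv[j] = surv[j - 1]
                repaired += 1
        self.repairs = repaired
        self.curve_points = [
            (t, s) for (t, _), s in zip(self.curve_points, surv)
        ]

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.curve_points])

    @property
    def survival(self) -> np.ndarray:
        return np.array([s for _, s in self.curve_points])

    def to_csv(self, curve_path, risk_path) -> None:
        pd.DataFrame(self.curve_points, columns=["time", "survival"]).to_csv(
            curve_path, index=False
        )
        pd.DataFrame(self.risk_table, columns=["time", "n_risk"]).to_csv(
            risk_path, index=False
        )

    @classmethod
    def from_csv(cls, curve_path, risk_path, total_events: int | None = None):
        curve = pd.read_csv(curve_path)
        risk = pd.read_csv(risk_path)
        return cls(
            curve_points=list(zip(curve["time"], curve["survival"])),
            risk_table=list(zip(risk["time"], risk["n_risk"])),
            total_events=total_events,
        )


@dataclass
class StepSurvival:
    """Right-continuous product-limit step function with Greenwood variance."""

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t_k) just after each event time
    at_risk: np.ndarray
    events: np.ndarray
    censored: np.ndarray
    variance: np.ndarray = field(default=None)  # Greenwood Var[S(t_k)]

    def evaluate(self, t) -> np.ndarray:
        """S(t) by right-continuous step interpolation, S(0)=1."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.survival[np.maximum(idx, 0)], 1.0)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "n_risk": self.at_risk,
                "events": self.events,
                "censored": self.censored,
                "greenwood_var": self.variance,
            }
        )


def _extract_endpoint(records, endpoint: str):
    if isinstance(records, pd.DataFrame):
        if endpoint not in ("pfs", "os"):
            raise ValueError("endpoint must be 'pfs' or 'os'")
        return (
            records[f"{endpoint}_time"].to_numpy(dtype=float),
            records[f"{endpoint}_event"].to_numpy(dtype=int),
        )
    raise TypeError("records must be a cohort DataFrame")


def km_estimate(
    records,
    endpoint: str = "os",
    weights: np.ndarray | None = None,
) -> StepSurvival:
    """Weighted product-limit estimate of the survival function.

    Weights enter as frequency weights in both risk sets and event
    counts; equal weights reproduce the unweighted estimator exactly.
    """
    times, events = _extract_endpoint(records, endpoint)
    if len(times) == 0:
        raise ValueError("need at least one observation")
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if np.any(weights < 0):
            raise ValueError("weights must be nonnegative")
        if weights.sum() == 0:
            raise ValueError("weights sum to zero")

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events, weights=weights)
    table = kmf.event_table  # indexed by time; weighted counts
    # drop the bookkeeping row at t=0 unless something happened there
    if 0.0 in table.index and table.loc[0.0, ["observed", "censored"]].sum() == 0:
        table = table[table.index > 0]

    t = table.index.to_numpy(dtype=float)
    d = table["observed"].to_numpy(dtype=float)
    c = table["censored"].to_numpy(dtype=float)
    n = table["at_risk"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.cumprod(np.where(n > 0, 1.0 - d / n, 1.0))
        gw_terms = np.where((n > 0) & (n > d), d / (n * (n - d)), 0.0)
        var = s**2 * np.cumsum(gw_terms)
    return StepSurvival(
        times=t, survival=s, at_risk=n, events=d, censored=c, variance=var
    )


def median_survival(s: StepSurvival) -> float | None:
    """Smallest time with S(t) <= 0.5; ``None`` when never reached."""
    below = np.nonzero(s.survival <= 0.5)[0]
    if len(below) == 0:
        return None
    return float(s.times[below[0]])


def reconstruct_ipd(
    dk: DigitizedKM, arm: str = "comparator", endpoint: str = "os"
) -> pd.DataFrame:
    """Recover pseudo individual patient data from a digitized KM curve.

    Within each risk-table interval the algorithm iterates on the number
    of censorings: censoring times are spread evenly over the interval,
    event counts at each digitized coordinate are chosen so the running
    product-limit estimate tracks the digitized survival, and the implied
    number at risk at the next interval boundary is compared with the
    printed one; the censoring count is adjusted until they agree.  In
    the final interval (no further risk-table anchor) censoring is
    assumed absent unless a reported total event count says otherwise,
    in which case residual subjects are censored at the last coordinate.
    Events are placed before censorings within an interval (standard KM
    tie convention).

    Returns a single-endpoint cohort frame (columns ``os_time`` /
    ``os_event``; covariates absent).
    """
    t_curve = dk.times
    s_curve = dk.survival
    if len(t_curve) < 2:
        raise ValueError("need at least 2 digitized curve points")
    risk_t = np.array([t for t, _ in dk.risk_table], dtype=float)
    risk_n = np.array([n for _, n in dk.risk_table], dtype=float)
    if risk_t[0] > t_curve[0]:
        raise ValueError("risk table must cover the start of the curve")

    K = len(t_curve)
    # bnd[i]: last curve index at or before risk time T_i; interval i
    # covers the half-open span (T_i, T_{i+1}] so the survival drop into
    # each anchor is attributed to events inside the interval.
    bnd = np.searchsorted(t_curve, risk_t, side="right") - 1
    nI = len(risk_t)

    d = np.zeros(K)  # events at each curve coordinate
    cen_times: list[float] = []
    last_surv = 1.0
    # The risk set is carried forward continuously; the printed risk
    # table enters as the matching target for the censoring iteration.
    n_global = float(risk_n[0])

    for i in range(nI):
        lo = int(bnd[i]) + 1  # first curve index strictly after T_i
        hi = int(bnd[i + 1]) + 1 if i + 1 < nI else K
        if lo >= K or lo >= hi:
            continue
        n_start = n_global
        t_lo = risk_t[i]
        t_hi = t_curve[hi - 1]
        anchor_is_last = i + 1 < nI and abs(t_hi - risk_t[i + 1]) < 1e-9

        def _pass(nc: int):
            """One sweep of the interval with nc censorings spread evenly.

            Returns (events per point, censor times, at-risk after the
            interval, events placed exactly at the next anchor, KM value).
            """
            if nc > 0 and t_hi > t_lo:
                ctimes = t_lo + (np.arange(1, nc + 1) - 0.5) * (t_hi - t_lo) / nc
            else:
                ctimes = np.array([])
            n_run = n_start
            km_run = last_surv
            d_int = np.zeros(hi - lo)
            carry = 0.0  # error diffusion: rounding residue carried forward
            for j, k in enumerate(range(lo, hi)):
                if n_run <= 0:
                    break
                # censorings in (t_{k-1}, t_k] leave the risk set before
                # the drop at t_k is counted (events placed at the
                # digitized coordinate, censorings mid-interval before it)
                t_prev = t_curve[k - 1] if k > lo else t_lo
                nc_before = int(((ctimes > t_prev) & (ctimes <= t_curve[k])).sum())
                n_run = n_run - nc_before
                if n_run <= 0:
                    break
                if km_run > 0:
                    x = n_run * (1.0 - s_curve[k] / km_run) + carry
                    dk_j = int(round(x))
                    carry = x - dk_j
                else:
                    dk_j = 0
                dk_j = int(min(max(dk_j, 0), n_run))
                if dk_j > 0:
                    km_run = km_run * (1.0 - dk_j / n_run)
                d_int[j] = dk_j
                n_run = n_run - dk_j
            d_anchor = d_int[-1] if anchor_is_last else 0.0
            return d_int, ctimes, n_run, d_anchor, km_run

        def _diff(res) -> int:
            """Mismatch vs the printed at-risk at the next anchor.

            The printed number may count subjects dying exactly at the
            anchor instant as still at risk (event times digitized on
            their own coordinates) or not (grid readoff between
            scheduled times); the convention closer to consistency is
            used.
            """
            n_after, d_anchor = res[2], res[3]
            diff_excl = int(round(n_after - risk_n[i + 1]))
            diff_incl = int(round(n_after + d_anchor - risk_n[i + 1]))
            return diff_excl if abs(diff_excl) <= abs(diff_incl) else diff_incl

        if i + 1 < nI:
            # iterate censoring count until the implied number at risk at
            # the next anchor matches the printed one
            s_lo = s_curve[bnd[i]]
            s_next = s_curve[bnd[i + 1]]
            guess = int(round(n_start * (s_next / max(s_lo, 1e-12)))) - int(
                risk_n[i + 1]
            )
            nc = max(guess, 0)
            prev_nc = -1
            best = None
            for _ in range(60):
                best = _pass(nc)
                diff = _diff(best)
                if diff == 0 or nc + diff < 0:
                    break
                nc = nc + diff
                if nc == prev_nc:
                    break
                prev_nc = nc
        elif dk.total_events is not None:
            # final interval: no anchor ahead; choose the censoring count
            # whose implied cumulative event total matches the reported one
            events_so_far = int(d[:lo].sum())
            target = int(dk.total_events) - events_so_far
            best, best_err = None, None
            for nc in range(int(n_start) + 1):
                cand = _pass(nc)
                err = abs(int(cand[0].sum()) - target)
                if best is None or err < best_err:
                    best, best_err = cand, err
                if err == 0:
                    break
        else:
            best = _pass(0)

        d_int, ctimes, n_after, _, km_run = best
        d[lo:hi] = d_int
        cen_times.extend(ctimes.tolist())
        last_surv = km_run
        n_global = n_after

    # Residual subjects still at risk after the last coordinate: censor
    # them at the last digitized time (administrative cutoff).
    total_n = risk_n[0]
    n_events = int(d.sum())
    n_cens = len(cen_times)
    residual = int(round(total_n - n_events - n_cens))
    cutoff = float(t_curve[-1])
    times = []
    events = []
    for k in range(K):
        times.extend([t_curve[k]] * int(d[k]))
        events.extend([1] * int(d[k]))
    times.extend(cen_times)
    events.extend([0] * len(cen_times))
    if residual > 0:
        times.extend([cutoff] * residual)
        events.extend([0] * residual)

    df = pd.DataFrame(
        {
            "id": [f"{arm[:3].upper()}-R{i:04d}" for i in range(len(times))],
            "arm": arm,
            f"{endpoint}_time": np.asarray(times, dtype=float),
            f"{endpoint}_event": np.asarray(events, dtype=int),
        }
    ).sort_values(f"{endpoint}_time", kind="stable", ignore_index=True)
    return df
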