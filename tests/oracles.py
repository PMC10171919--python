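"""Independent test oracles, deliberately written without reusing the
package's production code paths."""

from __future__ import annotations

import numpy as np


def microsimulate(p_death, p_prog, n_walkers: int, seed: int):
    """Per-patient random-walk oracle for the cohort Markov recursion.

    Simulates ``n_walkers`` independent patients through the same
    per-cycle transition probabilities (state 0 = progression-free,
    1 = progressed, 2 = dead) and returns occupancy fractions with one
    row per cycle boundary, matching the cohort trace layout.
    """
    rng = np.random.default_rng(seed)
    p_death = np.asarray(p_death, dtype=float)
    p_prog = np.asarray(p_prog, dtype=float)
    n_cycles = len(p_death)
    state = np.zeros(n_walkers, dtype=np.int8)
    occ = np.zeros((n_cycles + 1, 3))
    occ[0] = [1.0, 0.0, 0.0]
    for j in range(n_cycles):
        u = rng.uniform(size=n_walkers)
        in_pfs = state == 0
        in_pd = state == 1
        dies = u < p_death[j]
        progresses = (~dies) & (u < p_death[j] + p_prog[j])
        state = np.where(in_pfs & dies, 2, state)
        state = np.where(in_pfs & progresses & (state != 2), 1, state)
        u2 = rng.uniform(size=n_walkers)
        state = np.where(in_pd & (u2 < p_death[j]), 2, state)
        occ[j + 1] = [
            np.mean(state == 0),
            np.mean(state == 1),
            np.mean(state == 2),
        ]
    return occ


def spreadsheet_cycle_costs(
    occ_pfs,
    occ_pd,
    deaths_in_cycle,
    *,
    diagnosis,
    drug,
    drug_cap,
    monitoring_pfs,
    monitoring_pd,
    admin_pfs,
    admin_pd,
    hosp_pfs,
    hosp_pd,
    subsequent_pd,
    eol,
    one_off_ae_cost,
    periodic_ae_cost_per_cycle,
):
    """Cell-by-cell cost arithmetic as a spreadsheet would lay it out.

    ``occ_pfs``/``occ_pd`` are occupancies at each cycle start,
    ``deaths_in_cycle`` the mass dying during each cycle.  Returns the
    per-cycle undiscounted totals.
    """
    totals = []
    for j in range(len(occ_pfs)):
        cell = 0.0
        if j == 0:
            cell += diagnosis + one_off_ae_cost
        drug_j = drug if (drug_cap is None or j < drug_cap) else 0.0
        cell += occ_pfs[j] * (
            drug_j + monitoring_pfs + admin_pfs + hosp_pfs + periodic_ae_cost_per_cycle
        )
        cell += occ_pd[j] * (monitoring_pd + admin_pd + hosp_pd + subsequent_pd)
        cell += deaths_in_cycle[j] * eol
        totals.append(cell)
    return totals


def two_level_maic_weights(n1: int, n0: int, target: float):
    """Closed-form MAIC solution for a single binary covariate.

    With ``n1`` subjects at x=1 and ``n0`` at x=0, the moment condition
    forces the weighted prevalence to equal ``target``; weights are
    constant within level.  Returns (w1, w0, ess) with weights scaled to
    sum to n.
    """
    n = n1 + n0
    # weighted prevalence: n1*w1 / (n1*w1 + n0*w0) = target
    # fix w0 = 1, solve w1
    w1 = target * n0 / ((1.0 - target) * n1)
    w0 = 1.0
    s = n1 * w1 + n0 * w0
    scale = n / s
    w1, w0 = w1 * scale, w0 * scale
    ess = (n1 * w1 + n0 * w0) ** 2 / (n1 * w1**2 + n0 * w0**2)
    return w1, w0, ess


def exponential_mle(times, events):
    """Closed-form exponential MLE: total events / total exposure."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    return events.sum() / times.sum()


def empirical_survival(times):
    """No-censoring survival function: S(t) = #{T > t}/n at each event time."""
    times = np.sort(np.asarray(times, dtype=float))
    n = len(times)
    uniq = np.unique(times)
    surv = [(times > t).sum() / n for t in uniq]
    return uniq, np.asarray(surv)
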