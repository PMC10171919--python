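"""Three-state Markov cohort engine on 4-week cycles.

States are progression-free (PFS), progressed disease (PD) and Death
(absorbing).  Transition probabilities are derived from the two
extrapolated survival curves per arm: the per-cycle death probability
comes from the OS curve and applies equally in PFS and PD (the evidence
base provides no state-specific mortality), and the PFS exit probability
in excess of death is progression.  With that construction — and no
clamping — the trace reproduces both input curves exactly on cycle
boundaries: occupancy of PFS equals S_pfs and the alive fraction equals
S_os, i.e. the model coincides with a partitioned-survival analysis.

The cohort starts fully in PFS.  The lifetime horizon stops once more
than 99% of the cohort has died.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from oncocea.survival_models import CYCLE_DAYS, CycleSurvival

__all__ = ["TransitionSchedule", "CohortTrace", "derive_transitions", "run_cohort"]


@dataclass
class TransitionSchedule:
    """Per-cycle transition probabilities with repair diagnostics."""

    p_death: np.ndarray
    p_prog: np.ndarray
    #: count of cycles where S_pfs > S_os had to be clamped
    pfs_clamped: int = 0
    #: count of cycles where the progression probability was floored at 0
    prog_clamped: int = 0
    truncated: bool = False  # OS curve hit exactly 0 before the grid end

    def __post_init__(self) -> None:
        self.p_death = np.asarray(self.p_death, dtype=float)
        self.p_prog = np.asarray(self.p_prog, dtype=float)
        if len(self.p_death) != len(self.p_prog):
            raise ValueError("p_death and p_prog must have equal length")
        if np.any(self.p_death < -1e-12) or np.any(self.p_prog < -1e-12):
            raise ValueError("transition probabilities must be nonnegative")
        if np.any(self.p_death + self.p_prog > 1 + 1e-9):
            raise ValueError("p_death + p_prog must not exceed 1")

    def __len__(self) -> int:
        return len(self.p_death)


@dataclass
class CohortTrace:
    """Per-cycle state occupancy; row j is the start of cycle j."""

    occ_pfs: np.ndarray
    occ_pd: np.ndarray
    occ_death: np.ndarray
    new_deaths: np.ndarray  # mass entering Death during cycle j

    def __len__(self) -> int:
        return len(self.occ_pfs)

    @property
    def t_days(self) -> np.ndarray:
        return np.arange(len(self)) * CYCLE_DAYS

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": np.arange(len(self)),
                "t_days": self.t_days,
                "occ_pfs": self.occ_pfs,
                "occ_pd": self.occ_pd,
                "occ_death": self.occ_death,
                "new_deaths": self.new_deaths,
            }
        )


def derive_transitions(
    s_pfs: CycleSurvival, s_os: CycleSurvival
) -> TransitionSchedule:
    """Transition probabilities from discretized PFS and OS curves.

    ``p_death[j] = 1 - S_os[j+1]/S_os[j]`` and
    ``p_prog[j] = max(0, (1 - S_pfs[j+1]/S_pfs[j]) - p_death[j])``.
    Independently extrapolated curves can cross; any ``S_pfs > S_os``
    is repaired by ``S_pfs := min(S_pfs, S_os)`` with the number of
    clamped cycles recorded.  The schedule is truncated where the OS
    curve reaches exactly zero.
    """
    if len(s_pfs) != len(s_os):
        raise ValueError("PFS and OS grids must be equal length")
    pfs = s_pfs.values.copy()
    os_ = s_os.values
    clamped = int(np.sum(pfs > os_ + 1e-15))
    pfs = np.minimum(pfs, os_)

    n = len(os_) - 1
    p_death = np.zeros(n)
    p_prog = np.zeros(n)
    prog_clamped = 0
    truncated = False
    m = n
    for j in range(n):
        if os_[j] <= 0.0:
            m = j
            truncated = True
            break
        p_death[j] = 1.0 - os_[j + 1] / os_[j]
        if pfs[j] <= 0.0:
            exit_pfs = 0.0
        else:
            exit_pfs = 1.0 - pfs[j + 1] / pfs[j]
        raw = exit_pfs - p_death[j]
        if raw < 0:
            prog_clamped += 1
        p_prog[j] = max(0.0, raw)
    return TransitionSchedule(
        p_death=p_death[:m],
        p_prog=p_prog[:m],
        pfs_clamped=clamped,
        prog_clamped=prog_clamped,
        truncated=truncated,
    )


def run_cohort(
    ts: TransitionSchedule,
    horizon: str | int = "lifetime",
    death_stop: float = 0.99,
) -> CohortTrace:
    """Run the cohort recursion from full PFS occupancy.

    ``horizon='lifetime'`` stops after the cycle in which cumulative
    deaths exceed ``death_stop`` (or when the schedule is exhausted);
    an integer horizon runs exactly that many cycles (used by the
    36-month scenario, 39 cycles).
    """
    if isinstance(horizon, int):
        if horizon <= 0:
            raise ValueError("fixed horizon must be a positive cycle count")
        n_max = min(horizon, len(ts))
    elif horizon == "lifetime":
        n_max = len(ts)
    else:
        raise ValueError("horizon must be 'lifetime' or a positive integer")

    occ_pfs = [1.0]
    occ_pd = [0.0]
    occ_death = [0.0]
    new_deaths = [0.0]
    for j in range(n_max):
        pd_death = ts.p_death[j]
        p_prog = ts.p_prog[j]
        pfs, pdis, dead = occ_pfs[-1], occ_pd[-1], occ_death[-1]
        deaths = (pfs + pdis) * pd_death
        pfs_next = pfs * (1.0 - pd_death - p_prog)
        pd_next = pdis * (1.0 - pd_death) + pfs * p_prog
        dead_next = dead + deaths
        occ_pfs.append(pfs_next)
        occ_pd.append(pd_next)
        occ_death.append(dead_next)
        new_deaths.append(deaths)
        if horizon == "lifetime" and dead_next > death_stop:
            break
    return CohortTrace(
        occ_pfs=np.asarray(occ_pfs),
        occ_pd=np.asarray(occ_pd),
        occ_death=np.asarray(occ_death),
        new_deaths=np.asarray(new_deaths),
    )
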