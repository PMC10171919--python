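"""Cost and utility layer: attach money and QALY weights to a cohort trace.

Costs follow the direct-medical-cost taxonomy of a Chinese health-system
perspective analysis: diagnosis (one-off, first cycle), drug acquisition
(dosing-rule based), administration, monitoring (time-banded in PFS),
hospitalization, subsequent treatment in PD, adverse-event management
(one-off at cycle 0 or periodic per cycle) and end-of-life care at death.
Utilities weight time in PFS/PD into QALYs, with one-off and periodic
AE disutilities subtracted.  An annual discount rate (default 5%) is
applied as ``(1+r)**(-t_years)`` with ``t`` at cycle start.

All monetary amounts are 2022 US dollars (the source evidence converts at
6.7413 CNY per USD).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from oncocea.markov_engine import CohortTrace
from oncocea.survival_models import CYCLE_DAYS, DAYS_PER_MONTH

__all__ = [
    "AEItem",
    "CostInputs",
    "UtilityInputs",
    "ArmResult",
    "CEResult",
    "drug_cost_per_cycle",
    "cycle_costs",
    "rate_convert",
    "qaly_accumulate",
    "evaluate_arm",
    "compute_icer",
]

YEAR_DAYS = 365.25
CYCLE_YEARS = CYCLE_DAYS / YEAR_DAYS


@dataclass
class AEItem:
    """One grade >=3 adverse event with its economic footprint."""

    name: str
    incidence: float  # over the trial horizon
    mgmt_cost: float = 0.0
    disutility: float = 0.0
    kind: str = "one_off"  # or "periodic"

    def __post_init__(self) -> None:
        if not (0.0 <= self.incidence <= 1.0):
            raise ValueError(f"AE {self.name!r}: incidence outside [0, 1]")
        if self.mgmt_cost < 0 or self.disutility < 0:
            raise ValueError(f"AE {self.name!r}: negative cost or disutility")
        if self.kind not in ("one_off", "periodic"):
            raise ValueError(f"AE {self.name!r}: unknown kind {self.kind!r}")


@dataclass
class CostInputs:
    """Per-arm cost parameters (USD)."""

    arm: str
    diagnosis_cost: float
    drug_cost_per_cycle: float  # acquisition while on treatment, in PFS
    drug_cap_cycles: int | None  # e.g. 26 four-week cycles for a 2-year cap
    monitoring_pfs_y0_3: float  # per cycle, first three years in PFS
    monitoring_pfs_y4_5: float
    monitoring_pfs_gt5: float
    monitoring_pd: float
    admin_pfs: float
    admin_pd: float
    hosp_pfs: float
    hosp_pd: float
    subsequent_tx_pd: float
    eol_cost: float
    ae_list: list[AEItem] = field(default_factory=list)
    #: months of exposure used to convert periodic AE incidences to rates
    ae_rate_horizon_months: float = 12.0

    def __post_init__(self) -> None:
        for name in (
            "diagnosis_cost", "drug_cost_per_cycle", "monitoring_pfs_y0_3",
            "monitoring_pfs_y4_5", "monitoring_pfs_gt5", "monitoring_pd",
            "admin_pfs", "admin_pd", "hosp_pfs", "hosp_pd",
            "subsequent_tx_pd", "eol_cost",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class UtilityInputs:
    u_pfs: float
    u_pd: float
    source: str = "base"

    def __post_init__(self) -> None:
        if not (0.0 <= self.u_pfs <= 1.0 and 0.0 <= self.u_pd <= 1.0):
            raise ValueError("utilities must lie in [0, 1]")


@dataclass
class ArmResult:
    arm: str
    cost: float
    ly: float
    qaly: float
    cost_undiscounted: float
    ly_undiscounted: float
    qaly_undiscounted: float
    cost_components: dict[str, float] = field(default_factory=dict)


@dataclass
class CEResult:
    intervention: ArmResult
    comparator: ArmResult
    delta_cost: float
    delta_qaly: float
    delta_ly: float
    icer: float | None  # None when delta_qaly == 0
    dominance: str  # "", "dominant", "dominated"
    wtp: float | None = None
    cost_effective: bool | None = None

    def to_dict(self) -> dict:
        return {
            "intervention": self.intervention.__dict__,
            "comparator": self.comparator.__dict__,
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "delta_ly": self.delta_ly,
            "icer": self.icer,
            "dominance": self.dominance,
            "wtp": self.wtp,
            "cost_effective": self.cost_effective,
        }


# ---------------------------------------------------------------------------
# dosing rules
# ---------------------------------------------------------------------------

def serplulimab_cycle_cost(
    price_per_vial: float = 828.92,
    vial_mg: float = 100.0,
    dose_mg_per_kg: float = 3.0,
    weight_kg: float = 65.0,
    administrations_per_cycle: int = 2,
) -> float:
    """Acquisition cost of one 4-week serplulimab cycle.

    3 mg/kg every two weeks; per administration the dose is rounded up
    to whole vials (no vial sharing), twice per 4-week cycle.
    """
    vials = math.ceil(dose_mg_per_kg * weight_kg / vial_mg)
    return vials * price_per_vial * administrations_per_cycle


def regorafenib_cycle_cost(
    price_per_unit: float = 102.34,
    unit_mg: float = 160.0,
    daily_mg: float = 160.0,
    dosing_days: int = 21,
) -> float:
    """Acquisition cost of one regorafenib cycle: 160 mg daily, 21 of 28 days."""
    return dosing_days * price_per_unit * (daily_mg / unit_mg)


def drug_cost_per_cycle(inputs: CostInputs, cycle_index: int) -> float:
    """Acquisition cost charged in cycle ``cycle_index`` while in PFS.

    Zero beyond the treatment-duration cap (the anti-PD-1 regimen stops
    at two years = 26 four-week cycles); regorafenib has no cap.
    """
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    if inputs.drug_cap_cycles is not None and cycle_index >= inputs.drug_cap_cycles:
        return 0.0
    return inputs.drug_cost_per_cycle


def _monitoring_pfs(inputs: CostInputs, t_days: float) -> float:
    if t_days < 3 * YEAR_DAYS:
        return inputs.monitoring_pfs_y0_3
    if t_days < 5 * YEAR_DAYS:
        return inputs.monitoring_pfs_y4_5
    return inputs.monitoring_pfs_gt5


def rate_convert(incidence: float, horizon_months: float, cycle_days: float = CYCLE_DAYS) -> float:
    """Convert a cumulative incidence over a horizon to a per-cycle probability.

    The incidence is first converted to a constant rate
    ``r = -ln(1 - incidence)/horizon`` and then back to a probability
    over one cycle: ``1 - exp(-r * cycle_months)``.
    """
    if not (0.0 <= incidence < 1.0):
        raise ValueError("incidence must lie in [0, 1)")
    if incidence == 0.0:
        return 0.0
    r = -math.log(1.0 - incidence) / horizon_months
    return 1.0 - math.exp(-r * cycle_days / DAYS_PER_MONTH)


def cycle_costs(trace: CohortTrace, inputs: CostInputs) -> pd.DataFrame:
    """Undiscounted per-cycle cost streams, one column per component.

    Cycle 0 carries diagnosis and the expected one-off AE management
    cost.  Every cycle adds occupancy-weighted drug, administration,
    monitoring, hospitalization and subsequent-treatment costs, the
    expected periodic-AE cost among progression-free patients, and
    end-of-life cost on the mass entering Death during the cycle.
    Occupancy is taken at cycle start; a trace with N+1 rows (cycle
    boundaries) yields N cost rows.
    """
    n = len(trace) - 1
    t_days = trace.t_days
    comp = {
        name: np.zeros(n)
        for name in (
            "diagnosis", "drug", "admin", "monitoring", "hospitalization",
            "subsequent_tx", "ae", "eol",
        )
    }
    comp["diagnosis"][0] = inputs.diagnosis_cost
    one_off = sum(a.incidence * a.mgmt_cost for a in inputs.ae_list if a.kind == "one_off")
    comp["ae"][0] += one_off
    periodic = [
        (rate_convert(a.incidence, inputs.ae_rate_horizon_months), a.mgmt_cost)
        for a in inputs.ae_list
        if a.kind == "periodic"
    ]
    for j in range(n):
        pfs = trace.occ_pfs[j]
        pd_ = trace.occ_pd[j]
        comp["drug"][j] += pfs * drug_cost_per_cycle(inputs, j)
        comp["admin"][j] += pfs * inputs.admin_pfs + pd_ * inputs.admin_pd
        comp["monitoring"][j] += pfs * _monitoring_pfs(inputs, t_days[j]) + pd_ * inputs.monitoring_pd
        comp["hospitalization"][j] += pfs * inputs.hosp_pfs + pd_ * inputs.hosp_pd
        comp["subsequent_tx"][j] += pd_ * inputs.subsequent_tx_pd
        for p_cycle, cost in periodic:
            comp["ae"][j] += pfs * p_cycle * cost
        comp["eol"][j] += trace.new_deaths[j + 1] * inputs.eol_cost
    df = pd.DataFrame(comp)
    df.insert(0, "cycle", np.arange(n))
    df["total"] = df[list(comp)].sum(axis=1)
    return df


def discount_factors(n: int, rate: float, timing: str = "cycle_start") -> np.ndarray:
    """(1+r)^(-t) per cycle, with t in years at cycle start (or midpoint)."""
    t_years = np.arange(n) * CYCLE_YEARS
    if timing == "midpoint":
        t_years = t_years + 0.5 * CYCLE_YEARS
    return (1.0 + rate) ** (-t_years)


def qaly_accumulate(
    trace: CohortTrace,
    utilities: UtilityInputs,
    ae_list: Sequence[AEItem] = (),
    discount_rate: float = 0.05,
    ae_rate_horizon_months: float = 12.0,
    timing: str = "cycle_start",
) -> dict[str, float]:
    """Life-years and QALYs over the trace, discounted and undiscounted.

    Each cycle contributes ``(occ_pfs + occ_pd) * 28/365.25`` life-years
    and the utility-weighted analogue in QALYs.  One-off AE disutilities
    are charged once at cycle 0 (lasting one cycle); periodic ones per
    cycle at the converted probability among progression-free patients.
    Occupancy is taken at cycle start over the N cycles of the trace.
    """
    n = len(trace) - 1
    occ_pfs = trace.occ_pfs[:n]
    occ_pd = trace.occ_pd[:n]
    alive = occ_pfs + occ_pd
    ly_c = alive * CYCLE_YEARS
    q_c = (occ_pfs * utilities.u_pfs + occ_pd * utilities.u_pd) * CYCLE_YEARS
    one_off = sum(a.incidence * a.disutility for a in ae_list if a.kind == "one_off")
    q_c = q_c.copy()
    q_c[0] -= one_off * CYCLE_YEARS
    for a in ae_list:
        if a.kind == "periodic":
            p_cycle = rate_convert(a.incidence, ae_rate_horizon_months)
            q_c -= occ_pfs * p_cycle * a.disutility * CYCLE_YEARS
    disc = discount_factors(n, discount_rate, timing)
    return {
        "ly": float((ly_c * disc).sum()),
        "qaly": float((q_c * disc).sum()),
        "ly_undiscounted": float(ly_c.sum()),
        "qaly_undiscounted": float(q_c.sum()),
    }


def evaluate_arm(
    arm: str,
    trace: CohortTrace,
    costs: CostInputs,
    utilities: UtilityInputs,
    discount_cost: float = 0.05,
    discount_outcome: float = 0.05,
    timing: str = "cycle_start",
) -> ArmResult:
    """Discounted cost, LY and QALY totals for one arm."""
    cdf = cycle_costs(trace, costs)
    disc = discount_factors(len(cdf), discount_cost, timing)
    components = {
        c: float((cdf[c].to_numpy() * disc).sum())
        for c in cdf.columns
        if c not in ("cycle", "total")
    }
    cost = float((cdf["total"].to_numpy() * disc).sum())
    eff = qaly_accumulate(
        trace, utilities, costs.ae_list, discount_outcome,
        costs.ae_rate_horizon_months, timing,
    )
    return ArmResult(
        arm=arm,
        cost=cost,
        ly=eff["ly"],
        qaly=eff["qaly"],
        cost_undiscounted=float(cdf["total"].sum()),
        ly_undiscounted=eff["ly_undiscounted"],
        qaly_undiscounted=eff["qaly_undiscounted"],
        cost_components=components,
    )


def compute_icer(
    intervention: ArmResult, comparator: ArmResult, wtp: float | None = None
) -> CEResult:
    """Incremental cost-effectiveness ratio with dominance flags."""
    d_cost = intervention.cost - comparator.cost
    d_qaly = intervention.qaly - comparator.qaly
    d_ly = intervention.ly - comparator.ly
    dominance = ""
    icer: float | None
    if d_cost < 0 and d_qaly > 0:
        dominance = "dominant"
    elif d_cost > 0 and d_qaly < 0:
        dominance = "dominated"
    icer = d_cost / d_qaly if d_qaly != 0 else None
    ce = None
    if wtp is not None:
        ce = bool(wtp * d_qaly - d_cost > 0)
    return CEResult(
        intervention=intervention,
        comparator=comparator,
        delta_cost=d_cost,
        delta_qaly=d_qaly,
        delta_ly=d_ly,
        icer=icer,
        dominance=dominance,
        wtp=wtp,
        cost_effective=ce,
    )
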