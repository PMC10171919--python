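"""Costing rules, discounting, QALY accumulation and the ICER."""

import math

import numpy as np
import pytest

from oncocea.economics import (
    AEItem,
    CostInputs,
    UtilityInputs,
    compute_icer,
    cycle_costs,
    discount_factors,
    drug_cost_per_cycle,
    evaluate_arm,
    qaly_accumulate,
    rate_convert,
    regorafenib_cycle_cost,
    serplulimab_cycle_cost,
)
from oncocea.markov_engine import CohortTrace
from oncocea.pipeline import load_economic_inputs

from .oracles import spreadsheet_cycle_costs

CYCLE_YEARS = 28.0 / 365.25


def bare_inputs(**overrides) -> CostInputs:
    base = dict(
        arm="toy", diagnosis_cost=0.0, drug_cost_per_cycle=0.0,
        drug_cap_cycles=None, monitoring_pfs_y0_3=0.0, monitoring_pfs_y4_5=0.0,
        monitoring_pfs_gt5=0.0, monitoring_pd=0.0, admin_pfs=0.0, admin_pd=0.0,
        hosp_pfs=0.0, hosp_pd=0.0, subsequent_tx_pd=0.0, eol_cost=0.0,
        ae_list=[],
    )
    base.update(overrides)
    return CostInputs(**base)


def trace_from_occ(occ_pfs, occ_pd, occ_death):
    occ_pfs = np.asarray(occ_pfs, float)
    occ_pd = np.asarray(occ_pd, float)
    occ_death = np.asarray(occ_death, float)
    return CohortTrace(
        occ_pfs=occ_pfs, occ_pd=occ_pd, occ_death=occ_death,
        new_deaths=np.r_[0.0, np.diff(occ_death)],
    )


@pytest.fixture(scope="module")
def packaged():
    return load_economic_inputs("economic_inputs.yaml")


class TestDrugCost:
    def test_serplulimab_cycle_cost_from_dosing_rule(self):
        # 3 mg/kg x 65 kg = 195 mg -> 2 whole 100-mg vials, twice per cycle
        assert serplulimab_cycle_cost() == pytest.approx(4 * 828.92)
        assert serplulimab_cycle_cost() == pytest.approx(3315.68)

    def test_regorafenib_cycle_cost_from_unit_price(self):
        # 21 dosing days at $102.34 per 160-mg day
        assert regorafenib_cycle_cost() == pytest.approx(21 * 102.34)
        assert regorafenib_cycle_cost() == pytest.approx(2149.14)

    def test_two_year_cap_zeroes_cost_from_cycle_26(self, packaged):
        ci = packaged["cost_inputs"]["intervention"]
        assert drug_cost_per_cycle(ci, 0) == pytest.approx(3315.68)
        assert drug_cost_per_cycle(ci, 25) == pytest.approx(3315.68)
        assert drug_cost_per_cycle(ci, 26) == 0.0
        assert drug_cost_per_cycle(ci, 100) == 0.0

    def test_uncapped_comparator_cost_is_constant(self, packaged):
        ci = packaged["cost_inputs"]["comparator"]
        assert drug_cost_per_cycle(ci, 0) == drug_cost_per_cycle(ci, 500)


class TestRateConvert:
    def test_zero_incidence_stays_zero(self):
        assert rate_convert(0.0, 12.0) == 0.0

    def test_identity_when_horizon_equals_cycle(self):
        inc = 0.11
        cycle_months = 28.0 / 30.4375
        assert rate_convert(inc, cycle_months) == pytest.approx(inc, rel=1e-12)

    def test_compounding_inverts_to_original_incidence(self):
        inc, horizon = 0.027, 12.0
        p_cycle = rate_convert(inc, horizon)
        n_cycles = horizon / (28.0 / 30.4375)
        recovered = 1.0 - (1.0 - p_cycle) ** n_cycles
        assert recovered == pytest.approx(inc, abs=1e-10)


class TestCycleCosts:
    def test_immediate_death_charges_only_eol(self):
        trace = trace_from_occ([1, 0], [0, 0], [0, 1])
        inputs = bare_inputs(eol_cost=2046.84)
        total = cycle_costs(trace, inputs)["total"].sum()
        assert total == pytest.approx(2046.84)

    def test_constant_pfs_occupancy_costs_constant_within_band(self):
        n = 39  # stays inside the first 3-year monitoring band
        trace = trace_from_occ(np.ones(n), np.zeros(n), np.zeros(n))
        inputs = bare_inputs(
            monitoring_pfs_y0_3=75.65, admin_pfs=2.97, drug_cost_per_cycle=100.0
        )
        cdf = cycle_costs(trace, inputs)
        per_cycle = cdf.loc[1:, "total"]  # cycle 0 may carry one-offs
        assert per_cycle.nunique() == 1

    def test_three_cycle_toy_matches_spreadsheet_to_the_cent(self, packaged):
        ci = packaged["cost_inputs"]["intervention"]
        occ_pfs = [1.0, 0.8, 0.65, 0.5]
        occ_pd = [0.0, 0.15, 0.2, 0.25]
        occ_death = [0.0, 0.05, 0.15, 0.25]
        trace = trace_from_occ(occ_pfs, occ_pd, occ_death)
        cdf = cycle_costs(trace, ci)

        one_off = sum(
            a.incidence * a.mgmt_cost for a in ci.ae_list if a.kind == "one_off"
        )
        p_hyp = rate_convert(0.0270, ci.ae_rate_horizon_months)
        oracle = spreadsheet_cycle_costs(
            occ_pfs[:3], occ_pd[:3], [0.05, 0.10, 0.10],
            diagnosis=519.26, drug=3315.68, drug_cap=26,
            monitoring_pfs=75.65, monitoring_pd=75.65,
            admin_pfs=2.97, admin_pd=1.67, hosp_pfs=73.38, hosp_pd=110.08,
            subsequent_pd=749.71, eol=2046.84,
            one_off_ae_cost=one_off, periodic_ae_cost_per_cycle=p_hyp * 0.18,
        )
        assert np.allclose(cdf["total"].to_numpy(), oracle, atol=0.005)

    def test_component_streams_sum_to_total(self, packaged):
        ci = packaged["cost_inputs"]["comparator"]
        n = 30
        occ_death = np.linspace(0, 0.6, n)
        trace = trace_from_occ(
            np.linspace(1, 0.2, n), 0.8 - np.linspace(1, 0.2, n) + occ_death * 0,
            occ_death,
        )
        cdf = cycle_costs(trace, ci)
        comps = [c for c in cdf.columns if c not in ("cycle", "total")]
        assert np.allclose(cdf[comps].sum(axis=1), cdf["total"], atol=1e-9)


class TestQALY:
    def test_full_utility_no_discount_equals_life_years(self):
        trace = trace_from_occ([1, 0.9, 0.8], [0, 0.05, 0.1], [0, 0.05, 0.1])
        u = UtilityInputs(u_pfs=1.0, u_pd=1.0)
        out = qaly_accumulate(trace, u, discount_rate=0.0)
        assert out["qaly"] == pytest.approx(out["ly"])

    def test_discount_factor_at_one_year(self):
        # cycle 13.0446... lands past a year; check the factor formula itself
        f = discount_factors(20, 0.05)
        j_year = 365.25 / 28.0
        assert (1.05) ** (-1.0) == pytest.approx(0.952381, abs=1e-6)
        assert f[13] == pytest.approx(1.05 ** (-(13 * CYCLE_YEARS)))

    def test_single_pfs_cycle_qaly_arithmetic(self):
        trace = trace_from_occ([1, 1], [0, 0], [0, 0])
        u = UtilityInputs(u_pfs=0.84, u_pd=0.57)
        out = qaly_accumulate(trace, u, discount_rate=0.0)
        assert out["qaly"] == pytest.approx(0.84 * 28.0 / 365.25)

    def test_discounted_totals_nonincreasing_in_rate(self, packaged):
        n = 120
        occ_pfs = 0.97 ** np.arange(n)
        occ_pd = 0.6 * (0.97 ** np.arange(n)) * (1 - 0.98 ** np.arange(n))
        occ_death = 1 - occ_pfs - occ_pd
        trace = trace_from_occ(occ_pfs, occ_pd, occ_death)
        u = packaged["utilities"]["base"]
        prev = math.inf
        for r in (0.0, 0.02, 0.05, 0.08):
            q = qaly_accumulate(trace, u, discount_rate=r)["qaly"]
            assert q <= prev + 1e-12
            prev = q


class TestICER:
    def arm(self, cost, qaly, ly=1.0, name="a"):
        from oncocea.economics import ArmResult

        return ArmResult(
            arm=name, cost=cost, ly=ly, qaly=qaly, cost_undiscounted=cost,
            ly_undiscounted=ly, qaly_undiscounted=qaly,
        )

    def test_identical_arms_have_undefined_icer(self):
        ce = compute_icer(self.arm(100, 1.0), self.arm(100, 1.0))
        assert ce.icer is None
        assert ce.dominance == ""

    def test_published_scenario_arithmetic(self):
        ce = compute_icer(self.arm(25929.32 + 100, 4.29 + 1.0), self.arm(100, 1.0))
        assert ce.icer == pytest.approx(25929.32 / 4.29, abs=0.01)
        assert ce.icer == pytest.approx(6044.13, abs=0.01)

    def test_dominant_flag(self):
        ce = compute_icer(self.arm(50, 2.0), self.arm(100, 1.0))
        assert ce.dominance == "dominant"
        ce2 = compute_icer(self.arm(150, 0.5), self.arm(100, 1.0))
        assert ce2.dominance == "dominated"

    def test_wtp_verdict(self):
        ce = compute_icer(self.arm(200, 2.0), self.arm(100, 1.0), wtp=200.0)
        assert ce.cost_effective  # ICER 100 < 200
        ce2 = compute_icer(self.arm(500, 2.0), self.arm(100, 1.0), wtp=200.0)
        assert not ce2.cost_effective


class TestScalingProperties:
    def test_doubling_unit_costs_doubles_delta_cost_only(self, packaged, ce_model):
        base = ce_model.evaluate()
        doubled = {}
        for arm, ci in ce_model.cost_inputs.items():
            import dataclasses

            doubled[arm] = dataclasses.replace(
                ci,
                diagnosis_cost=2 * ci.diagnosis_cost,
                drug_cost_per_cycle=2 * ci.drug_cost_per_cycle,
                monitoring_pfs_y0_3=2 * ci.monitoring_pfs_y0_3,
                monitoring_pfs_y4_5=2 * ci.monitoring_pfs_y4_5,
                monitoring_pfs_gt5=2 * ci.monitoring_pfs_gt5,
                monitoring_pd=2 * ci.monitoring_pd,
                admin_pfs=2 * ci.admin_pfs,
                admin_pd=2 * ci.admin_pd,
                hosp_pfs=2 * ci.hosp_pfs,
                hosp_pd=2 * ci.hosp_pd,
                subsequent_tx_pd=2 * ci.subsequent_tx_pd,
                eol_cost=2 * ci.eol_cost,
                ae_list=[
                    AEItem(a.name, a.incidence, 2 * a.mgmt_cost, a.disutility, a.kind)
                    for a in ci.ae_list
                ],
            )
        res = ce_model.evaluate(cost_inputs=doubled)
        assert res.delta_cost == pytest.approx(2 * base.delta_cost, rel=1e-9)
        assert res.delta_qaly == pytest.approx(base.delta_qaly, rel=1e-12)

    def test_comparator_pfs_admin_contributes_nothing(self, packaged, ce_model):
        # oral drug: no infusion cost while progression-free
        trace, _ = ce_model.trace("comparator")
        ci = packaged["cost_inputs"]["comparator"]
        assert ci.admin_pfs == 0.0
        cdf = cycle_costs(trace, ci)
        import dataclasses

        no_pd_admin = dataclasses.replace(ci, admin_pd=0.0)
        cdf2 = cycle_costs(trace, no_pd_admin)
        pd_admin_total = (cdf["admin"] - cdf2["admin"]).sum()
        assert cdf["admin"].sum() == pytest.approx(pd_admin_total)
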