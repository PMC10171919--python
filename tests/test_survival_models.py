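"""Parametric ML fitting, mixture cure, model selection, mortality floor."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from oncocea.maic import WeightedCohort
from oncocea.survival_models import (
    FAMILIES,
    CycleSurvival,
    LifeTable,
    apply_mortality_floor,
    discretize,
    fit_mixture_cure,
    fit_parametric,
    hazard_at,
    select_best,
    survival_at,
)
from oncocea.synthetic_cohort import CohortGenConfig, generate_ipd

from .conftest import make_cohort
from .oracles import exponential_mle

ALL_FAMILIES = list(FAMILIES)


@pytest.fixture(scope="module")
def censored_cohort():
    cfg = CohortGenConfig(
        n=400, seed=71, cure_fraction=0.0, latent_os_family="weibull",
        latent_os_params=(12.0, 1.3), followup_months=24, accrual_months=12,
    )
    return generate_ipd(cfg)


class TestFitParametric:
    def test_exponential_closed_form(self):
        # uncensored times with mean 10 -> rate exactly 0.1
        times = [5.0, 10.0, 15.0, 8.0, 12.0]
        df = make_cohort(times, [1] * 5)
        fit = fit_parametric(df, "os", "exponential")
        lam_oracle = exponential_mle(times, [1] * 5)
        assert fit.params[0] == pytest.approx(lam_oracle, rel=1e-6)
        assert fit.params[0] == pytest.approx(1.0 / np.mean(times), rel=1e-6)

    def test_weibull_with_unit_shape_nests_exponential(self, censored_cohort):
        fe = fit_parametric(censored_cohort, "os", "exponential")
        fw = fit_parametric(censored_cohort, "os", "weibull")
        # Weibull loglik at kappa=1, sigma=1/lambda equals exponential loglik
        t = censored_cohort["os_time"].to_numpy()
        d = censored_cohort["os_event"].to_numpy()
        lam = fe.params[0]
        fam = FAMILIES["weibull"]
        p = (1.0 / lam, 1.0)
        ll = float(
            np.sum(d * fam.logf(np.maximum(t, 1e-8), p) + (1 - d) * fam.logS(t, p))
        )
        assert ll == pytest.approx(fe.loglik, abs=1e-6)
        assert fw.loglik >= fe.loglik - 1e-8  # nesting: richer model fits >=

    def test_gamma_with_unit_shape_nests_exponential(self, censored_cohort):
        fe = fit_parametric(censored_cohort, "os", "exponential")
        fam = FAMILIES["gamma"]
        t = censored_cohort["os_time"].to_numpy()
        d = censored_cohort["os_event"].to_numpy()
        p = (1.0, fe.params[0])
        ll = float(
            np.sum(d * fam.logf(np.maximum(t, 1e-8), p) + (1 - d) * fam.logS(t, p))
        )
        assert ll == pytest.approx(fe.loglik, abs=1e-6)

    def test_gompertz_small_shape_approaches_exponential(self, censored_cohort):
        fe = fit_parametric(censored_cohort, "os", "exponential")
        fam = FAMILIES["gompertz"]
        t = censored_cohort["os_time"].to_numpy()
        d = censored_cohort["os_event"].to_numpy()
        p = (fe.params[0], 1e-8)
        ll = float(
            np.sum(d * fam.logf(np.maximum(t, 1e-8), p) + (1 - d) * fam.logS(t, p))
        )
        assert ll == pytest.approx(fe.loglik, abs=1e-4)

    @pytest.mark.parametrize("family", ALL_FAMILIES)
    def test_fits_match_lifelines(self, censored_cohort, family):
        """Cross-check every family's MLE against the independent fitter."""
        import lifelines

        ll_fitters = {
            "exponential": lifelines.ExponentialFitter,
            "weibull": lifelines.WeibullFitter,
            "lognormal": lifelines.LogNormalFitter,
            "loglogistic": lifelines.LogLogisticFitter,
        }
        fit = fit_parametric(censored_cohort, "os", family)
        t = censored_cohort["os_time"]
        d = censored_cohort["os_event"]
        if family in ll_fitters:
            ref = ll_fitters[family]().fit(t, d)
            assert fit.loglik == pytest.approx(ref.log_likelihood_, rel=1e-6)
        else:
            # no lifelines analogue (gamma, Gompertz): the fitted loglik
            # must at least dominate the exponential submodel
            fe = fit_parametric(censored_cohort, "os", "exponential")
            assert fit.loglik >= fe.loglik - 1e-8

    def test_zero_events_raises(self):
        df = make_cohort([1.0, 2.0], [0, 0])
        with pytest.raises(Exception, match="events"):
            fit_parametric(df, "os", "weibull")

    def test_frequency_weights_equal_physical_duplication(self):
        df = make_cohort([2, 4, 6, 9, 12], [1, 1, 0, 1, 1])
        w = np.array([2.0, 0.0, 1.0, 1.0, 2.0])
        wc = WeightedCohort(records=df, weights=w)
        dup = make_cohort([2, 2, 6, 9, 12, 12], [1, 1, 0, 1, 1, 1])
        for family in ("exponential", "weibull", "lognormal"):
            fw = fit_parametric(wc, "os", family)
            fd = fit_parametric(dup, "os", family)
            assert fw.loglik == pytest.approx(fd.loglik, abs=1e-6)
            assert np.allclose(fw.params, fd.params, rtol=1e-4)

    def test_aic_bic_identities(self, censored_cohort):
        fit = fit_parametric(censored_cohort, "os", "weibull")
        assert fit.aic == pytest.approx(2 * 2 - 2 * fit.loglik)
        assert fit.bic == pytest.approx(2 * np.log(fit.n_eff) - 2 * fit.loglik)
        # vcov symmetric PSD
        assert np.allclose(fit.vcov, fit.vcov.T)
        assert np.linalg.eigvalsh(fit.vcov).min() >= -1e-10


class TestFamilies:
    @pytest.mark.parametrize("family,params", [
        ("exponential", (0.1,)),
        ("weibull", (10.0, 1.4)),
        ("gamma", (2.0, 0.25)),
        ("lognormal", (2.0, 0.7)),
        ("loglogistic", (9.0, 1.8)),
        ("gompertz", (0.05, 0.08)),
    ])
    def test_survival_starts_at_one_and_density_integrates_to_one(
        self, family, params
    ):
        fam = FAMILIES[family]
        assert np.exp(fam.logS(1e-12, params)) == pytest.approx(1.0, abs=1e-8)
        total, _ = quad(
            lambda t: np.exp(fam.logf(t, params)), 1e-10, np.inf, limit=200
        )
        assert total == pytest.approx(1.0, abs=1e-6)
        grid = np.linspace(0.1, 60, 50)
        S = np.exp(fam.logS(grid, params))
        assert (np.diff(S) <= 1e-12).all()

    def test_loglogistic_median_at_scale_parameter(self):
        fit = fit_parametric(
            make_cohort([3, 5, 8, 12, 20], [1] * 5), "os", "loglogistic"
        )
        alpha = fit.params[0]
        assert survival_at(fit, alpha) == pytest.approx(0.5, abs=1e-9)

    def test_hazard_matches_numerical_log_survival_derivative(self):
        df = make_cohort([3, 5, 8, 12, 20, 7, 9], [1] * 7)
        for family in ALL_FAMILIES:
            fit = fit_parametric(df, "os", family)
            grid = np.linspace(1.0, 25.0, 7)
            h = hazard_at(fit, grid)
            eps = 1e-6
            num = -(
                np.log(survival_at(fit, grid + eps))
                - np.log(survival_at(fit, grid - eps))
            ) / (2 * eps)
            assert np.allclose(h, num, rtol=1e-5), family

    def test_survival_at_zero_is_one(self, censored_cohort):
        for family in ALL_FAMILIES:
            fit = fit_parametric(censored_cohort, "os", family)
            assert survival_at(fit, 0.0) == 1.0


class TestMixtureCure:
    def test_nests_parametric_when_pi_zero(self):
        # uncensored data: cure mass is implausible, pi -> ~0 and logliks agree
        df = make_cohort(
            np.random.default_rng(3).lognormal(2.0, 0.5, 300), np.ones(300)
        )
        plain = fit_parametric(df, "os", "lognormal")
        cure = fit_mixture_cure(df, "os", "lognormal")
        assert cure.pi < 0.01
        assert cure.loglik == pytest.approx(plain.loglik, abs=0.05)

    def test_limit_survival_is_cure_probability(self):
        cfg = CohortGenConfig(n=500, seed=9, cure_fraction=0.35, followup_months=80)
        cure = fit_mixture_cure(generate_ipd(cfg), "os", "lognormal")
        assert survival_at(cure, 1e9) == pytest.approx(cure.pi, abs=1e-9)
        grid = np.linspace(0, 200, 100)
        S = survival_at(cure, grid)
        assert (np.diff(S) <= 1e-12).all()
        assert (S >= cure.pi - 1e-12).all()

    def test_plateau_warning_when_followup_too_short(self):
        df = make_cohort([1, 2, 3, 4, 5], [1, 1, 1, 1, 1])
        with pytest.warns(UserWarning, match="plateau"):
            fit_mixture_cure(df, "os", "lognormal")


class TestSelectBest:
    def test_equal_loglik_prefers_fewer_parameters(self, censored_cohort):
        fe = fit_parametric(censored_cohort, "os", "exponential")
        fw = fit_parametric(censored_cohort, "os", "weibull")
        # force identical loglik so AICs differ only by k
        fw2 = type(fw)(
            family=fw.family, params=fw.params, theta=fw.theta,
            loglik=fe.loglik, aic=2 * 2 - 2 * fe.loglik,
            bic=fw.bic, vcov=fw.vcov, n_eff=fw.n_eff,
        )
        best, ranking = select_best([fw2, fe])
        assert best.family == "exponential"
        assert list(ranking.columns) == ["family", "k", "loglik", "aic", "bic"]

    def test_override_returns_named_family_with_ranking(self, censored_cohort):
        fits = [
            fit_parametric(censored_cohort, "os", f)
            for f in ("exponential", "weibull", "gompertz")
        ]
        best, ranking = select_best(fits, override="gompertz")
        assert best.family == "gompertz"
        assert len(ranking) == 3

    def test_unknown_override_rejected(self, censored_cohort):
        fits = [fit_parametric(censored_cohort, "os", "exponential")]
        with pytest.raises(ValueError):
            select_best(fits, override="weibull")


@pytest.fixture(scope="module")
def life_table():
    from oncocea.pipeline import _data_path

    return LifeTable.from_csv(_data_path("life_table_synthetic.csv"))


class TestLifeTable:
    def test_rejects_qx_outside_unit_interval(self):
        df = pd.DataFrame(
            {"age": [0, 1], "sex": ["male", "male"], "qx": [0.5, 1.2]}
        )
        with pytest.raises(ValueError):
            LifeTable(df)

    def test_rejects_open_ended_table(self):
        df = pd.DataFrame(
            {"age": [0, 1], "sex": ["male", "male"], "qx": [0.01, 0.02]}
        )
        with pytest.raises(ValueError, match="terminal"):
            LifeTable(df)

    def test_sex_mix_interpolates_between_sexes(self, life_table):
        qm = life_table.annual_qx(60, 1.0)
        qf = life_table.annual_qx(60, 0.0)
        qmix = life_table.annual_qx(60, 0.6)
        assert qf < qm
        assert qmix == pytest.approx(0.6 * qm + 0.4 * qf)


class TestMortalityFloor:
    def test_inactive_floor_reproduces_model_curve(self, life_table):
        # a high constant hazard dominates population mortality everywhere
        s_model = lambda t: np.exp(-0.05 * t)
        floored = apply_mortality_floor(s_model, life_table, 55.0, 0.6, 1.0, 120)
        base = discretize(s_model, 120)
        assert np.allclose(floored.values, base.values, atol=1e-12)

    def test_cure_plateau_decays_at_k_scaled_population_rate(self, life_table):
        s_model = lambda t: 0.4 + 0.0 * t  # pure plateau (cured fraction)
        k = 2.0
        floored = apply_mortality_floor(s_model, life_table, 55.0, 0.6, k, 60)
        v = floored.values
        # conditional death prob in cycle j equals k-powered population prob
        frac = 28.0 / 365.25
        for j in (5, 20, 40):
            qx = life_table.annual_qx(55.0 + j * frac, 0.6)
            d_pop = 1.0 - (1.0 - qx) ** frac
            expected = 1.0 - (1.0 - d_pop) ** k
            assert 1.0 - v[j + 1] / v[j] == pytest.approx(expected, rel=1e-10)

    def test_k4_dominated_by_k2_and_reaches_zero(self, life_table):
        cfg = CohortGenConfig(n=300, seed=12, cure_fraction=0.45, followup_months=60)
        cure = fit_mixture_cure(generate_ipd(cfg), "os", "lognormal")
        k2 = apply_mortality_floor(cure, life_table, 55.0, 0.6, 2.0, 700)
        k4 = apply_mortality_floor(cure, life_table, 55.0, 0.6, 4.0, 700)
        assert (k4.values <= k2.values + 1e-12).all()
        unfloored = discretize(cure, 700)
        assert (k2.values <= unfloored.values + 1e-12).all()
        assert k2.values[-1] < 1e-6  # life table closes: everyone dies

    def test_start_age_outside_table_raises(self, life_table):
        with pytest.raises(ValueError, match="below"):
            apply_mortality_floor(
                lambda t: np.exp(-0.01 * t), life_table, -3.0, 0.6, 2.0, 10
            )

    def test_k_below_one_rejected(self, life_table):
        with pytest.raises(ValueError):
            apply_mortality_floor(
                lambda t: np.exp(-0.01 * t), life_table, 55.0, 0.6, 0.5, 10
            )
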