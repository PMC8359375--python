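"""Time-response fitting, AIC selection and lethal-time inversion."""

import math

import numpy as np
import pytest
from scipy import optimize, stats

from toxdta import (
    FAMILIES,
    InsufficientDataError,
    LTEstimate,
    ModelFit,
    NonToxicDirectionError,
    SelectionError,
    TimeResponseError,
    estimate_lt,
    fit_model,
    model_curve,
    select_best,
)
from toxdta.time_response import _aic

DAYS_14 = np.array([1.0, 2.0, 4.0, 7.0, 10.0, 14.0])


def replicate_days(n_reps: int = 5) -> np.ndarray:
    return np.repeat(DAYS_14, n_reps)


def bisect_lt(family: str, params: dict, p: float) -> float:
    """Independent oracle: root-find the p% relative decline on the curve."""
    c, d = params.get("c", FAMILIES[family].fixed.get("c")), params.get(
        "d", FAMILIES[family].fixed.get("d"))
    target = d - (p / 100.0) * (d - c)

    def g(log_t: float) -> float:
        return model_curve(family, params, math.exp(log_t)) - target

    return math.exp(optimize.brentq(g, math.log(1e-8), math.log(1e8), xtol=1e-14))


class TestModelCurve:
    def test_log_logistic_inflection_gives_half_range(self):
        assert model_curve("LL3u100", {"b": 3, "e": 8}, 8.0) == pytest.approx(50.0)

    def test_upper_asymptote_as_time_vanishes(self):
        assert model_curve("LL3u100", {"b": 3, "e": 8}, 1e-9) == pytest.approx(100.0)

    def test_weibull1_closed_form_at_inflection_time(self):
        y = model_curve("W14", {"b": 2, "c": 0, "d": 100, "e": 8}, 8.0)
        assert y == pytest.approx(100.0 * math.exp(-1.0), abs=1e-9)

    def test_weibull2_complements_weibull1(self):
        params = {"b": 2, "c": 0, "d": 100, "e": 8}
        for t in (1.0, 5.0, 8.0, 20.0):
            w1 = model_curve("W14", params, t)
            w2 = model_curve("W24", params, t)
            assert w1 + w2 == pytest.approx(100.0)

    def test_ll5_asymmetry_reduces_to_ll4_at_f1(self):
        p5 = {"b": 2.5, "c": 5, "d": 95, "e": 6, "f": 1.0}
        t = np.linspace(0.5, 20, 7)
        np.testing.assert_allclose(model_curve("LL5", p5, t), model_curve("LL4", p5, t))

    def test_nonpositive_time_rejected(self):
        with pytest.raises(TimeResponseError):
            model_curve("LL3u100", {"b": 3, "e": 8}, 0.0)


class TestFitModel:
    def test_exact_data_recovers_parameters(self):
        truth = {"b": 3.0, "e": 8.0}
        days = replicate_days()
        y = model_curve("LL3u100", truth, days)
        fit = fit_model(days, y, "LL3u100")
        assert fit.converged
        assert fit.params["b"] == pytest.approx(3.0, abs=1e-4)
        assert fit.params["e"] == pytest.approx(8.0, abs=1e-4)
        assert fit.rss < 1e-8

    def test_constant_survival_is_non_modellable(self):
        fit = fit_model(replicate_days(), np.full(30, 100.0), "LL3u100")
        assert not fit.converged
        assert math.isnan(fit.aic)

    def test_too_few_distinct_days_raises(self):
        with pytest.raises(InsufficientDataError):
            fit_model([1, 1, 2, 2], [100, 99, 60, 62], "LL4")

    def test_refit_on_regenerated_curve_is_idempotent(self):
        rng = np.random.default_rng(3)
        days = replicate_days()
        y = model_curve("LL3u100", {"b": 2.5, "e": 6.0}, days) + rng.normal(0, 5, days.size)
        first = fit_model(days, y, "LL3u100")
        second = fit_model(days, first.predict(days), "LL3u100")
        assert second.params["b"] == pytest.approx(first.params["b"], rel=1e-5)
        assert second.params["e"] == pytest.approx(first.params["e"], rel=1e-5)

    def test_wald_intervals_attain_nominal_coverage_under_model(self):
        # model-correct regime: iid Gaussian noise on the true curve
        rng = np.random.default_rng(11)
        days = replicate_days()
        truth = {"b": 3.0, "e": 8.0}
        n_sims = 300
        hits_e = hits_b = 0
        for _ in range(n_sims):
            y = model_curve("LL3u100", truth, days) + rng.normal(0, 5, days.size)
            fit = fit_model(days, y, "LL3u100")
            tq = stats.t.ppf(0.975, fit.n_obs - fit.family.k)
            se_b, se_e = np.sqrt(np.diag(fit.cov))
            hits_b += abs(fit.params["b"] - truth["b"]) <= tq * se_b
            hits_e += abs(fit.params["e"] - truth["e"]) <= tq * se_e
        assert 0.90 <= hits_b / n_sims <= 0.99
        assert 0.90 <= hits_e / n_sims <= 0.99

    def test_covariance_is_symmetric_psd(self):
        rng = np.random.default_rng(5)
        days = replicate_days()
        y = model_curve("LL4", {"b": 2, "c": 5, "d": 98, "e": 7}, days)
        y = y + rng.normal(0, 4, days.size)
        fit = fit_model(days, y, "LL4")
        assert fit.converged
        np.testing.assert_allclose(fit.cov, fit.cov.T)
        assert np.all(np.linalg.eigvalsh(fit.cov) > -1e-10)


class TestSelection:
    def test_single_converged_fit_is_selected(self):
        days = replicate_days()
        y = model_curve("LL3u100", {"b": 3, "e": 8}, days)
        fit = fit_model(days, y, "LL3u100")
        assert select_best([fit]) is fit

    def test_aic_tie_prefers_fewer_parameters(self):
        f3 = FAMILIES["LL3"]
        f4 = FAMILIES["LL4"]
        params = {"b": 2.0, "c": 0.0, "d": 100.0, "e": 8.0, "f": 1.0}
        a = ModelFit(f3, params, None, 10.0, 30, 50.0, True)
        b = ModelFit(f4, params, None, 10.0, 30, 50.0, True)
        assert select_best([b, a]).family.name == "LL3"

    def test_no_converged_fit_raises(self):
        dead = ModelFit(FAMILIES["LL3u100"], {"b": np.nan, "c": 0, "d": 100, "e": np.nan, "f": 1},
                        None, np.nan, 30, np.nan, False)
        with pytest.raises(SelectionError):
            select_best([dead])

    def test_true_family_selected_in_majority_of_noisy_datasets(self):
        # data simulated from the fixed-asymptote log-logistic truth at sigma=3
        rng = np.random.default_rng(21)
        days = replicate_days()
        truth = {"b": 3.0, "e": 8.0}
        wins = 0
        n_sims = 60
        for _ in range(n_sims):
            y = model_curve("LL3u100", truth, days) + rng.normal(0, 3, days.size)
            fits = [fit_model(days, y, name) for name in FAMILIES]
            best = select_best(fits)
            d_hat = best.params["d"]
            wins += best.family.name == "LL3u100" or (
                best.family.name == "LL3" and abs(d_hat - 100.0) < 5.0
            )
        assert wins > n_sims / 2

    def test_aic_depends_only_on_rss_n_k(self):
        assert _aic(12.5, 30, 2) == _aic(12.5, 30, 2)
        assert _aic(12.5, 30, 2) != _aic(12.5, 30, 3)
        assert _aic(12.5, 30, 2) == pytest.approx(30 * math.log(12.5 / 30) + 6)


class TestLethalTime:
    def exact_fit(self, family: str, params: dict) -> ModelFit:
        days = replicate_days()
        y = model_curve(family, params, days)
        fit = fit_model(days, y, family)
        assert fit.converged
        return fit

    def test_lt50_equals_inflection_for_fixed_asymptote_model(self):
        fit = self.exact_fit("LL3u100", {"b": 3, "e": 8})
        assert estimate_lt(fit, 50).estimate == pytest.approx(8.0, abs=1e-6)

    def test_lt10_closed_form(self):
        fit = self.exact_fit("LL3u100", {"b": 3, "e": 8})
        assert estimate_lt(fit, 10).estimate == pytest.approx(8 * (1 / 9) ** (1 / 3), abs=1e-6)

    @pytest.mark.parametrize("family,params", [
        ("LL3u100", {"b": 2.2, "e": 7.0}),
        ("LL3", {"b": 3.1, "d": 97.0, "e": 6.0}),
        ("LL4", {"b": 2.0, "c": 4.0, "d": 96.0, "e": 9.0}),
        ("LL5", {"b": 2.4, "c": 2.0, "d": 99.0, "e": 8.0, "f": 1.7}),
        ("W14", {"b": 1.8, "c": 3.0, "d": 98.0, "e": 7.5}),
        ("W24", {"b": -2.1, "c": 5.0, "d": 99.0, "e": 6.5}),
    ])
    @pytest.mark.parametrize("p", [10.0, 50.0, 90.0])
    def test_closed_form_matches_bisection_oracle(self, family, params, p):
        full = FAMILIES[family].full_params([params[n] for n in FAMILIES[family].free])
        full.update(params)
        fit = ModelFit(FAMILIES[family], full, None, 1.0, 30, 0.0, True)
        est = estimate_lt(fit, p).estimate
        assert est == pytest.approx(bisect_lt(family, full, p), abs=1e-8)

    def test_lt10_precedes_lt50_for_decreasing_fits(self):
        for family, params in [("LL3u100", {"b": 1.2, "e": 9.0}),
                               ("W14", {"b": 2.5, "c": 0.0, "d": 100.0, "e": 5.0})]:
            full = FAMILIES[family].full_params([params[n] for n in FAMILIES[family].free])
            full.update(params)
            fit = ModelFit(FAMILIES[family], full, None, 1.0, 30, 0.0, True)
            assert estimate_lt(fit, 10).estimate < estimate_lt(fit, 50).estimate

    def test_interval_brackets_estimate_and_may_go_negative(self):
        rng = np.random.default_rng(17)
        days = replicate_days()
        y = model_curve("LL3u100", {"b": 1.1, "e": 10.0}, days) + rng.normal(0, 12, days.size)
        fit = fit_model(days, y, "LL3u100")
        lt = estimate_lt(fit, 10)
        assert lt.lower <= lt.estimate <= lt.upper
        # weakly identified early decline: a negative lower limit is legitimate
        wide = ModelFit(fit.family, fit.params, fit.cov * 25.0, fit.rss, fit.n_obs,
                        fit.aic, True)
        lt_wide = estimate_lt(wide, 10)
        assert lt_wide.lower < 0 < lt_wide.estimate

    def test_increasing_curve_flagged_as_non_toxic_direction(self):
        fit = ModelFit(FAMILIES["LL3u100"], {"b": -2.0, "c": 0, "d": 100, "e": 8, "f": 1},
                       None, 1.0, 30, 0.0, True)
        with pytest.raises(NonToxicDirectionError):
            estimate_lt(fit, 50)

    def test_absolute_and_relative_targets_coincide_when_asymptotes_fixed(self):
        fit = self.exact_fit("LL3u100", {"b": 3, "e": 8})
        rel = estimate_lt(fit, 10, relative=True).estimate
        absolute = estimate_lt(fit, 10, relative=False).estimate
        assert rel == pytest.approx(absolute, abs=1e-9)
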