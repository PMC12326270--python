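import numpy as np
import pandas as pd
import pytest

from mitoflight.errors import (
    CollinearityError,
    DegenerateVarianceError,
    InsufficientDataError,
)
from mitoflight.schema import MITO_PREDICTORS
from mitoflight.stats import (
    collinearity_screen,
    fit_all_models,
    fit_single_predictor_model,
    influence_refit,
    residual_diagnostics,
    response_independence_check,
)
from mitoflight.synthetic import CohortSimParams, replicate_seeds, simulate_cohort


def toy_table(n=20, seed=0, noise=0.0, slope=2.0, mass_slope=3.0):
    rng = np.random.default_rng(seed)
    mito = np.linspace(1.0, 10.0, n)
    mass = rng.normal(27.0, 1.5, n)
    cells = rng.normal(3.5e6, 5e5, n)
    y = slope * mito + mass_slope * mass + rng.normal(0, noise, n)
    return pd.DataFrame({
        "endurance_s": y,
        "takeoff_energy_j": rng.normal(0.14, 0.03, n),
        "ets_c": mito,
        "body_mass_g": mass,
        "blood_cell_count_per_ul": cells,
    })


class TestFitSinglePredictorModel:
    def test_exact_linear_recovery(self):
        fit = fit_single_predictor_model(toy_table(), "endurance_s", "ets_c")
        assert fit.coef == pytest.approx(2.0, abs=1e-8)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)
        assert fit.p_value < 1e-10
        assert fit.covariates["body_mass_g"] == pytest.approx(3.0, abs=1e-8)

    def test_scale_equivariance(self, default_cohort):
        fit = fit_single_predictor_model(default_cohort, "endurance_s", "ets_c")
        scaled = default_cohort.assign(ets_c=default_cohort["ets_c"] * 10.0)
        fit10 = fit_single_predictor_model(scaled, "endurance_s", "ets_c")
        assert fit10.coef == pytest.approx(fit.coef / 10.0, rel=1e-9)
        assert fit10.se == pytest.approx(fit.se / 10.0, rel=1e-9)
        assert fit10.partial_f == pytest.approx(fit.partial_f, rel=1e-9)
        assert fit10.p_value == pytest.approx(fit.p_value, rel=1e-9)
        assert fit10.r_squared == pytest.approx(fit.r_squared, rel=1e-9)

    def test_partial_f_identity_across_all_models(self, default_cohort):
        for fit in fit_all_models(default_cohort):
            assert fit.partial_f == pytest.approx((fit.coef / fit.se) ** 2, rel=1e-9)
            assert 0.0 < fit.p_value <= 1.0
            assert 0.0 <= fit.r_squared <= 1.0

    def test_too_few_rows_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_single_predictor_model(toy_table(n=4), "endurance_s", "ets_c")

    def test_rank_deficiency_rejected(self):
        t = toy_table()
        t["ets_c"] = t["body_mass_g"]  # duplicate predictor column
        with pytest.raises(CollinearityError):
            fit_single_predictor_model(t, "endurance_s", "ets_c")

    def test_deterministic_report(self, default_cohort):
        a = fit_single_predictor_model(default_cohort, "endurance_s", "ets_c")
        b = fit_single_predictor_model(default_cohort.copy(), "endurance_s", "ets_c")
        assert a.to_dict() == b.to_dict()


class TestResponseIndependenceCheck:
    def test_proportional_responses_warn(self, caplog):
        t = toy_table()
        t["takeoff_energy_j"] = 0.001 * t["endurance_s"]
        with caplog.at_level("WARNING"):
            check = response_independence_check(t)
        assert check.p_value < 1e-10
        assert check.warning

    def test_independent_responses_pass(self, default_cohort):
        check = response_independence_check(default_cohort)
        assert check.nobs == 53

    def test_constant_response_rejected(self):
        t = toy_table()
        t["takeoff_energy_j"] = 0.14
        with pytest.raises(DegenerateVarianceError):
            response_independence_check(t)

    def test_null_arm_rejection_rate_is_nominal(self):
        """Take-off energy is generated independently of endurance, so the
        pre-check rejects at about the nominal 5% rate."""
        rejections = 0
        n_rep = 400
        for seed in replicate_seeds(77, n_rep):
            t = simulate_cohort(CohortSimParams(seed=seed))
            rejections += response_independence_check(t).warning
        assert 0.02 <= rejections / n_rep <= 0.08


class TestCollinearityScreen:
    def test_exact_linear_dependence_flagged(self):
        t = toy_table()
        t["routine_c"] = t["ets_c"] + 5.0  # oxphos = routine - constant leak
        t["oxphos_c"] = t["routine_c"] - 5.0
        rep = collinearity_screen(t, predictors=["routine_c", "oxphos_c"])
        assert rep.corr.loc["routine_c", "oxphos_c"] == pytest.approx(1.0)
        assert rep.any_strong

    def test_generator_correlation_recovered(self):
        pooled = pd.concat(
            [simulate_cohort(CohortSimParams(seed=s)) for s in range(20)]
        )
        rep = collinearity_screen(pooled)
        assert rep.corr.loc["routine_c", "ets_c"] == pytest.approx(0.8, abs=0.06)
        assert ("routine_c", "ets_c", rep.corr.loc["routine_c", "ets_c"]) in [
            (a, b, r) for a, b, r in rep.flagged
        ] or any(
            {a, b} == {"routine_c", "ets_c"} for a, b, _ in rep.flagged
        )

    def test_independent_predictors_unflagged(self, rng):
        t = pd.DataFrame(rng.normal(size=(200, 3)),
                         columns=["routine_c", "leak_c", "ets_c"])
        rep = collinearity_screen(t, predictors=["routine_c", "leak_c", "ets_c"])
        assert not rep.any_strong

    def test_zero_variance_predictor_named(self):
        t = toy_table()
        t["leak_c"] = 1.0
        with pytest.raises(DegenerateVarianceError, match="leak_c"):
            collinearity_screen(t, predictors=["ets_c", "leak_c"])


class TestInfluenceRefit:
    def test_constructed_outlier_is_removed(self):
        t = toy_table(n=20, noise=0.5, seed=3)
        t.loc[19, "endurance_s"] += 60.0  # one far outlier off the line
        fit = fit_single_predictor_model(t, "endurance_s", "ets_c")
        rep = influence_refit(fit)
        assert rep.removed_row == 19
        assert np.argmax(rep.cooks) == 19
        assert rep.refit.nobs == fit.nobs - 1
        # the refit slope moves back toward the generating value of 2
        assert abs(rep.refit.coef - 2.0) < abs(fit.coef - 2.0)
        assert rep.classification in {"unchanged", "weakened", "reversed"}

    def test_no_flags_means_no_refit(self, default_cohort):
        fit = fit_single_predictor_model(default_cohort, "endurance_s", "ets_c")
        rep = influence_refit(fit, cooks_threshold=10.0)
        assert rep.flagged_rows == [] and rep.refit is None
        assert rep.classification is None

    def test_minimum_sample_size(self):
        fit = fit_single_predictor_model(toy_table(n=5, noise=0.1),
                                         "endurance_s", "ets_c")
        with pytest.raises(InsufficientDataError):
            influence_refit(fit)

    def test_null_flagging_rate_matches_reference(self):
        """On clean Gaussian cohorts the 4/n rule flags a small, stable
        fraction of rows (about 5-8% at n = 53)."""
        fracs = []
        for seed in replicate_seeds(5150, 100):
            t = simulate_cohort(CohortSimParams(seed=seed))
            fit = fit_single_predictor_model(t, "endurance_s", "ets_c")
            rep = influence_refit(fit)
            fracs.append(len(rep.flagged_rows) / fit.nobs)
        assert 0.02 <= np.mean(fracs) <= 0.12


class TestResidualDiagnostics:
    def test_gaussian_homoscedastic_passes_at_nominal_rate(self, rng):
        shapiro_ok = bp_ok = 0
        n_rep = 150
        for _ in range(n_rep):
            t = pd.DataFrame({
                "ets_c": rng.normal(30, 9, 53),
                "body_mass_g": rng.normal(27, 1.5, 53),
                "blood_cell_count_per_ul": rng.normal(3.5e6, 5e5, 53),
                "takeoff_energy_j": rng.normal(0.14, 0.03, 53),
            })
            t["endurance_s"] = 2 * t["ets_c"] + rng.normal(0, 40, 53)
            fit = fit_single_predictor_model(t, "endurance_s", "ets_c")
            d = residual_diagnostics(fit)
            shapiro_ok += d.shapiro_p > 0.05
            bp_ok += d.breusch_pagan_p > 0.05
        assert shapiro_ok / n_rep >= 0.88
        assert bp_ok / n_rep >= 0.88

    def test_heteroscedasticity_detected_with_power(self, rng):
        """Residual spread proportional to the predictor (a strong effect)
        should be caught by Breusch-Pagan most of the time at n = 53."""
        detected = 0
        n_rep = 200
        for _ in range(n_rep):
            x = rng.uniform(0, 1, 53)
            t = pd.DataFrame({
                "ets_c": x,
                "body_mass_g": rng.normal(27, 1.5, 53),
                "blood_cell_count_per_ul": rng.normal(3.5e6, 5e5, 53),
                "endurance_s": 1 + 2 * x + rng.normal(size=53) * 4.0 * x,
                "takeoff_energy_j": rng.normal(0.14, 0.03, 53),
            })
            fit = fit_single_predictor_model(t, "endurance_s", "ets_c")
            detected += residual_diagnostics(fit).breusch_pagan_p < 0.05
        assert detected / n_rep > 0.8

    def test_zero_residuals_reported_degenerate(self):
        fit = fit_single_predictor_model(toy_table(noise=0.0),
                                         "endurance_s", "ets_c")
        d = residual_diagnostics(fit)
        assert d.degenerate and d.shapiro_p is None and d.passed


class TestFitAllModels:
    def test_one_model_per_predictor_and_response(self, default_cohort):
        fits = fit_all_models(default_cohort)
        assert len(fits) == 2 * len(MITO_PREDICTORS)
        combos = {(f.response, f.predictor) for f in fits}
        assert len(combos) == len(fits)
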