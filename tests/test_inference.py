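"""The from-scratch MLEs against closed forms, oracles, and recovery designs."""

import numpy as np
import pandas as pd
import pytest

from bgconflict.inference import (
    FitError,
    fit_logistic,
    fit_ordinal,
    loglik_oracle,
    predicted_win_curve,
)
from bgconflict.simulate import GeneratorConfig, generate_contests, generate_spread_observations


def grouped_2x2_frame():
    """x=0: 30 wins / 10 losses; x=1: 10 wins / 30 losses."""
    rows = (
        [(0, 1)] * 30 + [(0, 0)] * 10 + [(1, 1)] * 10 + [(1, 0)] * 30
    )
    return pd.DataFrame(rows, columns=["x", "focal_win"])


class TestLogistic:
    def test_closed_form_log_odds_of_2x2_table(self):
        fit = fit_logistic(grouped_2x2_frame(), predictors=["x"])
        assert fit.converged
        assert fit.coef["intercept"] == pytest.approx(np.log(3.0), abs=1e-8)
        assert fit.coef["x"] == pytest.approx(np.log(1.0 / 9.0), abs=1e-8)

    def test_agrees_with_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        df = generate_contests(GeneratorConfig(seed=2, total_contests=500))
        fit = fit_logistic(df)
        X = sm.add_constant(
            np.column_stack(
                [df.spread_diff, (df.season == "winter").astype(float), df.rel_ndvi]
            )
        )
        ref = sm.Logit(df.focal_win, X).fit(disp=0)
        assert np.allclose(list(fit.coef.values()), ref.params, atol=1e-6)
        assert np.allclose(list(fit.se.values()), ref.bse, atol=1e-5)

    def test_recovers_generating_spread_difference_effect(self):
        df = generate_contests(GeneratorConfig(seed=7, total_contests=2000))
        fit = fit_logistic(df)
        assert fit.converged
        assert abs(fit.beta_dq - (-0.52)) < 0.10

    def test_null_slope_within_two_se(self):
        df = generate_contests(GeneratorConfig(seed=9, total_contests=3000, beta_dq=0.0))
        fit = fit_logistic(df)
        assert abs(fit.beta_dq) < 2 * fit.se["spread_diff"]

    def test_wald_interval_brackets_estimate(self):
        df = generate_contests(GeneratorConfig(seed=3, total_contests=1000))
        fit = fit_logistic(df)
        lo, hi = fit.ci95["spread_diff"]
        assert lo < fit.beta_dq < hi

    def test_complete_separation_flagged(self):
        df = pd.DataFrame({"x": [-2, -1, 1, 2] * 10, "focal_win": [0, 0, 1, 1] * 10})
        fit = fit_logistic(df, predictors=["x"])
        assert not fit.converged
        assert "separation" in fit.message

    def test_single_outcome_rejected(self):
        df = pd.DataFrame({"x": [0, 1, 2], "focal_win": [1, 1, 1]})
        with pytest.raises(FitError):
            fit_logistic(df, predictors=["x"])


class TestOrdinal:
    def test_recovers_generating_slopes(self):
        cfg = GeneratorConfig(seed=1, n_obs=5000)
        df = generate_spread_observations(cfg)
        fit = fit_ordinal(df)
        assert fit.converged
        assert abs(fit.beta_size - 0.15) < 0.03
        assert abs(fit.beta_interaction - 0.04) < 0.02
        assert fit.theta_spacing > 0
        assert fit.se["beta_size"] > 0

    def test_two_category_reduction_equals_logistic(self):
        cfg = GeneratorConfig(seed=6, n_obs=3000)
        df = generate_spread_observations(cfg).copy()
        df["spread_category"] = np.where(df.spread_category <= 2, 1, 2)
        ofit = fit_ordinal(df, center=cfg.size_center)
        bin_df = df.assign(
            y=(df.spread_category == 2).astype(int),
            x=df.group_size - cfg.size_center,
            winter=(df.season == "winter").astype(float),
        )
        bin_df["xw"] = bin_df.x * bin_df.winter
        lfit = fit_logistic(bin_df, response="y", predictors=["x", "winter", "xw"])
        # P(Y=2) = expit(eta - theta_1): same slopes, intercept = -theta_base
        assert ofit.beta_size == pytest.approx(lfit.coef["x"], abs=1e-4)
        assert ofit.beta_season == pytest.approx(lfit.coef["winter"], abs=1e-4)
        assert ofit.beta_interaction == pytest.approx(lfit.coef["xw"], abs=1e-4)
        assert ofit.theta_base == pytest.approx(-lfit.coef["intercept"], abs=1e-4)

    def test_null_data_slope_within_two_se(self):
        cfg = GeneratorConfig(seed=17, n_obs=4000, beta_size=0.0, beta_interaction=0.0, beta_season=0.0)
        df = generate_spread_observations(cfg)
        fit = fit_ordinal(df)
        assert abs(fit.beta_size) < 2 * fit.se["beta_size"]

    def test_shuffle_invariance(self):
        cfg = GeneratorConfig(seed=23, n_obs=2000)
        df = generate_spread_observations(cfg)
        f1 = fit_ordinal(df, center=cfg.size_center)
        f2 = fit_ordinal(df.sample(frac=1.0, random_state=99), center=cfg.size_center)
        for attr in ("beta_size", "beta_season", "beta_interaction", "theta_base", "theta_spacing"):
            assert getattr(f1, attr) == pytest.approx(getattr(f2, attr), abs=1e-10)

    def test_single_category_rejected(self):
        df = pd.DataFrame(
            {"group_id": "AK", "group_size": 20.0, "season": "summer", "spread_category": 2},
            index=range(50),
        )
        with pytest.raises(FitError):
            fit_ordinal(df)


class TestLoglikOracle:
    def test_matches_reported_loglik_for_both_models(self):
        cfg = GeneratorConfig(seed=31, n_obs=1500)
        sdf = generate_spread_observations(cfg)
        ofit = fit_ordinal(sdf)
        assert abs(loglik_oracle(ofit, sdf) - ofit.loglik) < 1e-8
        cdf = generate_contests(GeneratorConfig(seed=31, total_contests=800))
        lfit = fit_logistic(cdf)
        assert abs(loglik_oracle(lfit, cdf) - lfit.loglik) < 1e-8

    def test_mle_is_a_local_maximum(self):
        import dataclasses

        cfg = GeneratorConfig(seed=37, n_obs=1500)
        df = generate_spread_observations(cfg)
        fit = fit_ordinal(df)
        base = loglik_oracle(fit, df)
        for attr in ("beta_size", "beta_season", "beta_interaction", "theta_base", "theta_spacing"):
            bumped = dataclasses.replace(fit, **{attr: getattr(fit, attr) + 0.1})
            assert loglik_oracle(bumped, df) < base

    def test_empty_dataset_gives_zero(self):
        cfg = GeneratorConfig(seed=41, n_obs=100)
        fit = fit_ordinal(generate_spread_observations(cfg))
        assert loglik_oracle(fit, pd.DataFrame(columns=["group_size", "season", "spread_category"])) == 0.0


class TestPredictedWinCurve:
    def test_reference_curve_values(self):
        df = generate_contests(GeneratorConfig(seed=51, total_contests=4000))
        fit = fit_logistic(df)
        curve = predicted_win_curve(fit)
        assert curve.loc[curve.spread_diff == 0, "p_win"].item() == pytest.approx(
            1 / (1 + np.exp(-fit.intercept)), rel=1e-12
        )
        assert curve.p_win.is_monotonic_decreasing  # beta_dq < 0 recovered
        # generating values imply ~0.826 at -3 and ~0.174 at +3
        assert curve.loc[curve.spread_diff == -3, "p_win"].item() == pytest.approx(0.826, abs=0.06)
        assert curve.loc[curve.spread_diff == 3, "p_win"].item() == pytest.approx(0.174, abs=0.06)

    def test_unconverged_fit_rejected(self):
        df = pd.DataFrame({"x": [-2, -1, 1, 2] * 10, "focal_win": [0, 0, 1, 1] * 10})
        fit = fit_logistic(df, predictors=["x"])
        with pytest.raises(FitError):
            predicted_win_curve(fit)
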