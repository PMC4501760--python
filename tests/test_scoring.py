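"""Hierarchical scoring model: OLS oracle, frozen transfer, correlations."""

import numpy as np
import pandas as pd
import pytest

from ffrkit.scoring import (PreliteracyScoreModel, PreliteracyScoreResults,
                            correlate, cross_validate,
                            prediction_error_summary)

NEURAL = ["peak_21", "peak_31", "peak_41", "peak_51",
          "h4", "h5", "h6", "h7", "stability_z"]
DEMO = ["sex", "age_months", "nonverbal_iq"]


def synth_design(n, seed=0, beta=None, noise_sd=1.0):
    """Planted linear design: 3 demographics + 9 'neural' columns."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(rng.standard_normal((n, 12)), columns=DEMO + NEURAL)
    df["sex"] = (df["sex"] > 0).astype(float)
    if beta is None:
        beta = np.zeros(12)
    y = 5.0 + df.to_numpy() @ beta + noise_sd * rng.standard_normal(n)
    df["outcome"] = y
    return df


class TestFitHierarchical:
    def test_null_neural_block_adds_no_variance(self):
        beta = np.zeros(12)
        beta[1] = 1.0   # age only
        df = synth_design(4000, seed=1, beta=beta)
        res = PreliteracyScoreModel(df, "outcome").fit()
        assert res.delta_r2 < 2 * 9 / 4000

    def test_ols_matches_normal_equations_oracle(self):
        for seed in range(5):
            df = synth_design(40, seed=seed,
                              beta=np.linspace(-0.5, 0.5, 12), noise_sd=0.5)
            res = PreliteracyScoreModel(df, "outcome").fit()
            x = np.column_stack([np.ones(40), df[DEMO + NEURAL].to_numpy()])
            y = df["outcome"].to_numpy()
            oracle = np.linalg.solve(x.T @ x, x.T @ y)
            np.testing.assert_allclose(res.params.to_numpy(), oracle,
                                       atol=1e-8)

    def test_delta_r2_identity_and_bounds(self):
        df = synth_design(200, seed=2, beta=np.full(12, 0.3), noise_sd=2.0)
        res = PreliteracyScoreModel(df, "outcome").fit()
        assert 0.0 <= res.r2_block1 <= res.r2_total <= 1.0
        assert res.delta_r2 == res.r2_total - res.r2_block1

    def test_standardized_betas_equal_zscored_refit(self):
        df = synth_design(300, seed=3, beta=np.full(12, 0.4), noise_sd=1.5)
        res = PreliteracyScoreModel(df, "outcome").fit()
        z = (df - df.mean()) / df.std(ddof=1)
        res_z = PreliteracyScoreModel(z, "outcome").fit()
        np.testing.assert_allclose(res.std_params.to_numpy(),
                                   res_z.params[DEMO + NEURAL].to_numpy(),
                                   atol=1e-10)

    def test_tolerance_matches_aux_regression_oracle(self):
        df = synth_design(150, seed=4, beta=np.full(12, 0.2))
        df["h5"] = 0.7 * df["h4"] + 0.3 * df["h5"]   # induce collinearity
        df["outcome"] = df["outcome"] + df["h5"]
        res = PreliteracyScoreModel(df, "outcome").fit()
        cols = DEMO + NEURAL
        x = df[cols].to_numpy()
        j = cols.index("h5")
        a = np.column_stack([np.ones(len(df)), np.delete(x, j, axis=1)])
        coef, *_ = np.linalg.lstsq(a, x[:, j], rcond=None)
        resid = x[:, j] - a @ coef
        r2 = 1 - resid.var() / x[:, j].var()
        assert res.tolerance["h5"] == pytest.approx(1 - r2, abs=1e-8)
        assert res.tolerance["h5"] < res.tolerance["age_months"]

    def test_rank_deficient_design_reports_columns(self):
        df = synth_design(50, seed=5)
        df["h7"] = df["h6"]
        with pytest.raises(ValueError, match="h6"):
            PreliteracyScoreModel(df, "outcome").fit()

    def test_listwise_deletion_logged(self):
        df = synth_design(60, seed=6)
        df.loc[3, "h4"] = np.nan
        df.loc[9, "outcome"] = np.nan
        model = PreliteracyScoreModel(df, "outcome")
        assert model.n_dropped == 2
        assert len(model.data) == 58

    def test_single_block_variants_are_column_subsets(self):
        df = synth_design(100, seed=7, beta=np.full(12, 0.3))
        timing = PreliteracyScoreModel(
            df, "outcome", block2=["peak_21", "peak_31", "peak_41", "peak_51"]
        ).fit()
        assert timing.df_change[0] == 4
        stability_only = PreliteracyScoreModel(
            df, "outcome", block2=["stability_z"]).fit()
        assert stability_only.df_change[0] == 1


class TestPredictScores:
    def test_in_sample_prediction_equals_fitted_values(self):
        df = synth_design(80, seed=8, beta=np.full(12, 0.3))
        res = PreliteracyScoreModel(df, "outcome").fit()
        scores = res.predict(df)
        assert scores.refit_flag is False
        np.testing.assert_allclose(scores.scores.to_numpy(),
                                   res.fitted_values.to_numpy(), atol=1e-12)

    def test_zero_design_returns_intercept(self):
        df = synth_design(60, seed=9, beta=np.full(12, 0.2))
        res = PreliteracyScoreModel(df, "outcome").fit()
        zeros = pd.DataFrame(0.0, index=[0, 1], columns=DEMO + NEURAL)
        scores = res.predict(zeros)
        np.testing.assert_allclose(scores.scores.to_numpy(),
                                   res.params["intercept"])

    def test_missing_column_named_in_error(self):
        df = synth_design(60, seed=10)
        res = PreliteracyScoreModel(df, "outcome").fit()
        with pytest.raises(KeyError, match="stability_z"):
            res.predict(df.drop(columns=["stability_z"]))

    def test_child_with_missing_predictor_flagged_not_scored(self):
        df = synth_design(60, seed=11)
        res = PreliteracyScoreModel(df, "outcome").fit()
        new = df.copy()
        new.loc[5, "h6"] = np.nan
        scores = res.predict(new)
        assert 5 in scores.missing_ids
        assert 5 not in scores.scores.index

    def test_predict_is_affine_superposition(self):
        df = synth_design(40, seed=12, beta=np.full(12, 0.1))
        res = PreliteracyScoreModel(df, "outcome").fit()
        cols = DEMO + NEURAL
        xa = df[cols].iloc[:10]
        xb = df[cols].iloc[10:20].set_index(xa.index)
        mix = 0.25 * xa + 0.75 * xb
        sa = res.predict(xa).scores.to_numpy()
        sb = res.predict(xb).scores.to_numpy()
        sm = res.predict(mix).scores.to_numpy()
        intercept = res.params["intercept"]
        np.testing.assert_allclose(
            sm - intercept,
            0.25 * (sa - intercept) + 0.75 * (sb - intercept), atol=1e-10)

    def test_json_round_trip_preserves_transfer(self):
        df = synth_design(60, seed=13, beta=np.full(12, 0.3))
        res = PreliteracyScoreModel(df, "outcome").fit()
        thawed = PreliteracyScoreResults.from_json(res.to_json())
        np.testing.assert_allclose(thawed.predict(df).scores.to_numpy(),
                                   res.predict(df).scores.to_numpy(),
                                   atol=1e-12)


class TestCorrelate:
    def test_perfect_linearity(self):
        x = pd.Series(np.arange(10.0))
        out = correlate(x, 2 * x + 1)
        assert out.r == pytest.approx(1.0)

    def test_disattenuation_value(self):
        # r = 0.826 with outcome reliability 0.9015 corrects to 0.870
        rng = np.random.default_rng(14)
        x = rng.standard_normal(500)
        y = x + rng.standard_normal(500) * 0.68
        out = correlate(pd.Series(x), pd.Series(y), reliability=0.9015)
        assert out.r_adjusted == pytest.approx(out.r / np.sqrt(0.9015),
                                               abs=1e-12)
        assert 0.826 / np.sqrt(0.9015) == pytest.approx(0.870, abs=5e-4)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            correlate(pd.Series(np.ones(10)), pd.Series(np.arange(10.0)))

    def test_prediction_error_summary_brute_force(self):
        actual = pd.Series([10.0, 12.0, 15.0, 9.0])
        predicted = pd.Series([11.0, 11.5, 12.0, 9.2])
        out = prediction_error_summary(actual, predicted)
        errs = sorted([1.0, 0.5, 3.0, 0.2])
        assert out["median"] == pytest.approx(np.median(errs))
        assert out["min"] == pytest.approx(0.2)
        assert out["max"] == pytest.approx(3.0)


class TestCrossValidate:
    def test_noise_free_relation_gives_holdout_r_one(self):
        df = synth_design(37, seed=15, beta=np.full(12, 0.5), noise_sd=0.0)
        res, holdout_r = cross_validate(df, "outcome", n_train=20, seed=0)
        assert holdout_r == pytest.approx(1.0, abs=1e-9)

    def test_default_split_sizes(self):
        df = synth_design(37, seed=16, beta=np.full(12, 0.4), noise_sd=1.0)
        res, holdout_r = cross_validate(df, "outcome", n_train=20, seed=1)
        assert res.n == 20
        assert np.isfinite(holdout_r)

    def test_empty_holdout_rejected(self):
        df = synth_design(37, seed=17)
        with pytest.raises(ValueError, match="holdout"):
            cross_validate(df, "outcome", n_train=37, seed=0)
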