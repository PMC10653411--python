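"""Survey-weighted logistic regression: closed-form, brute-force, and robust-SE oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from scipy.special import expit, logit

from svyequity.harmonize import SurveyDesign
from svyequity.regression import (
    Covariate,
    ModelSpec,
    SeparationError,
    SurveyLogisticRegression,
)


def flat(df):
    """Each row its own PSU in a single stratum (IID-style design)."""
    df = df.copy()
    df["stratum"] = 0
    df["psu"] = np.arange(len(df))
    return df


@pytest.fixture()
def design():
    return SurveyDesign(weight="weight", stratum="stratum", psu="psu")


class TestPointEstimates:
    def test_intercept_only_equals_logit_of_weighted_prevalence(self, design):
        rng = np.random.default_rng(0)
        df = flat(
            pd.DataFrame(
                {"y": rng.random(500) < 0.3, "weight": rng.uniform(0.5, 4.0, 500)}
            )
        )
        df["y"] = df["y"].astype(float)
        spec = ModelSpec(outcome="y", covariates=())
        fit = SurveyLogisticRegression(spec, design).fit(df)
        prev = np.average(df["y"], weights=df["weight"])
        assert fit.coef_["(Intercept)"] == pytest.approx(logit(prev), abs=1e-8)

    def test_single_binary_covariate_matches_weighted_crossproduct_ratio(self, design):
        rng = np.random.default_rng(1)
        n = 800
        x = rng.random(n) < 0.4
        y = rng.random(n) < np.where(x, 0.5, 0.3)
        w = rng.uniform(0.5, 3.0, n)
        df = flat(pd.DataFrame({"y": y.astype(float), "x": np.where(x, "b", "a"), "weight": w}))
        spec = ModelSpec(outcome="y", covariates=(Covariate("x", reference="a"),))
        fit = SurveyLogisticRegression(spec, design).fit(df)
        # weighted 2x2 cross-product odds ratio
        w11 = w[x & y].sum()
        w10 = w[x & ~y].sum()
        w01 = w[~x & y].sum()
        w00 = w[~x & ~y].sum()
        assert np.exp(fit.coef_["x[b]"]) == pytest.approx((w11 * w00) / (w10 * w01), rel=1e-7)

    def test_tiny_dataset_matches_brute_force_likelihood_maximizer(self, design):
        rng = np.random.default_rng(2)
        n = 12
        df = flat(
            pd.DataFrame(
                {
                    "y": [0, 1, 0, 1, 1, 0, 0, 1, 0, 1, 1, 0],
                    "x": rng.normal(size=n),
                    "weight": rng.uniform(0.5, 2.5, n),
                }
            )
        )
        df["y"] = df["y"].astype(float)
        spec = ModelSpec(outcome="y", covariates=(Covariate("x", kind="continuous"),))
        fit = SurveyLogisticRegression(spec, design).fit(df)

        X = np.column_stack([np.ones(n), df["x"]])
        y, w = df["y"].to_numpy(), df["weight"].to_numpy()

        def nll(beta):
            p = expit(X @ beta)
            p = np.clip(p, 1e-12, 1 - 1e-12)
            return -np.sum(w * (y * np.log(p) + (1 - y) * np.log(1 - p)))

        brute = optimize.minimize(nll, np.zeros(2), method="Nelder-Mead",
                                  options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 10000})
        np.testing.assert_allclose(fit.coef_.to_numpy(), brute.x, atol=1e-6)

    def test_weight_invariance(self, design):
        rng = np.random.default_rng(3)
        n = 600
        df = flat(
            pd.DataFrame(
                {
                    "y": (rng.random(n) < 0.4).astype(float),
                    "x": rng.normal(size=n),
                    "weight": rng.uniform(1.0, 5.0, n),
                }
            )
        )
        spec = ModelSpec(outcome="y", covariates=(Covariate("x", kind="continuous"),))
        a = SurveyLogisticRegression(spec, design).fit(df)
        df2 = df.copy()
        df2["weight"] *= 137.0
        b = SurveyLogisticRegression(spec, design).fit(df2)
        np.testing.assert_allclose(a.coef_.to_numpy(), b.coef_.to_numpy(), atol=1e-9)
        np.testing.assert_allclose(a.se_.to_numpy(), b.se_.to_numpy(), rtol=1e-8)


class TestVariance:
    def test_iid_design_matches_robust_sandwich_of_unweighted_fit(self, design):
        """With equal weights and one PSU per row, the linearized SEs equal the
        heteroskedasticity-robust (HC0) SEs up to the n/(n-1) PSU factor."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(4)
        n = 400
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(0.3 + 0.5 * x)).astype(float)
        df = flat(pd.DataFrame({"y": y, "x": x, "weight": 1.0}))
        spec = ModelSpec(outcome="y", covariates=(Covariate("x", kind="continuous"),))
        fit = SurveyLogisticRegression(spec, design).fit(df)

        X = np.column_stack([np.ones(n), x])
        glm = sm.GLM(y, X, family=sm.families.Binomial()).fit(cov_type="HC0")
        factor = np.sqrt(n / (n - 1))
        np.testing.assert_allclose(
            fit.se_.to_numpy(), glm.bse * factor, rtol=1e-6
        )

    def test_covariance_symmetric_psd(self, design):
        rng = np.random.default_rng(5)
        n = 500
        df = flat(
            pd.DataFrame(
                {
                    "y": (rng.random(n) < 0.5).astype(float),
                    "x": rng.normal(size=n),
                    "weight": rng.uniform(0.5, 2.0, n),
                }
            )
        )
        df["stratum"] = rng.integers(0, 10, n)
        df["psu"] = rng.integers(0, 2, n)
        spec = ModelSpec(outcome="y", covariates=(Covariate("x", kind="continuous"),))
        fit = SurveyLogisticRegression(spec, design).fit(df)
        cov = fit.cov_.to_numpy()
        np.testing.assert_allclose(cov, cov.T, atol=1e-14)
        assert np.linalg.eigvalsh(cov).min() >= -1e-12
        assert fit.df_resid_ == 10 * 2 - 10


class TestOddsRatios:
    def _fit(self, design, beta=0.0, n=2000, seed=6):
        rng = np.random.default_rng(seed)
        x = rng.random(n) < 0.5
        p = expit(-0.2 + beta * x)
        df = flat(
            pd.DataFrame(
                {
                    "y": (rng.random(n) < p).astype(float),
                    "x": np.where(x, "b", "a"),
                    "weight": 1.0,
                }
            )
        )
        spec = ModelSpec(outcome="y", covariates=(Covariate("x", reference="a"),))
        return SurveyLogisticRegression(spec, design).fit(df)

    def test_null_effect_or_near_one_ci_contains_one(self, design):
        ors = self._fit(design).odds_ratios()
        row = ors.loc["x[b]"]
        assert row["ci_low"] < 1.0 < row["ci_high"]
        assert not row["significant"]

    def test_or_is_exp_of_coefficient(self, design):
        fit = self._fit(design, beta=0.157)
        row = fit.odds_ratios().loc["x[b]"]
        assert row["or"] == pytest.approx(np.exp(fit.coef_["x[b]"]), rel=1e-12)
        assert row["ci_low"] <= row["or"] <= row["ci_high"]

    def test_significance_flag_iff_ci_excludes_one(self, design):
        for beta in (0.0, 0.3, 0.8):
            ors = self._fit(design, beta=beta, seed=int(beta * 10) + 1).odds_ratios()
            for _, row in ors.iterrows():
                excludes = row["ci_low"] > 1.0 or row["ci_high"] < 1.0
                assert bool(row["significant"]) == excludes

    def test_formatted_string_layout(self, design):
        row = self._fit(design, beta=0.2).odds_ratios().iloc[0]
        import re

        assert re.fullmatch(r"\d+\.\d\d \(\d+\.\d\d, \d+\.\d\d\)", row["formatted"])


class TestDiagnostics:
    def test_extreme_weight_contrarian_respondent_flagged(self, design):
        rng = np.random.default_rng(7)
        n = 400
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(2.5 * x)).astype(float)
        df = flat(pd.DataFrame({"y": y, "x": x, "weight": 1.0}))
        # plant: strongly positive x but outcome 0, with a huge weight
        df.loc[0, ["x", "y", "weight"]] = [3.0, 0.0, 40.0]
        spec = ModelSpec(outcome="y", covariates=(Covariate("x", kind="continuous"),))
        fit = SurveyLogisticRegression(spec, design).fit(df)
        assert 0 in fit.flag_outliers(df)

    def test_infinite_cutoff_flags_nothing(self, design):
        rng = np.random.default_rng(8)
        n = 300
        df = flat(
            pd.DataFrame(
                {
                    "y": (rng.random(n) < 0.5).astype(float),
                    "x": rng.normal(size=n),
                    "weight": rng.uniform(0.5, 2.0, n),
                }
            )
        )
        spec = ModelSpec(outcome="y", covariates=(Covariate("x", kind="continuous"),))
        fit = SurveyLogisticRegression(spec, design).fit(df)
        assert len(fit.flag_outliers(df, cutoff=np.inf)) == 0

    def test_well_specified_null_data_unflagged(self, design):
        rng = np.random.default_rng(9)
        n = 300
        df = flat(pd.DataFrame({"y": (rng.random(n) < 0.5).astype(float), "weight": 1.0}))
        spec = ModelSpec(outcome="y", covariates=())
        fit = SurveyLogisticRegression(spec, design).fit(df)
        assert len(fit.flag_outliers(df, cutoff=3.0)) == 0

    def test_separation_raises_naming_problem(self, design):
        n = 60
        x = np.linspace(-2, 2, n)
        df = flat(pd.DataFrame({"y": (x > 0).astype(float), "x": x, "weight": 1.0}))
        spec = ModelSpec(outcome="y", covariates=(Covariate("x", kind="continuous"),))
        with pytest.raises((SeparationError, RuntimeError)):
            SurveyLogisticRegression(spec, design, max_iter=40).fit(df)

    def test_nonbinary_outcome_rejected(self, design):
        df = flat(pd.DataFrame({"y": [0.0, 0.5, 1.0], "weight": 1.0}))
        spec = ModelSpec(outcome="y", covariates=())
        with pytest.raises(ValueError, match="binary"):
            SurveyLogisticRegression(spec, design).fit(df)


class TestSklearnProtocol:
    def test_get_set_params_roundtrip(self, design):
        spec = ModelSpec(outcome="y", covariates=())
        est = SurveyLogisticRegression(spec, design)
        params = est.get_params()
        assert params["max_iter"] == 25
        est.set_params(max_iter=50)
        assert est.get_params()["max_iter"] == 50
        with pytest.raises(ValueError):
            est.set_params(bogus=1)

    def test_predict_proba_matches_training_probabilities(self, design):
        rng = np.random.default_rng(10)
        n = 300
        df = flat(
            pd.DataFrame(
                {
                    "y": (rng.random(n) < 0.4).astype(float),
                    "x": rng.normal(size=n),
                    "weight": 1.0,
                }
            )
        )
        spec = ModelSpec(outcome="y", covariates=(Covariate("x", kind="continuous"),))
        fit = SurveyLogisticRegression(spec, design).fit(df)
        p = fit.predict_proba(df)
        assert p.shape == (n,)
        assert ((p > 0) & (p < 1)).all()
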