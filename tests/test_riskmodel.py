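"""Logistic fitting, the four selection strategies, and the published models."""

import numpy as np
import pandas as pd
import pytest

from ventidose.phantom import CohortSimSpec, simulate_cohort
from ventidose.riskmodel import (
    PUBLISHED_LASSO_MODEL,
    PUBLISHED_STEPWISE_MODEL,
    LogisticModel,
    PerfectSeparationError,
    _fit_lasso_point,
    _lambda_path,
    _lasso_path,
    _standardize,
    best_subset_select,
    ensemble_importance,
    fit_logistic,
    lasso_kkt_violation,
    lasso_select,
    predict_risk,
    stepwise_select,
)

FV = [f"V{x}" for x in range(5, 65, 5)]


def _noise_cohort(n, p, seed, beta=None, names=None):
    rng = np.random.default_rng(seed)
    names = names or [f"x{i}" for i in range(p)]
    X = rng.normal(size=(n, p))
    lp = X @ (np.zeros(p) if beta is None else np.asarray(beta))
    y = rng.binomial(1, 1 / (1 + np.exp(-lp)))
    df = pd.DataFrame(X, columns=names)
    df["rp_grade2plus"] = y
    return df


class TestFitLogistic:
    def test_intercept_only_equals_log_odds(self):
        # 16 events / 25 non-events: intercept = ln(16/25)
        df = pd.DataFrame({"rp_grade2plus": [1] * 16 + [0] * 25})
        m = fit_logistic(df, [])
        assert m.intercept == pytest.approx(np.log(16 / 25), abs=1e-10)

    def test_balanced_independent_covariate_gets_zero_coefficient(self):
        # perfectly balanced 2x2: outcome carries no information about x
        df = pd.DataFrame(
            {"x": [1, 1, -1, -1] * 10, "rp_grade2plus": [1, 0, 1, 0] * 10}
        )
        m = fit_logistic(df, ["x"])
        assert abs(m.coefficients["x"]) < 1e-8

    def test_matches_independent_glm_oracle(self, cohort200):
        sm = pytest.importorskip("statsmodels.api")
        covs = ["V10", "V25", "V45"]
        mine = fit_logistic(cohort200, covs)
        X = sm.add_constant(cohort200[covs])
        ref = sm.GLM(
            cohort200["rp_grade2plus"], X, family=sm.families.Binomial()
        ).fit()
        assert mine.intercept == pytest.approx(ref.params.iloc[0], abs=1e-6)
        for v in covs:
            assert mine.coefficients[v] == pytest.approx(ref.params[v], abs=1e-6)
            assert mine.standard_errors[v] == pytest.approx(ref.bse[v], abs=1e-6)
        assert mine.aic == pytest.approx(ref.aic, abs=1e-6)

    def test_recovers_true_coefficients_within_3_se(self):
        cohort = simulate_cohort(CohortSimSpec(n_patients=2000, seed=31))
        truth = PUBLISHED_STEPWISE_MODEL
        fit = fit_logistic(cohort, list(truth.coefficients))
        for name, beta in truth.coefficients.items():
            z = abs(fit.coefficients[name] - beta) / fit.standard_errors[name]
            assert z < 3.0, name
        zi = abs(fit.intercept - truth.intercept) / fit.standard_errors["(Intercept)"]
        assert zi < 3.0

    def test_perfect_separation_names_covariate(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=60)
        df = pd.DataFrame({"sep": x, "rp_grade2plus": (x > 0).astype(int)})
        with pytest.raises(PerfectSeparationError, match="sep"):
            fit_logistic(df, ["sep"])

    def test_single_class_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "rp_grade2plus": [0, 0, 0]})
        with pytest.raises(ValueError, match="both outcome classes"):
            fit_logistic(df, ["x"])

    def test_constant_covariate_rejected(self):
        df = pd.DataFrame({"x": [1.0] * 20, "rp_grade2plus": [0, 1] * 10})
        with pytest.raises(ValueError, match="singular"):
            fit_logistic(df, ["x"])


class TestPredictRisk:
    def test_published_stepwise_intercept_at_zero_covariates(self):
        fv = {name: 0.0 for name in PUBLISHED_STEPWISE_MODEL.coefficients}
        lp, prob = predict_risk(PUBLISHED_STEPWISE_MODEL, fv)
        assert lp == pytest.approx(0.23656, abs=1e-12)
        assert prob == pytest.approx(1 / (1 + np.exp(-0.23656)), abs=1e-12)

    def test_published_lasso_intercept_at_zero_covariates(self):
        fv = {name: 0.0 for name in PUBLISHED_LASSO_MODEL.coefficients}
        lp, _ = predict_risk(PUBLISHED_LASSO_MODEL, fv)
        assert lp == pytest.approx(-1.052542, abs=1e-12)

    def test_zero_linear_predictor_gives_half_probability(self):
        m = LogisticModel(intercept=-2.0, coefficients={"V20": 1.0})
        _, prob = predict_risk(m, {"V20": 2.0})
        assert prob == pytest.approx(0.5)

    def test_missing_covariate_rejected(self):
        with pytest.raises(KeyError, match="V35"):
            predict_risk(PUBLISHED_STEPWISE_MODEL, {"V30": 1.0})


class TestStepwise:
    def test_keeps_strong_predictor_among_noise(self):
        df = _noise_cohort(500, 6, seed=11, beta=[3, 0, 0, 0, 0, 0])
        res = stepwise_select(df, [f"x{i}" for i in range(6)])
        assert "x0" in res.selected

    def test_never_worse_than_full_model_aic(self):
        df = _noise_cohort(500, 5, seed=12)
        res = stepwise_select(df, [f"x{i}" for i in range(5)])
        start = res.criterion_trace[0]["criterion"]
        final = fit_logistic(df, res.selected).aic
        assert final <= start + 1e-9

    def test_agrees_with_exhaustive_search_on_small_problem(self):
        df = _noise_cohort(300, 3, seed=13, beta=[2.0, -1.5, 0.0])
        sw = stepwise_select(df, ["x0", "x1", "x2"])
        bs = best_subset_select(df, ["x0", "x1", "x2"])
        assert sorted(sw.selected) == sorted(bs.selected)


class TestBestSubset:
    def test_enumerates_all_subsets_and_attains_minimum(self):
        df = _noise_cohort(200, 5, seed=14, beta=[2, 1, 0, 0, 0])
        res = best_subset_select(df, [f"x{i}" for i in range(5)])
        assert len(res.criterion_trace) == 2**5
        best = min(t["criterion"] for t in res.criterion_trace)
        assert fit_logistic(df, res.selected).aic == pytest.approx(best, abs=1e-9)

    def test_independent_balanced_covariate_yields_empty_model(self):
        df = pd.DataFrame(
            {"x": [1.0, 1.0, 0.0, 0.0] * 25, "rp_grade2plus": [1, 0, 1, 0] * 25}
        )
        res = best_subset_select(df, ["x"])
        assert res.selected == []

    def test_too_many_candidates_rejected(self, cohort200):
        with pytest.raises(ValueError, match="20"):
            best_subset_select(cohort200, FV + [f"z{i}" for i in range(9)])


class TestLasso:
    def test_all_zero_at_lambda_max(self, cohort120):
        X, _, _ = _standardize(cohort120, FV)
        y = cohort120["rp_grade2plus"].to_numpy(float)
        lams = _lambda_path(X, y, 10)
        _, _, betas = _lasso_path(X, y, lams[:1])
        assert np.all(betas[0] == 0.0)

    def test_unpenalized_limit_matches_mle(self, cohort200):
        covs = ["V10", "V25", "V45"]
        X, mean, sd = _standardize(cohort200, covs)
        y = cohort200["rp_grade2plus"].to_numpy(float)
        b0, beta = _fit_lasso_point(X, y, 0.0, 0.0, np.zeros(3), kkt_tol=1e-10)
        mle = fit_logistic(cohort200, covs)
        back = beta / sd
        intercept = b0 - np.sum(beta * mean / sd)
        assert intercept == pytest.approx(mle.intercept, abs=1e-4)
        for name, b in zip(covs, back):
            assert b == pytest.approx(mle.coefficients[name], abs=1e-4)

    def test_kkt_conditions_along_path(self, cohort120):
        X, _, _ = _standardize(cohort120, FV)
        y = cohort120["rp_grade2plus"].to_numpy(float)
        lams, ints, betas = _lasso_path(X, y, _lambda_path(X, y, 50))
        worst = max(
            lasso_kkt_violation(X, y, ints[i], betas[i], lams[i])
            for i in range(len(lams))
        )
        assert worst <= 1e-6

    def test_path_continuous_with_monotone_support(self, cohort120):
        res = lasso_select(cohort120, FV, seed=5)
        nnz = (res.coef_path != 0).sum(axis=1)
        assert np.all(np.diff(nnz) >= 0)  # support grows as lambda decreases
        assert np.max(np.abs(np.diff(res.coef_path, axis=0))) < 0.1

    def test_selected_support_matches_reported_model(self, cohort120):
        res = lasso_select(cohort120, FV, seed=5)
        assert sorted(res.selected) == sorted(res.final_model.coefficients)


class TestEnsembleImportance:
    def test_constant_covariate_has_near_zero_importance(self, cohort120):
        df = cohort120.copy()
        df["flat"] = 7.0
        res = ensemble_importance(df, FV + ["flat"], n_trees=150, seed=2)
        assert abs(res.importances["mean_decrease_accuracy"]["flat"]) < 0.01
        assert abs(res.importances["mean_decrease_gini"]["flat"]) < 0.01

    def test_permuted_labels_give_null_importances(self, cohort120):
        df = cohort120.copy()
        rng = np.random.default_rng(9)
        df["rp_grade2plus"] = rng.permutation(df["rp_grade2plus"].to_numpy())
        res = ensemble_importance(df, FV, n_trees=200, seed=3)
        mda = np.array(list(res.importances["mean_decrease_accuracy"].values()))
        inside = np.abs(mda - 0.0) <= 2 * mda.std() + 1e-12
        assert inside.mean() >= 0.95 or np.all(np.abs(mda) < 0.02)

    def test_dominant_predictor_ranks_first_on_both_measures(self):
        rng = np.random.default_rng(4)
        n = 400
        X = rng.normal(size=(n, 5))
        y = (X[:, 2] + 0.1 * rng.normal(size=n) > 0).astype(int)
        df = pd.DataFrame(X, columns=[f"x{i}" for i in range(5)])
        df["rp_grade2plus"] = y
        res = ensemble_importance(df, [f"x{i}" for i in range(5)], n_trees=200, seed=5)
        mda = res.importances["mean_decrease_accuracy"]
        mdg = res.importances["mean_decrease_gini"]
        assert max(mda, key=mda.get) == "x2"
        assert max(mdg, key=mdg.get) == "x2"

    def test_tiny_cohort_rejected(self):
        df = _noise_cohort(8, 2, seed=5)
        with pytest.raises(ValueError, match="out-of-bag"):
            ensemble_importance(df, ["x0", "x1"])
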