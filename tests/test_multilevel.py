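import numpy as np
import pandas as pd
import pytest

from microgrowth.multilevel import (
    BayesianHierarchicalRegression,
    ModelSpec,
    fit_across_imputations,
    fit_multilevel,
    pool_draws,
    posterior_predictive_check,
    stack_lagged,
    standardize,
    summarize_draws,
)

LAG_PAIRS = [("1m", "3m"), ("3m", "4m"), ("4m", "2y"), ("6y", "7y"), ("10y", "12y")]


def planted_long_frame(planted_cohort):
    expo = pd.DataFrame(
        {tp: df["Subdoligranulum"]
         for tp, df in planted_cohort.truth["clr_standardized"].items()}
    )
    long = stack_lagged(planted_cohort.cohort, expo, LAG_PAIRS).dropna()
    long, _ = standardize(long, ["birthweight_g"])
    return long


class TestStandardize:
    def test_mean_zero_sd_one(self, rng):
        df = pd.DataFrame({"a": rng.normal(3, 5, 100), "b": rng.normal(size=100)})
        out, rec = standardize(df, ["a"])
        assert out["a"].mean() == pytest.approx(0, abs=1e-12)
        assert out["a"].std(ddof=0) == pytest.approx(1, abs=1e-12)
        assert "b" not in rec  # untouched

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="zero spread"):
            standardize(pd.DataFrame({"a": [1.0, 1.0, 1.0]}), ["a"])

    def test_scaling_record_roundtrips_to_new_data(self, rng):
        train = pd.DataFrame({"a": rng.normal(10, 2, 50)})
        _, rec = standardize(train, ["a"])
        new = pd.DataFrame({"a": [10.0, 12.0]})
        out, _ = standardize(new, ["a"], scaling=rec)
        mu, sd = rec["a"]
        assert out["a"].iloc[1] == pytest.approx((12.0 - mu) / sd)


class TestSampler:
    def test_known_variance_no_re_matches_conjugate_closed_form(self, rng):
        n = 200
        X = rng.normal(size=(n, 2))
        y = 0.5 + X @ [0.3, -0.2] + rng.normal(0, 1, n)
        m = BayesianHierarchicalRegression(
            n_iter=5000, n_chains=2, seed=3, sigma_fixed=1.0, random_effects=False
        ).fit(X, y)
        Xd = np.column_stack([np.ones(n), X])
        A = Xd.T @ Xd + np.diag([1.0, 4.0, 4.0])  # prior precisions 1/1^2, 1/0.5^2
        mu = np.linalg.solve(A, Xd.T @ y)
        sd = np.sqrt(np.diag(np.linalg.inv(A)))
        for i, name in enumerate(m.coef_names_):
            d = m.draws_[name].reshape(-1)
            assert d.mean() == pytest.approx(mu[i], abs=3e-3)
            assert d.std() == pytest.approx(sd[i], abs=3e-3)

    def test_prior_sampling_with_no_data(self):
        m = BayesianHierarchicalRegression(
            n_iter=4000, n_chains=2, seed=1, random_effects=False
        ).fit(np.empty((0, 1)), np.empty(0))
        slope = m.draws_["x0"].reshape(-1)
        assert slope.mean() == pytest.approx(0, abs=0.02)
        assert slope.std() == pytest.approx(0.5, abs=0.02)
        sigma = m.draws_["sigma"].reshape(-1)
        assert sigma.mean() == pytest.approx(1.0, abs=0.05)  # exponential(1)

    def test_recovers_planted_exposure_slope(self, planted_cohort):
        long = planted_long_frame(planted_cohort)
        fit = fit_multilevel(long, ModelSpec(), n_iter=800, n_chains=2, seed=5)
        s = fit.summary()
        assert s.loc["exposure", "l95"] < -0.3 < s.loc["exposure", "u95"] or abs(
            s.loc["exposure", "median"] + 0.3
        ) < 0.05

    def test_convergence_diagnostics_on_example_config(self, planted_cohort):
        long = planted_long_frame(planted_cohort)
        fit = fit_multilevel(long, ModelSpec(), n_iter=1500, n_chains=4, seed=2)
        s = fit.summary()
        assert (s["rhat"] < 1.01).all()
        assert (s["ess"] > 100).all()

    def test_chain_order_invariance(self, planted_cohort):
        long = planted_long_frame(planted_cohort)
        fit = fit_multilevel(long, ModelSpec(), n_iter=300, n_chains=2, seed=8)
        permuted = {k: v[::-1].copy() for k, v in fit.draws_.items()}
        a = summarize_draws(fit.draws_)[["median", "l95", "u95"]]
        b = summarize_draws(permuted)[["median", "l95", "u95"]]
        pd.testing.assert_frame_equal(a, b)

    def test_non_finite_outcome_rejected(self):
        X = np.ones((4, 1))
        y = np.array([1.0, np.inf, 2.0, 3.0])
        with pytest.raises(ValueError, match="non-finite"):
            BayesianHierarchicalRegression(n_iter=10).fit(X, y, groups=None)

    def test_sklearn_param_surface(self):
        m = BayesianHierarchicalRegression(prior_slope_sd=0.25)
        assert m.get_params()["prior_slope_sd"] == 0.25
        m.set_params(n_chains=3)
        assert m.n_chains == 3


class TestModelSpec:
    def test_varying_slope_must_be_an_exposure(self):
        with pytest.raises(ValueError):
            ModelSpec(exposures=("a",), varying_slope="b")

    def test_nonpositive_priors_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(prior_slope_sd=0.0)


class TestPooling:
    def _fit(self, data, seed):
        return fit_multilevel(data, ModelSpec(), n_iter=400, n_chains=2, seed=seed)

    def test_identical_datasets_match_single_fit_within_mc_error(self, planted_cohort):
        long = planted_long_frame(planted_cohort).head(400)
        single = self._fit(long, 1).summary()
        pooled, _ = fit_across_imputations([long, long.copy()], ModelSpec(),
                                           n_iter=400, n_chains=2, seed=1)
        assert pooled.loc["exposure", "median"] == pytest.approx(
            single.loc["exposure", "median"], abs=0.05
        )

    def test_shifted_outcomes_widen_the_pooled_interval(self, planted_cohort):
        long = planted_long_frame(planted_cohort).head(400)
        up = long.copy()
        up["zbmi"] = up["zbmi"] + 0.6
        m1 = self._fit(long, 2)
        m2 = self._fit(up, 2)
        pooled = pool_draws([m1, m2])
        lo, hi = np.percentile(pooled["intercept"], [2.5, 97.5])
        w1 = np.diff(np.percentile(m1.draws_["intercept"].reshape(-1), [2.5, 97.5]))
        w2 = np.diff(np.percentile(m2.draws_["intercept"].reshape(-1), [2.5, 97.5]))
        assert (hi - lo) > max(w1, w2)

    def test_draw_imbalance_rejected(self, planted_cohort):
        long = planted_long_frame(planted_cohort).head(200)
        m1 = self._fit(long, 3)
        m2 = fit_multilevel(long, ModelSpec(), n_iter=200, n_chains=2, seed=3)
        with pytest.raises(ValueError, match="imbalance"):
            pool_draws([m1, m2])

    def test_single_dataset_rejected(self, planted_cohort):
        long = planted_long_frame(planted_cohort).head(200)
        with pytest.raises(ValueError):
            fit_across_imputations([long], ModelSpec())


class TestPosteriorPredictive:
    def test_self_consistent_fit_passes_checks(self, rng):
        n = 300
        X = rng.normal(size=(n, 1))
        y = X[:, 0] * 0.4 + rng.normal(0, 1, n)
        m = BayesianHierarchicalRegression(
            n_iter=500, n_chains=2, seed=0, random_effects=False
        ).fit(pd.DataFrame({"x": X[:, 0]}), y)
        out = posterior_predictive_check(m, pd.DataFrame({"x": X[:, 0]}), y, seed=1)
        for stat in ("mean", "sd"):
            assert 0.05 < out.loc[stat, "bayes_p"] < 0.95

    def test_misfit_flagged_for_heavy_tailed_outcome(self, rng):
        n = 300
        X = rng.normal(size=(n, 1))
        y = rng.standard_t(1, n)  # far heavier tails than the Gaussian model
        m = BayesianHierarchicalRegression(
            n_iter=400, n_chains=2, seed=0, random_effects=False
        ).fit(pd.DataFrame({"x": X[:, 0]}), y)
        out = posterior_predictive_check(m, pd.DataFrame({"x": X[:, 0]}), y, seed=1)
        extremes = out.loc[["min", "max"], "bayes_p"]
        assert (extremes < 0.05).any() or (extremes > 0.95).any()

    def test_zero_replicates_rejected(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=10)})
        y = rng.normal(size=10)
        m = BayesianHierarchicalRegression(
            n_iter=50, n_chains=2, seed=0, random_effects=False
        ).fit(X, y)
        with pytest.raises(ValueError):
            posterior_predictive_check(m, X, y, n_rep=0)


class TestStackLagged:
    def test_lag_join_structure(self, planted_cohort):
        expo = pd.DataFrame(
            {tp: df["Subdoligranulum"]
             for tp, df in planted_cohort.truth["clr_standardized"].items()}
        )
        long = stack_lagged(planted_cohort.cohort, expo, [("10y", "12y")])
        assert set(long["time_point"]) == {"12y"}
        assert set(long["prev_time_point"]) == {"10y"}
        row = long.iloc[0]
        z = planted_cohort.cohort.set_index(["subject", "time_point"])["zbmi"]
        assert row["zbmi"] == pytest.approx(z.loc[(row["subject"], "12y")])
        assert row["zbmi_lag"] == pytest.approx(z.loc[(row["subject"], "10y")])
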