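import numpy as np
import pandas as pd
import pytest

from microgrowth.forest import RandomForest
from microgrowth.rf import (
    RFHyperparams,
    altmann_importance,
    bh_over_models,
    permutation_null_test,
    repeated_cv,
    run_model_family,
    tune_rf,
)


class TestForestEngine:
    def test_agrees_with_reference_forest(self, rng):
        """Accuracy and OOB error match sklearn's RandomForestRegressor."""
        from sklearn.ensemble import RandomForestRegressor
        from sklearn.metrics import mean_squared_error

        n = 120
        X = rng.normal(size=(n, 5))
        y = 2 * X[:, 0] - X[:, 1] + rng.normal(0, 0.5, n)
        Xte = rng.normal(size=(400, 5))
        yte = 2 * Xte[:, 0] - Xte[:, 1] + rng.normal(0, 0.5, 400)

        mine = RandomForest(300, mtry=2, min_samples_leaf=5, seed=1).fit(
            X, y, compute_oob=True
        )
        ref = RandomForestRegressor(
            300, max_features=2, min_samples_leaf=5,
            oob_score=mean_squared_error, random_state=1,
        ).fit(X, y)
        mse_mine = np.mean((mine.predict(Xte) - yte) ** 2)
        mse_ref = np.mean((ref.predict(Xte) - yte) ** 2)
        assert mse_mine == pytest.approx(mse_ref, rel=0.25)
        assert mine.oob_mse_ == pytest.approx(ref.oob_score_, rel=0.25)
        r = np.corrcoef(mine.predict(Xte), ref.predict(Xte))[0, 1]
        assert r > 0.97

    def test_deterministic(self, rng):
        X = rng.normal(size=(50, 4))
        y = rng.normal(size=50)
        a = RandomForest(100, 2, seed=7).fit(X, y).predict(X)
        b = RandomForest(100, 2, seed=7).fit(X, y).predict(X)
        c = RandomForest(100, 2, seed=8).fit(X, y).predict(X)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)


class TestTuning:
    def test_single_feature_grid_returns_mtry_one(self, rng):
        X = rng.normal(size=(60, 1))
        y = X[:, 0] + rng.normal(0, 0.3, 60)
        params = tune_rf(X, y, n_candidates=1, n_trees=50, seed=0)
        assert params.mtry == 1

    def test_strong_signal_beats_outcome_variance(self, rng):
        X = rng.normal(size=(150, 4))
        y = 2 * X[:, 0] + rng.normal(0, 0.3, 150)
        params = tune_rf(X, y, n_candidates=10, n_trees=100, seed=1)
        est = RandomForest(100, params.mtry, params.sample_fraction, seed=2).fit(
            X, y, compute_oob=True
        )
        assert est.oob_mse_ < y.var()

    def test_deterministic_selection(self, rng):
        X = rng.normal(size=(60, 5))
        y = rng.normal(size=60)
        assert tune_rf(X, y, seed=4, n_trees=50) == tune_rf(X, y, seed=4, n_trees=50)

    def test_degenerate_outcome_rejected(self, rng):
        with pytest.raises(ValueError, match="zero variance"):
            tune_rf(rng.normal(size=(30, 3)), np.ones(30))

    def test_hyperparam_invariants(self):
        with pytest.raises(ValueError):
            RFHyperparams(0, 0.5)
        with pytest.raises(ValueError):
            RFHyperparams(2, 1.5)
        with pytest.raises(ValueError):
            RFHyperparams(2, 0.5, n_trees=10)


class TestRepeatedCV:
    def test_strong_linear_signal_high_pearson(self, rng):
        X = rng.normal(size=(200, 3))
        y = X[:, 0] + 0.5 * X[:, 1]  # deterministic
        res = repeated_cv(X, y, RFHyperparams(2, 0.9, 200), repeats=3, seed=0)
        assert res.cv_pearson_median > 0.9

    def test_null_signal_near_zero(self, rng):
        X = rng.normal(size=(150, 3))
        y = rng.normal(size=150)
        res = repeated_cv(X, y, RFHyperparams(2, 0.9, 100), repeats=3, seed=0)
        assert abs(res.cv_pearson_median) < 0.3

    def test_leave_one_out_boundary(self, rng):
        X = rng.normal(size=(16, 2))
        y = X[:, 0] + rng.normal(0, 0.2, 16)
        res = repeated_cv(X, y, RFHyperparams(1, 1.0, 50), folds=8, repeats=1, seed=0)
        assert np.isfinite(res.cv_pearson_median)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            repeated_cv(rng.normal(size=(5, 2)), rng.normal(size=5),
                        RFHyperparams(1, 1.0, 50))


class TestPermutationTest:
    def test_observed_beats_every_null_gives_add_one_p(self, rng):
        X = rng.normal(size=(80, 3))
        y = 2 * X[:, 0]  # overwhelming signal
        res = permutation_null_test(
            X, y, B=19, repeats=1, folds=4, seed=0, retune=False,
            params=RFHyperparams(2, 0.9, 50),
        )
        assert res.p["pearson"] == pytest.approx(1 / 20)
        assert res.p["oob"] == pytest.approx(1 / 20)

    def test_small_b_rejected(self, rng):
        with pytest.raises(ValueError, match="B must be"):
            permutation_null_test(rng.normal(size=(30, 2)), rng.normal(size=30), B=5)

    def test_null_distributions_are_stored(self, rng):
        X = rng.normal(size=(60, 3))
        y = rng.normal(size=60)
        res = permutation_null_test(
            X, y, B=19, repeats=1, folds=2, seed=1, retune=False,
            params=RFHyperparams(1, 0.8, 50),
        )
        assert len(res.null_pearson) == 19 and len(res.null_oob) == 19
        assert 0 < res.p["pearson"] <= 1

    def test_bh_over_models_matches_step_up(self):
        np.testing.assert_allclose(
            bh_over_models([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04], atol=1e-12
        )


class TestAltmannImportance:
    def test_planted_feature_has_minimal_p(self, rng):
        n = 200
        X = rng.normal(size=(n, 6))
        y = X[:, 0] + rng.normal(0, 1, n)  # feature 0 explains ~50% of var
        res = altmann_importance(X, y, RFHyperparams(2, 0.9, 100), B=99, seed=0)
        tab = res.table.set_index("feature")
        assert tab.loc["f0", "p"] == pytest.approx(1 / 100)
        assert tab.index[0] == "f0"  # largest importance

    def test_noise_features_have_dispersed_p(self, rng):
        n = 150
        X = rng.normal(size=(n, 5))
        y = rng.normal(size=n)
        res = altmann_importance(X, y, RFHyperparams(2, 0.9, 50), B=49, seed=1)
        # under the null, p-values should span the unit interval
        assert res.table["p"].min() > 0
        assert 0.2 < res.table["p"].mean() < 0.8

    def test_constant_feature_convention(self, rng):
        X = rng.normal(size=(80, 3))
        X[:, 2] = 1.0
        y = X[:, 0] + rng.normal(0, 0.5, 80)
        res = altmann_importance(X, y, RFHyperparams(2, 0.9, 50), B=19, seed=2)
        row = res.table.set_index("feature").loc["f2"]
        assert row["importance"] == 0.0 and row["p"] == 1.0

    def test_duplicated_feature_still_gets_p_values(self, rng):
        X = rng.normal(size=(100, 2))
        X = np.column_stack([X, X[:, 0]])  # duplicate of the signal column
        y = X[:, 0] + rng.normal(0, 0.5, 100)
        res = altmann_importance(X, y, RFHyperparams(1, 0.9, 50), B=19, seed=3)
        assert res.table["p"].between(0, 1).all()


@pytest.fixture(scope="module")
def tiny_family():
    from microgrowth.synthetic import SimulationConfig, simulate_cohort

    cohort = simulate_cohort(
        SimulationConfig(n_subjects=60, seed=31,
                         effect_vector={"Subdoligranulum": -0.6},
                         effect_timepoints=("10y",))
    )
    return run_model_family(
        cohort.taxon_tables, cohort.cohort,
        list(cohort.truth["config"].anthro_timepoints),
        B=19, repeats=1, folds=4, tune_candidates=2, n_trees=50,
        retune=False, seed=5,
    )


class TestModelFamily:
    def test_report_shape(self, tiny_family):
        report, importances, results = tiny_family
        # 5 stool tps -> 5 cross-sectional + 5 future models, 2 metrics each
        assert len(report) == 20
        assert set(report["metric"]) == {"pearson", "oob"}
        assert report["q"].between(0, 1).all()

    def test_single_timepoint_has_no_future_model(self, null_cohort):
        report, _, _ = run_model_family(
            {"10y": null_cohort.taxon_tables["10y"]},
            null_cohort.cohort, ["10y"],
            B=19, repeats=1, folds=4, tune_candidates=2, n_trees=50,
            retune=False, seed=1,
        )
        assert set(zip(report.time_microbiota, report.time_zbmi)) == {("10y", "10y")}

    def test_deterministic_under_master_seed(self, null_cohort):
        kw = dict(B=19, repeats=1, folds=2, tune_candidates=2, n_trees=50,
                  retune=False, seed=9, compute_oob=False)
        tables = {"6y": null_cohort.taxon_tables["6y"]}
        r1, _, _ = run_model_family(tables, null_cohort.cohort, ["6y", "7y"], **kw)
        r2, _, _ = run_model_family(tables, null_cohort.cohort, ["6y", "7y"], **kw)
        pd.testing.assert_frame_equal(r1, r2)

    def test_unmatched_sample_ids_rejected(self, null_cohort, toy_table):
        with pytest.raises(ValueError, match="no cohort subject"):
            run_model_family(
                {"6y": toy_table}, null_cohort.cohort, ["6y"],
                B=19, repeats=1, folds=2, n_trees=50, seed=0,
            )
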