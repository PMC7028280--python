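"""Fold construction, CV statistics, and cross-validated runs."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

from ieg import synthetic
from ieg.evaluation import (
    CVConfig,
    CVData,
    compare_cv_schemes,
    cv_run,
    make_folds_buffer,
    make_folds_clustered,
    make_folds_conventional,
    mse_r2,
    pls_contribution,
    rmse,
    standardized_rmse,
)
from ieg.kriging import CovarianceParams, fit_uk, predict_uk


class TestConventionalFolds:
    def test_even_split(self):
        f = make_folds_conventional(100, 10, seed=1)
        assert sorted(np.bincount(f.labels)) == [10] * 10

    def test_uneven_split(self):
        f = make_folds_conventional(101, 10, seed=1)
        assert sorted(np.bincount(f.labels)) == [10] * 9 + [11]

    def test_seed_reproducible(self):
        a = make_folds_conventional(50, 10, seed=3)
        b = make_folds_conventional(50, 10, seed=3)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError):
            make_folds_conventional(5, 10)


class TestClusteredFolds:
    def test_well_separated_clumps_recovered(self):
        # clumps much tighter than their separation: k-means optimum = clumps
        sites = synthetic.gen_sites(300, 10, 5.0, (2000, 2000), seed=42)
        coords = sites[["x", "y"]].to_numpy(float)
        f = make_folds_clustered(coords, 10, seed=0)
        # fold labels must be a relabelling of clump membership
        df = pd.DataFrame({"clump": sites["clump"], "fold": f.labels})
        assert (df.groupby("clump")["fold"].nunique() == 1).all()
        assert df["fold"].nunique() == 10

    def test_ten_distinct_sites_each_own_fold(self, rng):
        coords = rng.uniform(0, 100, (10, 2))
        f = make_folds_clustered(coords, 10, seed=0)
        assert sorted(np.bincount(f.labels)) == [1] * 10

    def test_seed_reproducible(self, rng):
        coords = rng.uniform(0, 100, (40, 2))
        a = make_folds_clustered(coords, 5, seed=2)
        b = make_folds_clustered(coords, 5, seed=2)
        np.testing.assert_array_equal(a.labels, b.labels)


class TestStatistics:
    def test_perfect_prediction(self):
        obs = np.array([1.0, 2.0, 3.0])
        assert mse_r2(obs, obs) == 1.0
        assert standardized_rmse(obs, obs) == 0.0

    def test_constant_mean_prediction_scores_zero(self):
        obs = np.array([1.0, 2.0, 3.0, 6.0])
        pred = np.full(4, obs.mean())
        assert mse_r2(obs, pred) == 0.0

    def test_worse_than_mean_truncates_at_zero(self):
        obs = np.array([1.0, 2.0, 3.0])
        pred = np.array([30.0, -10.0, 7.0])
        assert mse_r2(obs, pred) == 0.0

    def test_standardized_rmse_worked_case(self):
        obs = np.array([2.0, 2.0, 2.0, 2.0])
        pred = np.array([1.0, 3.0, 1.0, 3.0])
        assert standardized_rmse(obs, pred) == 0.5

    def test_standardized_rmse_scale_invariant(self, rng):
        obs = rng.uniform(5, 10, 30)
        pred = obs + rng.normal(0, 1, 30)
        a = standardized_rmse(obs, pred)
        b = standardized_rmse(3 * obs, 3 * pred)
        assert a == pytest.approx(b)

    def test_r2_rmse_internal_consistency(self, rng):
        # 1 - (srmse * mean)^2 / var equals the untruncated R^2
        obs = rng.uniform(5, 15, 40)
        pred = obs + rng.normal(0, 2, 40)
        var = np.mean((obs - obs.mean()) ** 2)
        lhs = 1 - (standardized_rmse(obs, pred) * obs.mean()) ** 2 / var
        assert mse_r2(obs, pred) == pytest.approx(max(0.0, lhs))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            mse_r2(np.ones(5), np.zeros(5))

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            standardized_rmse(np.array([-1.0, 1.0]), np.zeros(2))


class TestPLSContribution:
    def test_no_pls_predictors_gives_zero(self):
        assert pls_contribution(np.zeros(5), np.ones(5)) == 0.0

    def test_no_kriging_adjustment_gives_one(self):
        assert pls_contribution(np.ones(5), np.zeros(5)) == 1.0

    def test_undefined_when_both_zero(self):
        assert np.isnan(pls_contribution(np.zeros(3), np.zeros(3)))

    def test_matches_dense_decomposition_on_toy_instance(self, rng):
        # hand decomposition via the BLUP formula on a 10-site instance
        coords = rng.uniform(0, 200, (10, 2))
        X = np.column_stack([np.ones(10), rng.standard_normal(10)])
        y = X @ np.array([5.0, 1.0]) + rng.normal(0, 0.5, 10)
        params = CovarianceParams(80.0, 1.0, 0.3)
        m = fit_uk(coords, X, y, fixed_cov=params)
        new_c = rng.uniform(0, 200, (4, 2))
        new_X = np.column_stack([np.ones(4), rng.standard_normal(4)])
        pred, _, comp = predict_uk(m, new_c, new_X, return_components=True)
        D0 = cdist(new_c, coords)
        C = params.partial_sill * np.exp(-cdist(coords, coords) / params.range_km)
        C += (params.nugget + 1e-10 * 1.3) * np.eye(10)
        c0 = params.partial_sill * np.exp(-D0 / params.range_km)
        krig_ref = c0 @ np.linalg.solve(C, y - X @ m.beta)
        mean_ref = new_X[:, 1:] @ m.beta[1:]
        np.testing.assert_allclose(comp["kriging"], krig_ref, rtol=1e-6)
        np.testing.assert_allclose(comp["mean"], mean_ref, rtol=1e-10)
        np.testing.assert_allclose(pred, comp["intercept"] + comp["mean"]
                                   + comp["kriging"])


class TestCVRun:
    def test_every_site_predicted_once(self, small_dataset):
        data, _ = small_dataset
        folds = make_folds_conventional(len(data.site_ids), 10, seed=0)
        res = cv_run(data, CVConfig(k_vars=4, ncomp=2), folds)
        assert sorted(res.pairs["site_id"]) == sorted(data.site_ids)

    def test_exact_linear_response_gives_r2_one(self, rng):
        # y an exact linear function of covariate 1, no noise
        n = 60
        coords = rng.uniform(0, 500, (n, 2))
        cov = rng.uniform(0, 2, (n, 3))
        y_sqrt = 5.0 + 2.0 * cov[:, 0]
        data = CVData(
            site_ids=np.array([f"s{i}" for i in range(n)]),
            coords=coords,
            covariates=cov,
            y_sqrt=y_sqrt,
            y_native=y_sqrt**2,
        )
        folds = make_folds_conventional(n, 10, seed=0)
        res = cv_run(data, CVConfig(k_vars=1, ncomp=1), folds)
        assert res.r2 == pytest.approx(1.0, abs=1e-6)

    def test_zero_k_is_ordinary_kriging(self, small_dataset):
        data, _ = small_dataset
        folds = make_folds_conventional(len(data.site_ids), 10, seed=0)
        res = cv_run(data, CVConfig(k_vars=0), folds)
        assert res.pls_contrib == 0.0

    def test_pure_noise_scores_zero_r2_clustered(self, rng):
        # no mean structure, no spatial structure: nothing to recover
        sites = synthetic.gen_sites(80, 8, 20.0, (800, 800), seed=31)
        coords = sites[["x", "y"]].to_numpy(float)
        y_sqrt = 6.0 + rng.normal(0, 0.5, 80)
        data = CVData(
            site_ids=sites["site_id"].to_numpy(),
            coords=coords,
            covariates=rng.standard_normal((80, 10)),
            y_sqrt=y_sqrt,
            y_native=y_sqrt**2,
        )
        folds = make_folds_clustered(coords, 8, seed=0)
        res = cv_run(data, CVConfig(k_vars=0), folds)
        assert res.r2 < 0.05

    def test_selection_inside_cv_runs(self, small_dataset):
        data, _ = small_dataset
        folds = make_folds_conventional(len(data.site_ids), 5, seed=0)
        res = cv_run(
            data, CVConfig(k_vars=3, ncomp=2, selection_inside_cv=True), folds
        )
        assert len(res.pairs) == len(data.site_ids)
        assert np.isfinite(res.r2)


class TestBufferOutCV:
    def test_zero_radius_is_leave_one_out(self, small_dataset):
        data, _ = small_dataset
        folds = make_folds_buffer(data.coords, 0.0)
        res = cv_run(data, CVConfig(k_vars=2, ncomp=2), folds)
        assert len(res.pairs) == len(data.site_ids)
        assert res.n_skipped_sites == 0

    def test_large_radius_fails_with_diagnostic(self, small_dataset):
        data, _ = small_dataset
        folds = make_folds_buffer(data.coords, 5000.0)
        with pytest.raises(RuntimeError, match="skipped"):
            cv_run(data, CVConfig(k_vars=2, ncomp=2), folds)

    def test_training_sets_respect_buffer(self, small_dataset):
        # buffer CV predictions must differ from plain LOO when the buffer
        # removes informative neighbours
        data, _ = small_dataset
        loo = cv_run(data, CVConfig(k_vars=2, ncomp=2),
                     make_folds_buffer(data.coords, 0.0))
        buf = cv_run(data, CVConfig(k_vars=2, ncomp=2),
                     make_folds_buffer(data.coords, 100.0))
        assert buf.r2 <= loo.r2 + 0.05


class TestCompareSchemes:
    def _mk(self, scheme, k, r2, srmse):
        cfg = CVConfig(k_vars=k)
        pairs = pd.DataFrame({"site_id": ["a"], "fold": [0], "obs": [1.0],
                              "pred": [1.0], "sqrt_pred": [1.0],
                              "converged": [True]})
        from ieg.evaluation import CVResult
        return CVResult(pairs, cfg, scheme, r2, srmse * 2.0, srmse, 0, 0.5)

    def test_single_configuration_is_best_and_worst(self):
        t = compare_cv_schemes([self._mk("conventional", 5, 0.7, 0.2)])
        assert set(t["which"]) == {"best", "worst"}
        assert (t["k_vars"] == 5).all()

    def test_higher_r2_wins(self):
        t = compare_cv_schemes(
            [self._mk("conventional", 5, 0.8, 0.2),
             self._mk("conventional", 10, 0.5, 0.3)]
        )
        best = t[t["which"] == "best"].iloc[0]
        assert best["k_vars"] == 5 and best["r2"] == 0.8

    def test_tie_broken_by_standardized_rmse(self):
        t = compare_cv_schemes(
            [self._mk("conventional", 5, 0.8, 0.3),
             self._mk("conventional", 10, 0.8, 0.2)]
        )
        assert t[t["which"] == "best"].iloc[0]["k_vars"] == 10
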