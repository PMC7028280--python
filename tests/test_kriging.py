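"""Universal kriging against dense brute-force matrix oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from ieg import synthetic
from ieg.kriging import (
    JITTER_REL,
    CovarianceParams,
    back_transform,
    exp_cov,
    fit_uk,
    neg_log_lik,
    predict_uk,
)


def dense_cov(coords, params):
    D = cdist(coords, coords)
    C = params.partial_sill * np.exp(-D / params.range_km)
    C += (params.nugget + JITTER_REL * (params.partial_sill + params.nugget)) * np.eye(
        len(coords)
    )
    return C


def dense_nll(params, coords, X, y):
    """Textbook Gaussian NLL with GLS beta, via explicit matrix inverses."""
    C = dense_cov(coords, params)
    Ci = np.linalg.inv(C)
    beta = np.linalg.solve(X.T @ Ci @ X, X.T @ Ci @ y)
    r = y - X @ beta
    sign, logdet = np.linalg.slogdet(C)
    n = len(y)
    return 0.5 * (n * np.log(2 * np.pi) + logdet + r @ Ci @ r), beta


def dense_blup(params, coords, X, y, x0, coords0):
    """Direct universal-kriging predictor and variance by explicit inverses."""
    C = dense_cov(coords, params)
    Ci = np.linalg.inv(C)
    beta = np.linalg.solve(X.T @ Ci @ X, X.T @ Ci @ y)
    c0 = params.partial_sill * np.exp(
        -cdist(coords0, coords) / params.range_km
    )
    pred = x0 @ beta + c0 @ Ci @ (y - X @ beta)
    sill = params.partial_sill + params.nugget
    XtCiX_inv = np.linalg.inv(X.T @ Ci @ X)
    var = np.empty(len(x0))
    for i in range(len(x0)):
        u = x0[i] - X.T @ Ci @ c0[i]
        var[i] = sill - c0[i] @ Ci @ c0[i] + u @ XtCiX_inv @ u
    return pred, var


def _random_instance(rng, n, q=2):
    coords = rng.uniform(0, 500, (n, 2))
    X = np.column_stack([np.ones(n), rng.standard_normal((n, q - 1))])
    params = CovarianceParams(
        range_km=float(rng.uniform(50, 300)),
        partial_sill=float(rng.uniform(0.5, 4.0)),
        nugget=float(rng.uniform(0.1, 2.0)),
    )
    beta = rng.standard_normal(q)
    L = np.linalg.cholesky(dense_cov(coords, params))
    y = X @ beta + L @ rng.standard_normal(n)
    return coords, X, y, params


class TestExpCov:
    def test_zero_distance_includes_nugget(self):
        p = CovarianceParams(100.0, 3.0, 1.0)
        assert exp_cov(0.0, p) == pytest.approx(4.0)

    def test_at_range_decays_to_e_inverse(self):
        p = CovarianceParams(100.0, 3.0, 1.0)
        assert exp_cov(100.0, p) == pytest.approx(3.0 / np.e)

    def test_far_field_vanishes(self):
        p = CovarianceParams(1.0, 3.0, 1.0)
        assert exp_cov(100.0, p) < 3.0 * 4e-44 + 1e-300

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            CovarianceParams(-1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            CovarianceParams(10.0, 0.0, 0.0)


class TestNegLogLik:
    def test_matches_dense_oracle_on_random_instances(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 26))
            coords, X, y, params = _random_instance(rng, n)
            ours = neg_log_lik(params, coords, X, y)
            ref, _ = dense_nll(params, coords, X, y)
            assert ours == pytest.approx(ref, rel=1e-8)

    def test_continuous_in_nugget(self, rng):
        coords, X, y, params = _random_instance(rng, 15)
        grid = np.linspace(params.nugget, 2 * params.nugget, 50)
        vals = [
            neg_log_lik(
                CovarianceParams(params.range_km, params.partial_sill, g),
                coords, X, y,
            )
            for g in grid
        ]
        steps = np.abs(np.diff(vals))
        assert steps.max() < 10 * np.median(steps) + 1e-6

    def test_site_permutation_invariance(self, rng):
        coords, X, y, params = _random_instance(rng, 18)
        perm = rng.permutation(18)
        a = neg_log_lik(params, coords, X, y)
        b = neg_log_lik(params, coords[perm], X[perm], y[perm])
        assert a == pytest.approx(b, rel=1e-10)


class TestFitUK:
    def test_likelihood_at_optimum_beats_all_starts(self, rng):
        # allowance of 0.5 for the documented nugget-boundary tie-break
        coords, X, y, _ = _random_instance(rng, 40)
        m = fit_uk(coords, X, y)
        assert -m.log_lik <= np.min(m.start_nlls) + 0.5 + 1e-6

    def test_translation_invariance(self, rng):
        coords, X, y, _ = _random_instance(rng, 30)
        a = fit_uk(coords, X, y)
        b = fit_uk(coords + np.array([1234.5, -678.9]), X, y)
        assert a.cov.range_km == pytest.approx(b.cov.range_km, rel=1e-4)
        np.testing.assert_allclose(a.beta, b.beta, rtol=1e-5)

    def test_pure_noise_pushes_partial_sill_to_boundary(self):
        hits = 0
        for s in range(20):
            r = np.random.default_rng(1000 + s)
            coords = r.uniform(0, 500, (60, 2))
            y = r.standard_normal(60)
            m = fit_uk(coords, np.ones((60, 1)), y)
            if m.cov.partial_sill < 0.05 * m.cov.nugget:
                hits += 1
        assert hits >= 16

    def test_rank_deficient_design_rejected(self, rng):
        coords = rng.uniform(0, 100, (20, 2))
        X = np.ones((20, 2))  # duplicated intercept
        with pytest.raises(ValueError, match="rank"):
            fit_uk(coords, X, rng.standard_normal(20))


class TestPredictUK:
    def test_matches_dense_oracle(self, rng):
        for _ in range(5):
            n = int(rng.integers(5, 20))
            coords, X, y, params = _random_instance(rng, n)
            m = fit_uk(coords, X, y, fixed_cov=params)
            coords0 = rng.uniform(0, 500, (4, 2))
            x0 = np.column_stack([np.ones(4), rng.standard_normal(4)])
            pred, var = predict_uk(m, coords0, x0)
            ref_p, ref_v = dense_blup(params, coords, X, y, x0, coords0)
            np.testing.assert_allclose(pred, ref_p, rtol=1e-8, atol=1e-10)
            np.testing.assert_allclose(var, ref_v, rtol=1e-6, atol=1e-8)

    def test_zero_nugget_interpolates_training_data(self, rng):
        coords, X, y, _ = _random_instance(rng, 25)
        params = CovarianceParams(150.0, 2.0, 0.0)
        m = fit_uk(coords, X, y, fixed_cov=params)
        pred, _ = predict_uk(m, coords, X)
        np.testing.assert_allclose(pred, y, atol=1e-6)

    def test_far_field_prediction_reverts_to_mean_surface(self, rng):
        coords, X, y, _ = _random_instance(rng, 20)
        params = CovarianceParams(5.0, 2.0, 0.5)
        m = fit_uk(coords, X, y, fixed_cov=params)
        far = coords + 5000.0
        x0 = X.copy()
        pred, _ = predict_uk(m, far, x0)
        np.testing.assert_allclose(pred, x0 @ m.beta, atol=1e-8)

    def test_shrinks_to_observation_as_nugget_vanishes(self, rng):
        coords, X, y, _ = _random_instance(rng, 15)
        errs = []
        for nug in (2.0, 0.5, 0.1, 0.01):
            m = fit_uk(coords, X, y, fixed_cov=CovarianceParams(100.0, 2.0, nug))
            pred, _ = predict_uk(m, coords, X)
            errs.append(np.abs(pred - y).max())
        assert all(np.diff(errs) < 0)

    def test_chunked_prediction_identical(self, rng):
        coords, X, y, params = _random_instance(rng, 30)
        m = fit_uk(coords, X, y, fixed_cov=params)
        coords0 = rng.uniform(0, 500, (57, 2))
        x0 = np.column_stack([np.ones(57), rng.standard_normal(57)])
        a = predict_uk(m, coords0, x0, chunk_size=7)
        b = predict_uk(m, coords0, x0, chunk_size=1000)
        np.testing.assert_allclose(a[0], b[0])
        np.testing.assert_allclose(a[1], b[1])

    def test_design_mismatch_rejected(self, rng):
        coords, X, y, params = _random_instance(rng, 12)
        m = fit_uk(coords, X, y, fixed_cov=params)
        with pytest.raises(ValueError, match="design"):
            predict_uk(m, coords[:2], np.ones((2, 5)))


class TestBackTransform:
    def test_squares_positive_predictions(self):
        out, n = back_transform(np.array([3.0]))
        assert out[0] == 9.0 and n == 0

    def test_floors_negative_predictions(self):
        out, n = back_transform(np.array([-0.2, 2.0]))
        assert out[0] == 0.0 and n == 1

    def test_round_trip_identity(self, rng):
        x = rng.normal(0, 2, 50)
        out, _ = back_transform(x)
        np.testing.assert_allclose(np.sqrt(out), np.clip(x, 0, None))


class TestOrdinaryKrigingSpecialCase:
    def test_intercept_only_design_is_ordinary_kriging(self):
        # constant mean: predictions far from data equal the GLS mean
        r = np.random.default_rng(7)
        coords = r.uniform(0, 300, (40, 2))
        y = 5.0 + r.standard_normal(40)
        m = fit_uk(coords, np.ones((40, 1)), y)
        assert m.beta.shape == (1,)
        pred, _ = predict_uk(m, np.array([[5000.0, 5000.0]]), np.ones((1, 1)))
        assert pred[0] == pytest.approx(m.beta[0])
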