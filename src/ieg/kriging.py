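"""Universal kriging on the square-root concentration scale.

The annual average at a site is decomposed into a mean component (a linear
regression on an intercept and a few PLS summary predictors) and a spatially
correlated residual with exponential covariance

    C(d) = partial_sill * exp(-d / range) + nugget * 1(d == 0),

where ``range`` is the distance scale of spatial correlation, ``partial_sill``
the spatially structured variance and ``nugget`` the non-spatial variance.
Regression and covariance parameters are estimated jointly by maximum
likelihood: the Gaussian likelihood is profiled over the mean coefficients by
generalised least squares and optimised over (log range, log partial sill,
log nugget) from several starting points.  Prediction is the universal-kriging
BLUP with its standard variance, evaluated in chunks so large location sets
never materialise an n x m dense cross-covariance block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.spatial.distance import cdist

_LOG2PI = float(np.log(2.0 * np.pi))
#: Relative ridge added to the covariance diagonal for factorisation stability.
JITTER_REL = 1e-10


@dataclass(frozen=True)
class CovarianceParams:
    """Exponential-covariance parameters (range in km, variances in sqrt-units^2)."""

    range_km: float
    partial_sill: float
    nugget: float

    def __post_init__(self) -> None:
        if self.range_km <= 0:
            raise ValueError("range must be positive")
        if self.partial_sill < 0 or self.nugget < 0:
            raise ValueError("partial sill and nugget must be non-negative")
        if self.partial_sill + self.nugget <= 0:
            raise ValueError("partial sill + nugget must be positive")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.range_km, self.partial_sill, self.nugget)


def exp_cov(d, params: CovarianceParams):
    """Exponential covariance at distance(s) ``d``.

    The nugget contributes only at identically zero distance; co-located
    distinct sites should be offered a tiny positive distance by the caller if
    they are to be treated as distinct measurements.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    out = params.partial_sill * np.exp(-d / params.range_km)
    return out + params.nugget * (d == 0)


def _cov_matrix(D: np.ndarray, params: CovarianceParams) -> np.ndarray:
    n = D.shape[0]
    cov = params.partial_sill * np.exp(-D / params.range_km)
    cov[np.diag_indices(n)] += params.nugget
    cov[np.diag_indices(n)] += JITTER_REL * (params.partial_sill + params.nugget)
    return cov


def _profiled_nll(D, X, y, params: CovarianceParams):
    """GLS-profiled Gaussian negative log-likelihood and its by-products."""
    n = len(y)
    cov = _cov_matrix(D, params)
    try:
        c, low = cho_factor(cov, lower=True)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(f"covariance not PSD after jitter: {e}") from e
    L = np.tril(c)
    b = solve_triangular(L, y, lower=True)
    if X.shape[1] == 0:  # known (zero) mean: covariance-only likelihood
        A = np.empty((n, 0))
        AtA = np.empty((0, 0))
        beta = np.empty(0)
        r = b
    else:
        A = solve_triangular(L, X, lower=True)
        AtA = A.T @ A
        beta = np.linalg.solve(AtA, A.T @ b)
        r = b - A @ beta
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    nll = 0.5 * (n * _LOG2PI + logdet + float(r @ r))
    return nll, beta, (c, low), AtA


def neg_log_lik(
    params: CovarianceParams, coords: np.ndarray, design: np.ndarray, y: np.ndarray
) -> float:
    """Negative log-likelihood with mean coefficients profiled out by GLS."""
    coords = np.asarray(coords, dtype=float)
    D = cdist(coords, coords)
    nll, _, _, _ = _profiled_nll(D, np.asarray(design, float), np.asarray(y, float), params)
    return nll


@dataclass
class UKModel:
    """Fitted universal-kriging model (sqrt concentration scale)."""

    beta: np.ndarray  # coefficients over [intercept | PLS scores]
    cov: CovarianceParams
    coords: np.ndarray
    design: np.ndarray
    y: np.ndarray
    log_lik: float
    converged: bool
    n_starts_converged: int = 0
    start_nlls: np.ndarray = field(default_factory=lambda: np.empty(0))
    # prediction cache
    _chol: tuple | None = None
    _sigma_inv_resid: np.ndarray | None = None
    _sigma_inv_X: np.ndarray | None = None
    _XtSiX_inv: np.ndarray | None = None

    def _prepare(self) -> None:
        if self._chol is not None:
            return
        D = cdist(self.coords, self.coords)
        cov = _cov_matrix(D, self.cov)
        self._chol = cho_factor(cov, lower=True)
        resid = self.y - self.design @ self.beta
        self._sigma_inv_resid = cho_solve(self._chol, resid)
        self._sigma_inv_X = cho_solve(self._chol, self.design)
        self._XtSiX_inv = np.linalg.inv(self.design.T @ self._sigma_inv_X)


def _variogram_start(D, resid, d_max):
    """Moment-based start: short-range semivariance -> nugget, tail -> sill."""
    var = float(resid.var())
    iu = np.triu_indices(D.shape[0], k=1)
    d = D[iu]
    if d.size == 0 or var == 0:
        return (max(d_max / 3.0, 1.0), max(var, 1e-6), max(var, 1e-6))
    sv = 0.5 * (resid[iu[0]] - resid[iu[1]]) ** 2
    near = d <= np.quantile(d, 0.05)
    nugget0 = float(np.clip(sv[near].mean() if near.any() else 0.5 * var,
                            1e-3 * var, var))
    psill0 = max(var - nugget0, 0.05 * var)
    # distance at which binned semivariance first reaches 63% of the sill
    order = np.argsort(d)
    csum = np.cumsum(sv[order])
    run = csum / np.arange(1, len(sv) + 1)
    hit = np.nonzero(run >= 0.63 * var)[0]
    range0 = float(d[order][hit[0]]) if hit.size else d_max / 3.0
    return (max(range0, 1.0), psill0, nugget0)


def fit_uk(
    coords: np.ndarray,
    design: np.ndarray,
    y: np.ndarray,
    fixed_cov: CovarianceParams | None = None,
    range_bounds: tuple[float, float] | None = None,
    extra_starts: int = 0,
    seed: int = 0,
) -> UKModel:
    """Maximum-likelihood universal kriging fit.

    ``design`` is the mean design matrix ``[1 | PLS scores]`` (intercept-only
    for ordinary kriging).  Covariance parameters are optimised in log space
    under bound constraints from three multi-starts (variogram-informed,
    data-variance split, wide-range); the best local optimum is kept and
    non-convergence is flagged rather than raised.  With ``fixed_cov`` given,
    only the mean coefficients are estimated by GLS.
    """
    coords = np.asarray(coords, dtype=float)
    design = np.atleast_2d(np.asarray(design, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, q = design.shape
    if coords.shape[0] != n or y.shape[0] != n:
        raise ValueError("coords/design/y length mismatch")
    if fixed_cov is None and n < q + 3:
        raise ValueError("too few sites to estimate mean and covariance")
    if np.linalg.matrix_rank(design) < q:
        raise ValueError("design matrix is rank deficient")
    D = cdist(coords, coords)

    if fixed_cov is not None:
        nll, beta, _, _ = _profiled_nll(D, design, y, fixed_cov)
        return UKModel(
            beta=beta, cov=fixed_cov, coords=coords, design=design, y=y,
            log_lik=-nll, converged=True,
        )

    d_max = float(D.max()) if D.max() > 0 else 1.0
    if q:
        ols_beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ ols_beta
    else:
        resid = y.copy()
    var = float(resid.var())
    if var <= 0:
        var = max(float(y.var()), 1e-12)

    lo_r, hi_r = range_bounds if range_bounds is not None else (1.0, 10.0 * d_max)
    bounds = [
        (np.log(lo_r), np.log(hi_r)),
        (np.log(1e-6 * var), np.log(1e3 * var)),
        (np.log(1e-6 * var), np.log(1e3 * var)),
    ]

    med_d = float(np.median(D[np.triu_indices(n, k=1)])) if n > 1 else d_max
    starts = [
        _variogram_start(D, resid, d_max),
        (np.clip(med_d / 2.0, lo_r, hi_r), 0.5 * var, 0.5 * var),
        (np.clip(d_max, lo_r, hi_r), 0.9 * var, 0.1 * var),
    ]
    if extra_starts:
        rng = np.random.default_rng(seed)
        for _ in range(extra_starts):
            starts.append(
                (float(np.exp(rng.uniform(np.log(lo_r), np.log(hi_r)))),
                 var * float(np.exp(rng.uniform(-3, 1))),
                 var * float(np.exp(rng.uniform(-3, 1)))))

    def objective(theta):
        p = CovarianceParams(*np.exp(theta))
        try:
            nll, _, _, _ = _profiled_nll(D, design, y, p)
        except np.linalg.LinAlgError:
            return 1e12
        return nll if np.isfinite(nll) else 1e12

    best = None
    n_conv = 0
    start_nlls = []
    for s in starts:
        theta0 = np.log(np.clip(s, 1e-300, None))
        theta0 = np.clip(theta0, [b[0] for b in bounds], [b[1] for b in bounds])
        start_nlls.append(objective(theta0))
        res = optimize.minimize(
            objective, theta0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 200, "ftol": 1e-10},
        )
        if res.success:
            n_conv += 1
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
        raise RuntimeError("maximum-likelihood optimisation failed on all starts")
    params = CovarianceParams(*np.exp(best.x))
    # Identifiability tie-break: partial sill at near-zero range is
    # likelihood-equivalent to nugget, so the optimiser can land anywhere on
    # that flat ridge.  When a pure-nugget model comes within half a
    # log-likelihood unit of the optimum, prefer the boundary representation.
    nug_ml = max(float(np.mean(resid**2)), 1e-6 * var)
    pure = CovarianceParams(lo_r, 1e-6 * var, nug_ml)
    nll_pure, *_ = _profiled_nll(D, design, y, pure)
    if nll_pure <= best.fun + 0.5:
        params = pure
        best = optimize.OptimizeResult(fun=nll_pure, x=np.log(pure.as_tuple()))
    nll, beta, _, _ = _profiled_nll(D, design, y, params)
    return UKModel(
        beta=beta, cov=params, coords=coords, design=design, y=y,
        log_lik=-nll, converged=n_conv > 0, n_starts_converged=n_conv,
        start_nlls=np.asarray(start_nlls),
    )


def predict_uk(
    model: UKModel,
    new_coords: np.ndarray,
    new_design: np.ndarray,
    chunk_size: int = 4096,
    return_components: bool = False,
):
    """Universal-kriging BLUP and prediction variance on the sqrt scale.

    Returns ``(pred, var)`` where ``pred = x0' beta + c0' Sigma^-1 (y - X beta)``
    and ``var`` is the standard universal-kriging prediction variance for a new
    measurement (it includes the nugget).  With ``return_components=True`` a
    third element gives the decomposition ``(intercept, mean_part, krig_part)``
    per location, where ``mean_part`` is the non-intercept regression
    contribution and ``krig_part`` the kriging residual adjustment.
    """
    new_coords = np.atleast_2d(np.asarray(new_coords, dtype=float))
    new_design = np.atleast_2d(np.asarray(new_design, dtype=float))
    if new_design.shape[1] != model.design.shape[1]:
        raise ValueError("prediction design does not match training design")
    if new_coords.shape[0] != new_design.shape[0]:
        raise ValueError("coords/design row mismatch")
    model._prepare()
    m = new_coords.shape[0]
    pred = np.empty(m)
    var = np.empty(m)
    mean_part = np.empty(m)
    krig_part = np.empty(m)
    sill = model.cov.partial_sill + model.cov.nugget
    for a in range(0, m, chunk_size):
        b = min(a + chunk_size, m)
        D0 = cdist(new_coords[a:b], model.coords)
        C0 = model.cov.partial_sill * np.exp(-D0 / model.cov.range_km)
        mean_term = new_design[a:b] @ model.beta
        krig_term = C0 @ model._sigma_inv_resid
        pred[a:b] = mean_term + krig_term
        # var = sill - c0' Si c0 + u' (X' Si X)^-1 u,  u = x0 - X' Si c0
        SiC0 = cho_solve(model._chol, C0.T)  # n x chunk
        quad = np.einsum("ij,ji->i", C0, SiC0)
        u = new_design[a:b].T - model.design.T @ SiC0  # q x chunk
        quad2 = np.einsum("ij,jk,ik->i", u.T, model._XtSiX_inv, u.T)
        var[a:b] = np.clip(sill - quad + quad2, 0.0, None)
        intercept = model.beta[0] if model.beta.size else 0.0
        mean_part[a:b] = mean_term - intercept
        krig_part[a:b] = krig_term
    if return_components:
        intercept = model.beta[0] if model.beta.size else 0.0
        comp = {"intercept": intercept, "mean": mean_part, "kriging": krig_part}
        return pred, var, comp
    return pred, var


def back_transform(sqrt_preds: np.ndarray) -> tuple[np.ndarray, int]:
    """Square sqrt-scale predictions onto the native concentration scale.

    Negative sqrt-scale predictions are floored at zero before squaring; the
    number floored is returned alongside.
    """
    sqrt_preds = np.asarray(sqrt_preds, dtype=float)
    n_floored = int((sqrt_preds < 0).sum())
    return np.clip(sqrt_preds, 0.0, None) ** 2, n_floored
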