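"""Partial least squares summary predictors for the model mean.

PLS components maximise covariance between the (standardised) covariates and
the sqrt-scale concentrations, collapsing a few-hundred-column covariate
matrix into two or three summary predictors that feed the universal-kriging
mean.  Fitting is delegated to scikit-learn's NIPALS implementation; on top
of it we fix the per-component sign (largest-magnitude weight positive) so
that fits are comparable across cross-validation folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cross_decomposition import PLSRegression


@dataclass
class PLSModel:
    """Fitted PLS projection.

    ``weights`` (p x ncomp) and ``loadings`` (p x ncomp) are the X-side weight
    and loading matrices, ``y_loadings`` the response loadings, ``rotations``
    the projection matrix such that ``scores = (Z - x_mean) @ rotations``, and
    ``scores`` the training score matrix T with mutually orthogonal columns.
    """

    n_components: int
    weights: np.ndarray
    loadings: np.ndarray
    y_loadings: np.ndarray
    rotations: np.ndarray
    x_mean: np.ndarray
    scores: np.ndarray


def fit_pls(Z: np.ndarray, y: np.ndarray, ncomp: int = 2) -> PLSModel:
    """Fit an ``ncomp``-component PLS regression of ``y`` on scaled covariates.

    ``Z`` must already be standardised with training statistics (see
    :mod:`ieg.covariates`); no further per-column scaling is applied here, only
    centring.  Deterministic up to the enforced sign convention.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if ncomp < 1:
        raise ValueError("ncomp must be >= 1")
    if np.isnan(Z).any() or np.isnan(y).any():
        raise ValueError("missing values in PLS inputs")
    Zc = Z - Z.mean(axis=0)
    rank = np.linalg.matrix_rank(Zc)
    if ncomp > rank:
        raise ValueError(f"ncomp={ncomp} exceeds rank {rank} of the design")
    yc = y - y.mean()
    cov = Zc.T @ yc
    scale = np.linalg.norm(Zc) * np.linalg.norm(yc)
    if scale == 0 or np.linalg.norm(cov) < 1e-12 * scale:
        # degenerate covariance-maximisation limit: the response carries no
        # linear signal, so response loadings are zero and the component
        # directions fall back to the principal axes of Z
        _, _, Vt = np.linalg.svd(Zc, full_matrices=False)
        W = Vt[:ncomp].T
        T = Zc @ W
        return _signed_model(ncomp, W, W.copy(), np.zeros(ncomp), W.copy(),
                             Z.mean(axis=0), T)
    pls = PLSRegression(n_components=ncomp, scale=False)
    pls.fit(Z, y)
    W = pls.x_weights_.copy()
    P = pls.x_loadings_.copy()
    q = pls.y_loadings_.ravel().copy()
    R = pls.x_rotations_.copy()
    T = pls.x_scores_.copy()
    return _signed_model(ncomp, W, P, q, R, pls._x_mean.copy(), T)


def _signed_model(ncomp, W, P, q, R, x_mean, T) -> PLSModel:
    """Apply the sign convention: largest-|w| entry positive per component."""
    for k in range(ncomp):
        j = np.argmax(np.abs(W[:, k]))
        if W[j, k] < 0:
            W[:, k] *= -1
            P[:, k] *= -1
            R[:, k] *= -1
            T[:, k] *= -1
            q[k] *= -1
    return PLSModel(
        n_components=ncomp,
        weights=W,
        loadings=P,
        y_loadings=q,
        rotations=R,
        x_mean=x_mean,
        scores=T,
    )


def project(model: PLSModel, Z_new: np.ndarray) -> np.ndarray:
    """Project new (already scaled) covariate rows onto the PLS components.

    Projecting the training matrix reproduces the stored training scores.
    """
    Z_new = np.atleast_2d(np.asarray(Z_new, dtype=float))
    if Z_new.shape[1] != model.rotations.shape[0]:
        raise ValueError("column count does not match the fitted PLS model")
    return (Z_new - model.x_mean) @ model.rotations
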