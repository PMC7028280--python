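"""Model evaluation: fold construction, cross-validated prediction, statistics.

Three hold-out schemes are supported.  Conventional 10-fold CV randomly
partitions sites; spatially clustered CV uses k-means clusters of the site
coordinates as folds, probing performance far from any monitor; buffer-out CV
leaves out, for each site, every site within a radius (50-300 km) and scores
a leave-one-out prediction.  Summary statistics are the root-mean-square
error, the standardized RMSE (RMSE over the mean observed concentration),
and the MSE-based R^2 -- 1 minus MSE over the data variance, truncated at
zero -- which measures agreement about the 1:1 line rather than about the
regression line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from . import selection as sel
from .covariates import apply_scaling, fit_scaling
from .kriging import CovarianceParams, UKModel, back_transform, fit_uk, predict_uk
from .pls import fit_pls, project

BUFFER_RADII = (50.0, 100.0, 200.0, 300.0)


@dataclass(frozen=True)
class FoldAssignment:
    scheme: str  # "conventional" | "clustered" | "buffer_out"
    labels: np.ndarray | None  # per-site fold label (None for buffer_out)
    k_folds: int
    seed: int
    radius_km: float | None = None

    def __post_init__(self) -> None:
        if self.scheme in ("conventional", "clustered"):
            counts = np.bincount(self.labels, minlength=self.k_folds)
            if (counts == 0).any():
                raise ValueError("empty fold in partition")


def make_folds_conventional(n: int, k_folds: int = 10, seed: int = 0) -> FoldAssignment:
    """Random partition into ``k_folds`` groups with sizes differing by <= 1."""
    if n < k_folds:
        raise ValueError(f"need n >= k_folds, got {n} < {k_folds}")
    rng = np.random.default_rng(seed)
    labels = np.empty(n, dtype=int)
    perm = rng.permutation(n)
    for f, idx in enumerate(np.array_split(perm, k_folds)):
        labels[idx] = f
    return FoldAssignment("conventional", labels, k_folds, seed)


def make_folds_clustered(
    coords: np.ndarray, k_folds: int = 10, seed: int = 0, n_init: int = 20
) -> FoldAssignment:
    """k-means spatial clusters of the site coordinates, one cluster per fold."""
    coords = np.asarray(coords, dtype=float)
    if len(np.unique(coords, axis=0)) < k_folds:
        raise ValueError("fewer distinct locations than clusters")
    km = KMeans(n_clusters=k_folds, n_init=n_init, random_state=seed)
    labels = km.fit_predict(coords)
    return FoldAssignment("clustered", labels.astype(int), k_folds, seed)


def make_folds_buffer(
    coords: np.ndarray, radius_km: float, seed: int = 0
) -> FoldAssignment:
    """Leave-one-out with every site within ``radius_km`` of the test site
    also removed from training."""
    if radius_km < 0:
        raise ValueError("radius must be non-negative")
    coords = np.asarray(coords, dtype=float)
    return FoldAssignment("buffer_out", None, len(coords), seed, radius_km=radius_km)


def mse_r2(obs: np.ndarray, pred: np.ndarray) -> float:
    """MSE-based R^2: max(0, 1 - MSE / population variance of obs)."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("obs and pred must be equal-length with n >= 2")
    var = float(np.mean((obs - obs.mean()) ** 2))
    if var == 0:
        raise ValueError("zero variance in observations")
    return max(0.0, 1.0 - float(np.mean((obs - pred) ** 2)) / var)


def rmse(obs: np.ndarray, pred: np.ndarray) -> float:
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def standardized_rmse(obs: np.ndarray, pred: np.ndarray) -> float:
    """RMSE divided by the mean observed concentration."""
    obs = np.asarray(obs, dtype=float)
    m = float(obs.mean())
    if m <= 0:
        raise ValueError("mean observed concentration must be positive")
    return rmse(obs, pred) / m


def pls_contribution(mean_parts: np.ndarray, krig_parts: np.ndarray) -> float:
    """Share of held-out sqrt-scale predictions carried by the PLS predictors.

    Each prediction decomposes into intercept + PLS-score contribution +
    kriging residual adjustment; the statistic is
    ``sum|PLS| / (sum|PLS| + sum|kriging|)``.  Returns NaN when both sums are
    zero (undefined).
    """
    p = float(np.abs(np.asarray(mean_parts, float)).sum())
    k = float(np.abs(np.asarray(krig_parts, float)).sum())
    if p + k == 0:
        return float("nan")
    return p / (p + k)


@dataclass
class CVData:
    """Everything a cross-validated model run needs, aligned by row."""

    site_ids: np.ndarray
    coords: np.ndarray  # n x 2 planar km
    covariates: np.ndarray  # n x p raw (filtered) covariate values
    y_sqrt: np.ndarray
    y_native: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.site_ids)
        if not (self.coords.shape[0] == self.covariates.shape[0]
                == self.y_sqrt.shape[0] == self.y_native.shape[0] == n):
            raise ValueError("row mismatch across CVData fields")


@dataclass(frozen=True)
class CVConfig:
    k_vars: int | str = 20  # number of covariates offered to PLS, or sel.ALL
    ncomp: int = 2
    selection_method: str = "forward"  # "forward" | "random"
    selection_inside_cv: bool = False
    selection_seed: int = 0
    ordered_indices: np.ndarray | None = None  # externally supplied ordering


@dataclass
class CVResult:
    pairs: pd.DataFrame  # site_id, fold, obs, pred, sqrt_pred, converged
    config: CVConfig
    scheme: str
    r2: float
    rmse_: float
    std_rmse: float
    n_nonconverged_folds: int
    pls_contrib: float
    n_skipped_sites: int = 0
    fold_cov_params: list = field(default_factory=list)


def _resolve_k(k_vars, p: int) -> int:
    return p if k_vars == sel.ALL else int(k_vars)


def _design_for(data: CVData, cfg: CVConfig, train_idx: np.ndarray):
    """Scaling + selection + PLS on the training rows; returns a projector."""
    Xtr = data.covariates[train_idx]
    stats = fit_scaling(Xtr)
    Ztr = apply_scaling(Xtr, stats)
    p = Ztr.shape[1]
    k = _resolve_k(cfg.k_vars, p)
    if k == 0:
        def make(rows):
            return np.ones((len(rows), 1))
        return make, None, None
    if cfg.ordered_indices is not None:
        idx = np.asarray(cfg.ordered_indices)[:k]
    elif cfg.selection_method == "random":
        idx = sel.random_select(p, k, seed=cfg.selection_seed).indices
    elif k == p:
        idx = np.arange(p)
    else:
        idx = sel.forward_select(Ztr, data.y_sqrt[train_idx], k).indices
    ncomp = min(cfg.ncomp, k)
    model = fit_pls(Ztr[:, idx], data.y_sqrt[train_idx], ncomp=ncomp)

    def make(rows):
        Z = apply_scaling(data.covariates[rows], stats)[:, idx]
        T = project(model, Z)
        return np.column_stack([np.ones(len(rows)), T])

    return make, idx, model


def cv_run(data: CVData, config: CVConfig, folds: FoldAssignment) -> CVResult:
    """Cross-validated universal-kriging run under one model configuration.

    With ``selection_inside_cv=False`` (the main analysis) scaling, variable
    selection and PLS estimation are done once on all sites and only the
    regression and covariance parameters are re-estimated per training fold;
    with ``True`` the whole model-building chain is repeated inside each fold.
    """
    n = len(data.site_ids)
    all_idx = np.arange(n)
    if folds.scheme == "buffer_out":
        return _cv_run_buffer(data, config, folds)
    if folds.labels.shape[0] != n:
        raise ValueError("fold labels inconsistent with data")

    if not config.selection_inside_cv:
        make_design, _, _ = _design_for(data, config, all_idx)

    rows = []
    n_bad = 0
    contrib_mean, contrib_krig = [], []
    fold_params = []
    for f in range(folds.k_folds):
        test = all_idx[folds.labels == f]
        train = all_idx[folds.labels != f]
        if config.selection_inside_cv:
            make_design, _, _ = _design_for(data, config, train)
        Xd_tr = make_design(train)
        Xd_te = make_design(test)
        model = fit_uk(data.coords[train], Xd_tr, data.y_sqrt[train])
        fold_params.append(model.cov)
        if not model.converged:
            n_bad += 1
        sqrt_pred, _, comp = predict_uk(
            model, data.coords[test], Xd_te, return_components=True
        )
        native_pred, _ = back_transform(sqrt_pred)
        contrib_mean.append(comp["mean"])
        contrib_krig.append(comp["kriging"])
        for i, site in enumerate(test):
            rows.append(
                {
                    "site_id": data.site_ids[site],
                    "fold": f,
                    "obs": data.y_native[site],
                    "pred": native_pred[i],
                    "sqrt_pred": sqrt_pred[i],
                    "converged": model.converged,
                }
            )
    pairs = pd.DataFrame(rows)
    ok = pairs[pairs["converged"]]
    return CVResult(
        pairs=pairs,
        config=config,
        scheme=folds.scheme,
        r2=mse_r2(ok["obs"].to_numpy(), ok["pred"].to_numpy()),
        rmse_=rmse(ok["obs"].to_numpy(), ok["pred"].to_numpy()),
        std_rmse=standardized_rmse(ok["obs"].to_numpy(), ok["pred"].to_numpy()),
        n_nonconverged_folds=n_bad,
        pls_contrib=pls_contribution(
            np.concatenate(contrib_mean), np.concatenate(contrib_krig)
        ),
        fold_cov_params=fold_params,
    )


def _cv_run_buffer(data: CVData, config: CVConfig, folds: FoldAssignment) -> CVResult:
    """Leave-one-out with a spatial exclusion buffer around each test site."""
    n = len(data.site_ids)
    all_idx = np.arange(n)
    D = cdist(data.coords, data.coords)
    if not config.selection_inside_cv:
        make_design, _, _ = _design_for(data, config, all_idx)
    rows = []
    n_bad = 0
    n_skipped = 0
    contrib_mean, contrib_krig = [], []
    min_fit = 10
    for i in range(n):
        train = all_idx[(D[i] > folds.radius_km) & (all_idx != i)]
        if len(train) < min_fit:
            n_skipped += 1
            continue
        if config.selection_inside_cv:
            make_design, _, _ = _design_for(data, config, train)
        model = fit_uk(data.coords[train], make_design(train), data.y_sqrt[train])
        if not model.converged:
            n_bad += 1
        sqrt_pred, _, comp = predict_uk(
            model, data.coords[[i]], make_design(np.array([i])),
            return_components=True,
        )
        native_pred, _ = back_transform(sqrt_pred)
        contrib_mean.append(comp["mean"])
        contrib_krig.append(comp["kriging"])
        rows.append(
            {
                "site_id": data.site_ids[i],
                "fold": i,
                "obs": data.y_native[i],
                "pred": native_pred[0],
                "sqrt_pred": sqrt_pred[0],
                "converged": model.converged,
            }
        )
    if not rows:
        raise RuntimeError(
            "buffer-out CV: every site was skipped (training sets below the "
            f"minimum of {min_fit} sites at radius {folds.radius_km} km)"
        )
    pairs = pd.DataFrame(rows)
    ok = pairs[pairs["converged"]]
    return CVResult(
        pairs=pairs,
        config=config,
        scheme="buffer_out",
        r2=mse_r2(ok["obs"].to_numpy(), ok["pred"].to_numpy()),
        rmse_=rmse(ok["obs"].to_numpy(), ok["pred"].to_numpy()),
        std_rmse=standardized_rmse(ok["obs"].to_numpy(), ok["pred"].to_numpy()),
        n_nonconverged_folds=n_bad,
        pls_contrib=pls_contribution(
            np.concatenate(contrib_mean), np.concatenate(contrib_krig)
        ),
        n_skipped_sites=n_skipped,
    )


def compare_cv_schemes(results: list[CVResult]) -> pd.DataFrame:
    """Best and worst configuration per scheme.

    Best is the highest MSE-based R^2, ties broken by lower standardized RMSE
    and then by fewer variables; worst is the mirror image.
    """
    if not results:
        raise ValueError("no CV results to compare")
    df = pd.DataFrame(
        {
            "scheme": [r.scheme for r in results],
            "k_vars": [r.config.k_vars for r in results],
            "r2": [r.r2 for r in results],
            "std_rmse": [r.std_rmse for r in results],
            "rmse": [r.rmse_ for r in results],
        }
    )
    df["_k"] = [len(results[i].pairs) if k == sel.ALL else int(k)
                for i, k in enumerate(df["k_vars"])]
    out = []
    for scheme, grp in df.groupby("scheme"):
        best = grp.sort_values(["r2", "std_rmse", "_k"],
                               ascending=[False, True, True]).iloc[0]
        worst = grp.sort_values(["r2", "std_rmse", "_k"],
                                ascending=[True, False, False]).iloc[0]
        for label, row in (("best", best), ("worst", worst)):
            out.append(
                {"scheme": scheme, "which": label, "k_vars": row["k_vars"],
                 "r2": row["r2"], "std_rmse": row["std_rmse"], "rmse": row["rmse"]}
            )
    return pd.DataFrame(out)
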