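"""Parsimony sweeps and prediction aggregation.

The central experiment sweeps the number of forward-selected covariates
offered to PLS (from zero, i.e. ordinary kriging, through intermediate sizes
to the full covariate set) under conventional and spatially clustered
cross-validation, and summarises performance for the no-variable, 3-30-band
and all-variable models.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import selection as sel
from .covariates import apply_scaling, fit_scaling
from .evaluation import CVConfig, CVData, CVResult, FoldAssignment, cv_run
from .kriging import UKModel, back_transform, predict_uk

#: subset sizes counted into the "3-30" parsimony band
BAND_3_30 = (3, 5, 7, 10, 13, 16, 20, 25, 30)
#: number of PLS components per CV scheme (conventional / clustered)
DEFAULT_NCOMP = {"conventional": 2, "clustered": 3, "buffer_out": 2}


def _cell_path(checkpoint_dir, scheme: str, k) -> Path:
    return Path(checkpoint_dir) / f"cell_{scheme}_k{k}.json"


def parsimony_sweep(
    data: CVData,
    folds_by_scheme: dict[str, FoldAssignment],
    k_list=None,
    ncomp_by_scheme: dict[str, int] | None = None,
    selection_method: str = "forward",
    selection_seed: int = 0,
    selection_inside_cv: bool = False,
    checkpoint_dir=None,
) -> pd.DataFrame:
    """One cross-validated run per (subset size, CV scheme) cell.

    Forward selection is nested (the k-variable subset is a prefix of the
    k'-variable subset for k < k'), so the ordering is computed once on all
    sites and sliced per cell when selection stays outside the CV loop.
    Cells are checkpointed as small JSON files when ``checkpoint_dir`` is
    given, so a failed sweep can resume without recomputing finished cells.
    """
    p = data.covariates.shape[1]
    ks = sel.k_schedule(k_list, p=p)
    ncomps = {**DEFAULT_NCOMP, **(ncomp_by_scheme or {})}

    ordered = None
    if selection_method == "forward" and not selection_inside_cv:
        kmax = max(k for k in ks if k < p) if any(k < p for k in ks) else 0
        if kmax > 0:
            stats = fit_scaling(data.covariates)
            Z = apply_scaling(data.covariates, stats)
            ordered = sel.forward_select(Z, data.y_sqrt, kmax).indices

    rows = []
    for scheme, folds in folds_by_scheme.items():
        for k in ks:
            cell = _cell_path(checkpoint_dir, scheme, k) if checkpoint_dir else None
            if cell is not None and cell.exists():
                rows.append(json.loads(cell.read_text()))
                continue
            cfg = CVConfig(
                k_vars=k,
                ncomp=ncomps[scheme],
                selection_method=selection_method,
                selection_inside_cv=selection_inside_cv,
                selection_seed=selection_seed,
                ordered_indices=(ordered if (ordered is not None and 0 < k < p)
                                 else None),
            )
            res = cv_run(data, cfg, folds)
            row = {
                "scheme": scheme,
                "k_vars": int(k),
                "ncomp": min(ncomps[scheme], k) if k else 0,
                "selection": selection_method if 0 < k < p else "none",
                "r2": res.r2,
                "rmse": res.rmse_,
                "std_rmse": res.std_rmse,
                "pls_contribution": res.pls_contrib,
                "n_nonconverged_folds": res.n_nonconverged_folds,
            }
            if cell is not None:
                cell.parent.mkdir(parents=True, exist_ok=True)
                cell.write_text(json.dumps(row))
            rows.append(row)
    return pd.DataFrame(rows)


def summarize_bands(table: pd.DataFrame, band=BAND_3_30) -> pd.DataFrame:
    """No-variable / 3-30-band-median / all-variable triplets per scheme.

    The band median is taken over whichever band sizes are present in the
    table; missing ones are reported in the ``band_sizes_missing`` column.
    """
    out = []
    for scheme, grp in table.groupby("scheme"):
        kmax = grp["k_vars"].max()
        zero = grp[grp["k_vars"] == 0]
        full = grp[grp["k_vars"] == kmax]
        in_band = grp[grp["k_vars"].isin(band)]
        if in_band.empty:
            raise ValueError(f"no band rows for scheme {scheme!r}")
        missing = sorted(set(band) - set(in_band["k_vars"]))
        for stat in ("r2", "rmse", "std_rmse"):
            out.append(
                {
                    "scheme": scheme,
                    "statistic": stat,
                    "zero": float(zero[stat].iloc[0]) if len(zero) else np.nan,
                    "band_3_30": float(in_band[stat].median()),
                    "all": float(full[stat].iloc[0]) if len(full) else np.nan,
                    "band_sizes_missing": ",".join(map(str, missing)),
                }
            )
    return pd.DataFrame(out)


def predict_and_aggregate(
    model: UKModel,
    coords: np.ndarray,
    design: np.ndarray,
    populations: np.ndarray,
    groups: np.ndarray,
) -> pd.DataFrame:
    """Population-weighted mean predicted concentration per group.

    Predicts at each location on the sqrt scale, back-transforms to native
    units and averages within groups with population weights:
    ``sum(pop * pred) / sum(pop)``.
    """
    populations = np.asarray(populations, dtype=float)
    if (populations < 0).any():
        raise ValueError("populations must be non-negative")
    sqrt_pred, _ = predict_uk(model, coords, design)
    native, _ = back_transform(sqrt_pred)
    df = pd.DataFrame({"group": groups, "pop": populations, "pred": native})
    out = []
    for g, grp in df.groupby("group", sort=True):
        tot = grp["pop"].sum()
        if tot <= 0:
            raise ValueError(f"zero total population in group {g!r}")
        out.append(
            {
                "group": g,
                "population": tot,
                "weighted_mean": float((grp["pop"] * grp["pred"]).sum() / tot),
                "n_locations": len(grp),
            }
        )
    return pd.DataFrame(out)
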