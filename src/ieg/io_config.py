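"""CSV readers/writers and run configuration for the pipeline.

All tabular interchange is plain CSV with documented headers:

* site table: ``site_id, x, y`` (planar km) plus optional metadata columns;
* annual records: ``site_id, year, pollutant, value, sqrt_value``;
* covariate matrix: ``site_id`` plus one column per variable, with a sidecar
  categories CSV ``variable, category``;
* hourly series: ``timestamp, value``.

Geographic (lon/lat) site tables are projected to planar km about their
centroid at load time so every downstream distance is Euclidean km.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .covariates import CovariateMatrix
from .evaluation import CVData

EARTH_RADIUS_KM = 6371.0


def lonlat_to_planar_km(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Equirectangular projection about the centroid, in km.

    Adequate for regional-to-continental monitoring domains where
    sub-percent distance distortion is acceptable; keeps every downstream
    distance computation Euclidean.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lat0 = np.deg2rad(lat.mean())
    x = np.deg2rad(lon - lon.mean()) * np.cos(lat0) * EARTH_RADIUS_KM
    y = np.deg2rad(lat - lat.mean()) * EARTH_RADIUS_KM
    return np.column_stack([x, y])


@dataclass(frozen=True)
class RunConfig:
    """Normalised configuration for a pipeline run."""

    pollutant: str = "synthetic"
    schedule: str = "1-in-1"
    coordinate_mode: str = "planar_km"  # or "geographic"
    k_list: tuple = ()
    ncomp_conventional: int = 2
    ncomp_clustered: int = 3
    schemes: tuple = ("conventional", "clustered")
    buffer_radii: tuple = (50.0, 100.0, 200.0, 300.0)
    seed: int = 0
    k_folds: int = 10
    paths: dict = field(default_factory=dict)


def validate_config(raw: dict | RunConfig | None = None) -> RunConfig:
    """Fill defaults and reject malformed settings."""
    if raw is None:
        raw = {}
    if isinstance(raw, RunConfig):
        cfg = raw
    else:
        known = set(RunConfig.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = RunConfig(**{k: tuple(v) if isinstance(v, list) else v
                           for k, v in raw.items()})
    if cfg.coordinate_mode not in ("planar_km", "geographic"):
        raise ValueError(f"unknown coordinate mode {cfg.coordinate_mode!r}")
    for s in cfg.schemes:
        if s not in ("conventional", "clustered", "buffer_out"):
            raise ValueError(f"unknown CV scheme {s!r}")
    if any(r < 0 for r in cfg.buffer_radii):
        raise ValueError("buffer radii must be non-negative")
    if cfg.ncomp_conventional < 1 or cfg.ncomp_clustered < 1:
        raise ValueError("ncomp must be >= 1")
    for p in cfg.paths.values():
        if not Path(p).exists():
            raise FileNotFoundError(p)
    return cfg


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})


def _check_unique(ids: pd.Series, what: str) -> None:
    dup = ids[ids.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate site_id in {what}: {dup.iloc[0]!r}")


def load_tables(
    site_path,
    annual_path,
    covariate_path,
    categories_path=None,
    coordinate_mode: str = "planar_km",
) -> tuple[CVData, CovariateMatrix, dict]:
    """Load and join the site, annual-average and covariate CSVs.

    Sites missing covariates or measurements are dropped with a count
    (returned in the report dict); duplicate site ids are a hard error.
    """
    sites = pd.read_csv(site_path)
    annual = pd.read_csv(annual_path)
    covs = pd.read_csv(covariate_path)
    if covs.shape[1] < 2:
        raise ValueError("empty covariate file")
    _check_unique(sites["site_id"], "site table")
    _check_unique(covs["site_id"], "covariate table")
    _check_unique(annual["site_id"], "annual table")

    cats = None
    if categories_path is not None:
        cat_df = pd.read_csv(categories_path)
        cats = dict(zip(cat_df["variable"], cat_df["category"]))

    if coordinate_mode == "geographic":
        xy = lonlat_to_planar_km(sites["lon"], sites["lat"])
        sites = sites.assign(x=xy[:, 0], y=xy[:, 1])
    for col in ("x", "y"):
        if not np.issubdtype(sites[col].dtype, np.number):
            raise ValueError(f"non-numeric {col} column in site table")

    merged = sites.merge(annual, on="site_id", how="inner").merge(
        covs, on="site_id", how="inner"
    )
    if "included" in merged.columns:
        merged = merged[merged["included"]]
    n_dropped = len(sites) - len(merged)
    var_cols = [c for c in covs.columns if c != "site_id"]
    values = merged[var_cols].to_numpy(float)
    if np.isnan(values).any():
        raise ValueError("missing covariate values at retained sites")
    cm = CovariateMatrix(
        site_ids=merged["site_id"].to_numpy(),
        variable_names=var_cols,
        categories=cats or {c: "unknown" for c in var_cols},
        values=values,
    )
    y_native = merged["value"].to_numpy(float)
    y_sqrt = (merged["sqrt_value"].to_numpy(float)
              if "sqrt_value" in merged.columns else np.sqrt(y_native))
    data = CVData(
        site_ids=merged["site_id"].to_numpy(),
        coords=merged[["x", "y"]].to_numpy(float),
        covariates=values,
        y_sqrt=y_sqrt,
        y_native=y_native,
    )
    report = {"n_sites_in": len(sites), "n_sites_used": len(merged),
              "n_sites_dropped": n_dropped}
    return data, cm, report


def write_dataset(outdir, sites, covariates, records, truth=None) -> None:
    """Write a synthetic dataset as CSVs plus a truth/categories sidecar."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sites.to_csv(out / "sites.csv", index=False)
    covariates.to_csv(out / "covariates.csv", index=False)
    records.to_csv(out / "annual.csv", index=False)
    cats = covariates.attrs.get("categories")
    if cats:
        pd.DataFrame(
            {"variable": list(cats), "category": list(cats.values())}
        ).to_csv(out / "categories.csv", index=False)
    if truth is not None:
        (out / "truth.json").write_text(
            json.dumps(
                {
                    "beta": truth.beta.tolist(),
                    "informative_idx": truth.informative_idx.tolist(),
                    "cov_params": list(truth.cov_params),
                    "seed": truth.seed,
                },
                indent=1,
            )
        )


def save_uk_model(model, path) -> None:
    """Serialise a fitted universal-kriging model to one JSON bundle."""
    payload = {
        "beta": model.beta.tolist(),
        "cov": {"range_km": model.cov.range_km,
                "partial_sill": model.cov.partial_sill,
                "nugget": model.cov.nugget},
        "coords": model.coords.tolist(),
        "design": model.design.tolist(),
        "y": model.y.tolist(),
        "log_lik": model.log_lik,
        "converged": bool(model.converged),
    }
    Path(path).write_text(json.dumps(payload))


def load_uk_model(path):
    from .kriging import CovarianceParams, UKModel

    d = json.loads(Path(path).read_text())
    return UKModel(
        beta=np.array(d["beta"]),
        cov=CovarianceParams(**d["cov"]),
        coords=np.array(d["coords"]),
        design=np.array(d["design"]),
        y=np.array(d["y"]),
        log_lik=d["log_lik"],
        converged=d["converged"],
    )

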