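"""Covariate screening and standardisation.

Variables with little spatial variability (identical 10th and 90th
percentiles) or too few distinct values are excluded before modelling.
Scaling statistics are estimated on training sites only and reused verbatim
at prediction locations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_MIN_UNIQUE = 10


@dataclass
class CovariateMatrix:
    """Sites x variables matrix with per-variable category labels."""

    site_ids: np.ndarray
    variable_names: list[str]
    categories: dict[str, str]
    values: np.ndarray
    exclusions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["variable", "reason"])
    )

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.site_ids), len(self.variable_names)):
            raise ValueError("values shape inconsistent with ids/names")
        missing = [v for v in self.variable_names if v not in self.categories]
        if missing:
            raise ValueError(f"variables without category label: {missing[:5]}")
        if np.isnan(self.values).any():
            raise ValueError("missing values in covariate matrix")

    @classmethod
    def from_frame(
        cls, table: pd.DataFrame, categories: dict[str, str] | None = None
    ) -> "CovariateMatrix":
        cols = [c for c in table.columns if c != "site_id"]
        cats = categories or table.attrs.get("categories") or {c: "unknown" for c in cols}
        return cls(
            site_ids=table["site_id"].to_numpy(),
            variable_names=cols,
            categories={c: cats[c] for c in cols},
            values=table[cols].to_numpy(float),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.variable_names)
        df.insert(0, "site_id", self.site_ids)
        df.attrs["categories"] = dict(self.categories)
        return df

    def subset(self, names: list[str], reason_rows: pd.DataFrame | None = None):
        idx = [self.variable_names.index(v) for v in names]
        exc = self.exclusions
        if reason_rows is not None:
            exc = pd.concat([exc, reason_rows], ignore_index=True)
        return CovariateMatrix(
            site_ids=self.site_ids,
            variable_names=list(names),
            categories={v: self.categories[v] for v in names},
            values=self.values[:, idx],
            exclusions=exc,
        )


@dataclass(frozen=True)
class ScalingStats:
    """Per-variable mean and sd estimated on training sites."""

    variable_names: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray


def filter_variables(
    X: CovariateMatrix, min_unique: int = DEFAULT_MIN_UNIQUE
) -> CovariateMatrix:
    """Drop variables with q10 == q90 or fewer than ``min_unique`` distinct values.

    Percentiles use linear interpolation between order statistics and the
    equality test is exact on the interpolated values, so the decision is
    bit-stable across runs.  Exclusion reasons are recorded on the result.
    """
    keep, dropped = [], []
    for j, name in enumerate(X.variable_names):
        col = X.values[:, j]
        q10, q90 = np.percentile(col, [10, 90])
        if q10 == q90:
            dropped.append({"variable": name, "reason": "low_spatial_variability"})
        elif len(np.unique(col)) < min_unique:
            dropped.append({"variable": name, "reason": "few_unique_values"})
        else:
            keep.append(name)
    if not keep:
        raise ValueError("all variables excluded by the variability filter")
    return X.subset(keep, pd.DataFrame(dropped, columns=["variable", "reason"]))


def drop_category(X: CovariateMatrix, category_name: str) -> CovariateMatrix:
    """Remove every variable belonging to one category (sensitivity runs)."""
    if category_name not in set(X.categories.values()):
        raise ValueError(f"unknown category {category_name!r}")
    keep = [v for v in X.variable_names if X.categories[v] != category_name]
    rows = pd.DataFrame(
        [{"variable": v, "reason": f"category_excluded:{category_name}"}
         for v in X.variable_names if X.categories[v] == category_name]
    )
    return X.subset(keep, rows)


def fit_scaling(values: np.ndarray, variable_names=None) -> ScalingStats:
    """Training-site column means and standard deviations (population sd)."""
    values = np.asarray(values, dtype=float)
    mean = values.mean(axis=0)
    sd = values.std(axis=0)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"zero standard deviation in retained columns {bad[:5]}")
    names = tuple(variable_names) if variable_names is not None else tuple(
        f"V{j}" for j in range(values.shape[1])
    )
    return ScalingStats(variable_names=names, mean=mean, sd=sd)


def apply_scaling(values: np.ndarray, stats: ScalingStats) -> np.ndarray:
    """Standardise any site set with training statistics."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[1] != stats.mean.shape[0]:
        raise ValueError("column count does not match scaling statistics")
    return (values - stats.mean) / stats.sd
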