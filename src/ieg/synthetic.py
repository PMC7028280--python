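"""Synthetic monitoring-network generator with known ground truth.

Everything the modelling pipeline consumes can be generated here: clustered
site maps, geographic covariates with a known informative subset, Gaussian
random-field concentration surfaces on the square-root scale, and hourly time
series laid out on regulatory sampling schedules (every day, 1-in-3, 1-in-6).

All generators are pure functions of their arguments including the seed, so
any dataset can be regenerated exactly from its parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

#: The eleven geographic-covariate categories used for round-robin labelling.
CATEGORIES = (
    "traffic",
    "population",
    "urban_land_use",
    "rural_land_use",
    "elevation",
    "vegetation",
    "imperviousness",
    "industrial_emissions",
    "position",
    "source",
    "satellite",
)

SCHEDULES = {"1-in-1": 1, "1-in-3": 3, "1-in-6": 6}


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth behind a synthetic dataset.

    ``beta`` holds mean coefficients on the square-root concentration scale per
    z-unit of each covariate; it is zero outside ``informative_idx``.
    ``cov_params`` is the (range_km, partial_sill, nugget) triple of the latent
    exponential-covariance field.
    """

    beta: np.ndarray
    informative_idx: np.ndarray
    cov_params: tuple[float, float, float]
    seed: int

    def __post_init__(self) -> None:
        rng, psill, nugget = self.cov_params
        if rng <= 0 or psill < 0 or nugget < 0:
            raise ValueError(f"invalid covariance parameters {self.cov_params}")
        p = self.beta.shape[0]
        if len(self.informative_idx) and (
            self.informative_idx.min() < 0 or self.informative_idx.max() >= p
        ):
            raise ValueError("informative_idx out of range")
        mask = np.ones(p, dtype=bool)
        mask[self.informative_idx] = False
        if np.any(self.beta[mask] != 0):
            raise ValueError("beta must be zero outside informative_idx")


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect coordinates into [lo, hi] (billiard reflection at the edges)."""
    width = hi - lo
    y = np.mod(x - lo, 2 * width)
    y = np.where(y > width, 2 * width - y, y)
    return lo + y


def gen_sites(
    n: int,
    n_clumps: int,
    clump_sd: float,
    domain: tuple[float, float] = (1000.0, 1000.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Generate ``n`` monitoring sites in spatial clumps on a planar-km domain.

    Clump centres are uniform on the domain; sites are assigned to clumps
    round-robin and scattered around their centre with isotropic Gaussian
    dispersion ``clump_sd`` (km), reflected at the domain edges.

    Returns a site table with columns ``site_id, x, y, clump``.
    """
    if n < n_clumps or n_clumps < 1:
        raise ValueError("need n >= n_clumps >= 1")
    if clump_sd < 0:
        raise ValueError("clump_sd must be non-negative")
    w, h = domain
    if w <= 0 or h <= 0:
        raise ValueError(f"non-positive domain dimensions {domain}")
    rng = np.random.default_rng(seed)
    centers = rng.uniform([0, 0], [w, h], size=(n_clumps, 2))
    clump = np.arange(n) % n_clumps
    xy = centers[clump] + rng.normal(0.0, clump_sd, size=(n, 2))
    xy[:, 0] = _reflect(xy[:, 0], 0.0, w)
    xy[:, 1] = _reflect(xy[:, 1], 0.0, h)
    return pd.DataFrame(
        {
            "site_id": [f"S{i:04d}" for i in range(n)],
            "x": xy[:, 0],
            "y": xy[:, 1],
            "clump": clump,
        }
    )


def gen_covariates(
    sites: pd.DataFrame,
    p: int,
    n_informative: int,
    spatial_smoothness: float = 10.0,
    noise_corr: float = 0.3,
    seed: int = 0,
    beta_scale: float = 0.45,
    cov_params: tuple[float, float, float] = (100.0, 0.3, 0.1),
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a sites x p covariate matrix with a known informative subset.

    Informative columns are smooth spatial surfaces — sums of Gaussian bumps
    of width ``spatial_smoothness`` km, with enough bumps to tile the domain
    at that correlation length — plus a little white noise.  The default
    width (10 km) is far below typical inter-cluster distances on a national
    network, emulating locally driven covariates (traffic, land use): models
    that observe the covariates can predict far from monitors while spatial
    interpolation alone cannot, yet the mean structure is still partially
    confounded with the residual field at short range.  Noise columns are
    equicorrelated white noise with pairwise correlation ``noise_corr`` (one
    shared latent factor).

    True coefficients ``beta`` apply to z-scored covariates; nonzero entries
    are drawn with magnitude ``beta_scale`` +/- 50% and random sign on the
    ``n_informative`` lowest-index columns.

    Returns the covariate table (``site_id`` plus ``V0000``.. columns) and the
    :class:`SyntheticTruth`.  Category labels for the columns are assigned
    round-robin over :data:`CATEGORIES` and returned in the table's ``attrs``
    under ``"categories"``.
    """
    if p == 0:
        raise ValueError("p must be positive")
    if not 0 <= n_informative <= p:
        raise ValueError("need 0 <= n_informative <= p")
    if not 0 <= noise_corr < 1:
        raise ValueError("noise_corr must be in [0, 1)")
    rng = np.random.default_rng(seed)
    xy = sites[["x", "y"]].to_numpy(float)
    n = len(xy)
    w = xy[:, 0].max() - xy[:, 0].min() + 1e-9
    h = xy[:, 1].max() - xy[:, 1].min() + 1e-9

    def bump_surface() -> np.ndarray:
        # enough bumps that the surface behaves like a random field with
        # correlation length ~ spatial_smoothness rather than isolated islands
        lam = max(3.0, w * h / (2 * np.pi * spatial_smoothness**2))
        n_bumps = max(3, int(rng.poisson(lam)))
        centers = rng.uniform(
            [xy[:, 0].min(), xy[:, 1].min()],
            [xy[:, 0].min() + w, xy[:, 1].min() + h],
            size=(n_bumps, 2),
        )
        amps = rng.normal(0.0, 1.0, size=n_bumps)
        d2 = cdist(xy, centers, "sqeuclidean")
        surf = (np.exp(-d2 / (2 * spatial_smoothness**2)) * amps).sum(axis=1)
        sd = surf.std()
        return (surf - surf.mean()) / (sd if sd > 0 else 1.0)

    X = np.empty((n, p))
    info_idx = np.arange(n_informative)
    for j in range(n_informative):
        surf = bump_surface()
        X[:, j] = surf + rng.normal(0.0, 0.1, size=n)

    # noise columns: spatially smooth surfaces unrelated to the response —
    # like real land-use covariates that simply do not drive the pollutant —
    # equicorrelated through one shared surface
    n_noise = p - n_informative
    if n_noise:
        shared = bump_surface()[:, None]
        for j in range(n_informative, p):
            X[:, j] = (
                np.sqrt(noise_corr) * shared[:, 0]
                + np.sqrt(1 - noise_corr) * bump_surface()
            )

    beta = np.zeros(p)
    if n_informative:
        mags = beta_scale * rng.uniform(0.5, 1.5, size=n_informative)
        beta[info_idx] = mags * rng.choice([-1.0, 1.0], size=n_informative)

    cols = [f"V{j:04d}" for j in range(p)]
    table = pd.DataFrame(X, columns=cols)
    table.insert(0, "site_id", sites["site_id"].to_numpy())
    table.attrs["categories"] = {
        c: CATEGORIES[j % len(CATEGORIES)] for j, c in enumerate(cols)
    }
    truth = SyntheticTruth(
        beta=beta, informative_idx=info_idx, cov_params=cov_params, seed=seed
    )
    return table, truth


def exp_cov_matrix(
    xy: np.ndarray, range_km: float, partial_sill: float, nugget: float
) -> np.ndarray:
    """Dense exponential covariance matrix psill*exp(-d/range) + nugget*I."""
    d = cdist(xy, xy)
    return partial_sill * np.exp(-d / range_km) + nugget * np.eye(len(xy))


def gen_field(
    sites: pd.DataFrame,
    cov_params: tuple[float, float, float],
    seed: int = 0,
) -> np.ndarray:
    """Draw a zero-mean Gaussian random field at the site locations.

    Covariance is ``psill * exp(-d / range) + nugget * 1(same site)``, realised
    through a symmetric (Cholesky, eigen fallback) factorisation of the dense
    covariance matrix.
    """
    range_km, psill, nugget = cov_params
    if range_km <= 0 or psill < 0 or nugget < 0:
        raise ValueError(f"invalid covariance parameters {cov_params}")
    xy = sites[["x", "y"]].to_numpy(float)
    if not np.all(np.isfinite(xy)):
        raise ValueError("non-finite coordinates")
    n = len(xy)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    if psill == 0 and nugget == 0:
        return np.zeros(n)
    cov = exp_cov_matrix(xy, range_km, psill, nugget)
    jitter = 1e-10 * (psill + nugget)
    try:
        L = np.linalg.cholesky(cov + jitter * np.eye(n))
    except np.linalg.LinAlgError:
        vals, vecs = np.linalg.eigh(cov)
        if vals.min() < -1e-6 * max(vals.max(), 1.0):
            raise np.linalg.LinAlgError(
                f"covariance matrix not PSD after jitter (min eig {vals.min():.3g})"
            )
        L = vecs * np.sqrt(np.clip(vals, 0.0, None))
    return L @ z


@dataclass
class ConcentrationResult:
    """Annual-average table plus generation bookkeeping."""

    records: pd.DataFrame
    n_clipped: int = 0
    field: np.ndarray = field(default_factory=lambda: np.empty(0))


def gen_concentrations(
    sites: pd.DataFrame,
    covariates: pd.DataFrame,
    truth: SyntheticTruth,
    intercept: float = 6.0,
    year: int = 2000,
    pollutant: str = "synthetic",
    field_seed: int | None = None,
) -> ConcentrationResult:
    """Generate annual-average concentrations on sqrt and native scales.

    ``sqrt_value = intercept + Z beta + field`` where Z is the z-scored
    covariate matrix and the field is drawn from ``truth.cov_params``.
    Negative sqrt-scale draws are clipped at 0 (and counted) so the generator
    is total; the native value is ``sqrt_value**2``.
    """
    if not sites["site_id"].equals(covariates["site_id"]):
        raise ValueError("site/covariate tables out of alignment")
    X = covariates.drop(columns="site_id").to_numpy(float)
    if X.shape[1] != truth.beta.shape[0]:
        raise ValueError("covariate/beta dimension mismatch")
    sd = X.std(axis=0)
    Z = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    seed = truth.seed if field_seed is None else field_seed
    eta = gen_field(sites, truth.cov_params, seed=seed)
    sqrt_val = intercept + Z @ truth.beta + eta
    n_clip = int((sqrt_val < 0).sum())
    sqrt_val = np.clip(sqrt_val, 0.0, None)
    rec = pd.DataFrame(
        {
            "site_id": sites["site_id"].to_numpy(),
            "year": year,
            "pollutant": pollutant,
            "value": sqrt_val**2,
            "sqrt_value": sqrt_val,
        }
    )
    return ConcentrationResult(records=rec, n_clipped=n_clip, field=eta)


def scheduled_days(year: int, schedule: str) -> pd.DatetimeIndex:
    """Calendar days a monitor on the given schedule operates (day 1 start)."""
    if schedule not in SCHEDULES:
        raise ValueError(f"unknown schedule {schedule!r}")
    step = SCHEDULES[schedule]
    days = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    return days[::step]


def gen_hourly_series(
    year: int,
    schedule: str = "1-in-1",
    missing_days: set[int] | None = None,
    missing_hours_per_day: int = 0,
    base: float = 30.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate an hourly concentration series on a sampling schedule.

    ``missing_days`` are 1-based day-of-year indices removed entirely;
    ``missing_hours_per_day`` hours are deleted (at random positions) from each
    remaining scheduled day.  Values are ``base`` plus a smooth diurnal cycle
    and noise.  Returns columns ``timestamp, value``.
    """
    missing_days = missing_days or set()
    days = scheduled_days(year, schedule)
    n_days_in_year = pd.Timestamp(f"{year}-12-31").dayofyear
    if any(d < 1 or d > n_days_in_year for d in missing_days):
        raise ValueError("missing_days outside the year")
    if not 0 <= missing_hours_per_day <= 24:
        raise ValueError("missing_hours_per_day must be in [0, 24]")
    rng = np.random.default_rng(seed)
    frames = []
    hours = np.arange(24)
    diurnal = 0.2 * base * np.sin(2 * np.pi * (hours - 6) / 24)
    for day in days:
        if day.dayofyear in missing_days:
            continue
        keep = np.ones(24, dtype=bool)
        if missing_hours_per_day:
            drop = rng.choice(24, size=missing_hours_per_day, replace=False)
            keep[drop] = False
        vals = base + diurnal + rng.normal(0.0, 0.05 * base, size=24)
        frames.append(
            pd.DataFrame(
                {
                    "timestamp": day + pd.to_timedelta(hours[keep], unit="h"),
                    "value": vals[keep],
                }
            )
        )
    if not frames:
        return pd.DataFrame({"timestamp": pd.DatetimeIndex([]), "value": []})
    return pd.concat(frames, ignore_index=True)
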