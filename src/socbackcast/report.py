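"""Zonal and statistical reporting of backcast results.

Covers Köppen-zone summary tables of absolute and relative SOC change over
the 100- and 50-year windows, density distributions of per-site changes,
driver regressions with exhaustive AIC model selection, and spatial
aggregation of per-site changes onto a regular 0.1° grid.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .zones import ZONE_ORDER, KOPPEN_ZONES

__all__ = [
    "DRIVER_COLUMNS",
    "RegressionResult",
    "sample_fraction",
    "zone_summary",
    "regression_select",
    "raster_aggregate",
    "write_raster_tiff",
    "change_density",
]

log = logging.getLogger(__name__)

# The seven candidate drivers of zonal SOC change.
DRIVER_COLUMNS = [
    "soc_2018", "mat_mean", "map_mean", "water_balance",
    "d_mat", "d_map", "d_water_balance",
]


def sample_fraction(sites: pd.DataFrame, fraction: float = 0.01, seed: int = 0) -> pd.DataFrame:
    """Uniform random subset of sites without replacement, reproducible.

    The subset size is fraction × n rounded half up.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if fraction == 1.0:
        return sites.copy()
    n = int(np.floor(fraction * len(sites) + 0.5))
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(sites), size=n, replace=False)
    return sites.iloc[np.sort(idx)].reset_index(drop=True)


def zone_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Per-zone mean/sd/n of absolute and relative change, per scenario.

    ``results`` is the per-site × scenario table from the backcast; the
    output carries one row per (zone, scenario), ordered by the
    conventional Köppen table order, with sample standard deviations
    (n−1 denominator).  Zones with no contributing sites are omitted.
    """
    stats = ["delta_100", "delta_50", "rel_100", "rel_50"]
    rows = []
    present = set(results["koppen_zone"])
    for zone in ZONE_ORDER:
        if zone not in present:
            log.info("zone %s: no contributing sites, omitted", zone)
            continue
        sub = results[results["koppen_zone"] == zone]
        for scen, grp in sub.groupby("scenario", sort=True):
            row = {"zone": zone, "zone_name": KOPPEN_ZONES[zone],
                   "scenario": scen, "n": len(grp)}
            for s in stats:
                row[f"{s}_mean"] = float(grp[s].mean())
                row[f"{s}_sd"] = float(grp[s].std(ddof=1)) if len(grp) > 1 else 0.0
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class RegressionResult:
    """AIC-selected ordinary least squares fit over candidate driver subsets."""

    predictors: tuple[str, ...]
    coefficients: dict[str, float]
    intercept: float
    r_squared: float
    aic: float
    n_obs: int
    residual_quantiles: dict[str, float]
    dropped_collinear: tuple[str, ...] = ()

    @property
    def signs(self) -> dict[str, int]:
        return {k: int(np.sign(v)) for k, v in self.coefficients.items()}


def _fit_ols(table: pd.DataFrame, response: str, predictors: tuple[str, ...]):
    X = sm.add_constant(table[list(predictors)], has_constant="add")
    return sm.OLS(table[response].to_numpy(), X).fit()


def regression_select(
    table: pd.DataFrame,
    response: str,
    candidates: list[str] | None = None,
) -> RegressionResult:
    """Exhaustive AIC search over all non-empty predictor subsets.

    ``table`` holds one observation per zone (or per site, if desired) with
    the seven candidate drivers; the AIC-minimal OLS fit is returned with
    residual quantile diagnostics attached.  Collinear predictors are
    dropped up front with a warning.
    """
    candidates = list(candidates if candidates is not None else DRIVER_COLUMNS)
    missing = [c for c in candidates + [response] if c not in table.columns]
    if missing:
        raise ValueError(f"table missing columns {missing}")
    data = table[candidates + [response]].dropna()
    if len(data) < len(candidates) + 1:
        raise ValueError(
            f"only {len(data)} complete observations for {len(candidates)} candidates"
        )
    dropped: list[str] = []
    X = data[candidates].to_numpy()
    # rank-deficiency guard: greedily drop predictors that add no rank
    keep: list[str] = []
    for j, name in enumerate(candidates):
        trial = data[keep + [name]].to_numpy()
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(data)), trial])) <= len(keep) + 1:
            dropped.append(name)
            log.warning("dropping collinear predictor %s", name)
        else:
            keep.append(name)
    best = None
    best_subset: tuple[str, ...] = ()
    for r in range(1, len(keep) + 1):
        for subset in itertools.combinations(keep, r):
            fit = _fit_ols(data, response, subset)
            if best is None or fit.aic < best.aic:
                best, best_subset = fit, subset
    resid = np.sort(best.resid)
    q = np.quantile(resid, [0.05, 0.25, 0.5, 0.75, 0.95])
    params = best.params
    return RegressionResult(
        predictors=best_subset,
        coefficients={name: float(params[name]) for name in best_subset},
        intercept=float(params["const"]),
        r_squared=float(best.rsquared),
        aic=float(best.aic),
        n_obs=int(best.nobs),
        residual_quantiles={f"q{int(p * 100):02d}": float(v)
                            for p, v in zip([0.05, 0.25, 0.5, 0.75, 0.95], q)},
        dropped_collinear=tuple(dropped),
    )


def raster_aggregate(
    results: pd.DataFrame,
    value: str = "delta_100",
    cell_size: float = 0.1,
) -> pd.DataFrame:
    """Mean of ``value`` per regular lon/lat cell.

    Cells are half-open intervals [x, x + cell) registered to multiples of
    the cell size; returns one row per non-empty cell with the cell's
    lower-left corner.  Coordinates outside the WGS84 domain are an error.
    """
    lon = results["lon"].to_numpy(dtype=float)
    lat = results["lat"].to_numpy(dtype=float)
    if np.any((lon < -180) | (lon > 180) | (lat < -90) | (lat > 90)):
        raise ValueError("coordinates outside [-180, 180] × [-90, 90]")
    ix = np.floor(lon / cell_size + 1e-9).astype(int)
    iy = np.floor(lat / cell_size + 1e-9).astype(int)
    df = pd.DataFrame({"ix": ix, "iy": iy, "v": results[value].to_numpy(dtype=float)})
    agg = df.groupby(["ix", "iy"], as_index=False).agg(mean=("v", "mean"), n=("v", "size"))
    agg["lon"] = agg.pop("ix") * cell_size
    agg["lat"] = agg.pop("iy") * cell_size
    return agg[["lon", "lat", "mean", "n"]].sort_values(["lat", "lon"]).reset_index(drop=True)


def write_raster_tiff(grid: pd.DataFrame, path, cell_size: float = 0.1, nodata: float = np.nan):
    """Write the aggregated grid as a single-band float TIFF.

    A plain (non-georeferenced) raster covering the bounding box of the
    occupied cells, row 0 at the northern edge; the companion CSV carries
    the coordinates.
    """
    import tifffile

    ix = np.round(grid["lon"].to_numpy() / cell_size).astype(int)
    iy = np.round(grid["lat"].to_numpy() / cell_size).astype(int)
    nx = ix.max() - ix.min() + 1
    ny = iy.max() - iy.min() + 1
    band = np.full((ny, nx), nodata, dtype=np.float32)
    band[iy.max() - iy, ix - ix.min()] = grid["mean"].to_numpy(dtype=np.float32)
    tifffile.imwrite(path, band)
    return path


def change_density(
    deltas: np.ndarray,
    edges: np.ndarray | None = None,
) -> pd.DataFrame:
    """Fraction of sites per change bin; bins are half-open (lo, hi].

    Default bins span −30 to +30 Mg C ha⁻¹ in 3-unit steps, with loss bins
    negative-signed; values outside the covering range fall into open-ended
    end bins.
    """
    deltas = np.asarray(deltas, dtype=float)
    if edges is None:
        edges = np.arange(-30.0, 30.1, 3.0)
    edges = np.asarray(edges, dtype=float)
    full = np.concatenate([[-np.inf], edges, [np.inf]])
    rows = []
    n = max(len(deltas), 1)
    for lo, hi in zip(full[:-1], full[1:]):
        count = int(np.sum((deltas > lo) & (deltas <= hi)))
        rows.append({"lo": lo, "hi": hi, "count": count, "fraction": count / n})
    return pd.DataFrame(rows)
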