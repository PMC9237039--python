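"""Site-level climate predictors.

Growing-season (May-September) means, normalized (z-scored) anomalies,
chilling-day counts (daily mean in [0, 5] degC) and forcing degree-days
(above 5 degC) accumulated from November 1 of the previous year to the
site's long-term mean season start, and bilinear interpolation of gridded
climate to site coordinates.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .errors import ConfigError, OutOfDomainError
from .series import DAYS_PER_YEAR, GROWING_SEASON, NOV1_DOY, DailySeries
from .synthetic import ClimateGrid


@dataclass
class SeasonStat:
    site_id: str
    year: int
    variable: str
    value: float  # NaN when coverage is insufficient
    flag: str = ""


@dataclass
class ChillForce:
    site_id: str
    year: int
    chilling_days: float
    forcing_gdd: float
    window_start: tuple  # (year, doy)
    window_end: tuple


def growing_season_mean(series: DailySeries, year: int,
                        doy_window: tuple = GROWING_SEASON,
                        min_coverage: float = 0.8) -> SeasonStat:
    """Arithmetic mean of daily values over the half-open DOY window."""
    lo, hi = doy_window
    sub = series.for_year(year)
    mask = (sub.doy >= lo) & (sub.doy < hi) & np.isfinite(sub.value)
    n_expected = hi - lo
    if mask.sum() < min_coverage * n_expected:
        return SeasonStat(series.site_id, int(year), series.variable,
                          np.nan, flag="insufficient_coverage")
    return SeasonStat(series.site_id, int(year), series.variable,
                      float(sub.value[mask].mean()))


def normalize_anomalies(values_by_year: pd.Series) -> pd.Series:
    """z-score a site's yearly values: (v - mean) / sample SD.

    Requires >= 3 non-missing years and positive spread; a constant record
    raises (the site is excluded with a flag by the caller).
    """
    vals = values_by_year.dropna()
    if len(vals) < 3:
        raise ConfigError("need >= 3 non-missing years to normalize")
    sd = vals.std(ddof=1)
    if not sd > 0:
        raise ConfigError("zero variance: site excluded from anomalies")
    return (values_by_year - vals.mean()) / sd


def _window_values(temp: DailySeries, start: tuple, end: tuple) -> np.ndarray:
    """Daily values over the half-open calendar window [start, end),
    each endpoint a (year, doy) pair on the 365-day calendar."""
    sy, sd = start
    ey, ed = end
    abs_day = temp.year * DAYS_PER_YEAR + temp.doy
    lo = sy * DAYS_PER_YEAR + sd
    hi = ey * DAYS_PER_YEAR + ed
    if lo >= hi:
        raise ConfigError("window start must precede window end")
    return temp.value[(abs_day >= lo) & (abs_day < hi)], hi - lo


def chilling_units(temp: DailySeries, window: tuple,
                   bounds: tuple = (0.0, 5.0),
                   min_coverage: float = 0.9) -> float:
    """Count of days with daily mean temperature in [0, 5] degC (inclusive)."""
    values, n_expected = _window_values(temp, *window)
    values = values[np.isfinite(values)]
    if values.size < min_coverage * n_expected:
        return np.nan
    lo, hi = bounds
    return float(np.count_nonzero((values >= lo) & (values <= hi)))


def forcing_units(temp: DailySeries, window: tuple, base: float = 5.0,
                  min_coverage: float = 0.9) -> float:
    """Growing degree-days: sum of max(T - base, 0); strictly-above-base
    days contribute."""
    values, n_expected = _window_values(temp, *window)
    values = values[np.isfinite(values)]
    if values.size < min_coverage * n_expected:
        return np.nan
    return float(np.maximum(values - base, 0.0).sum())


def dormancy_window(year: int, mean_sos: float) -> tuple:
    """The chilling/forcing accumulation window: November 1 of the previous
    year up to the site's mean season start (rounded to the nearest day)."""
    return ((year - 1, NOV1_DOY), (year, int(np.floor(mean_sos + 0.5))))


def bilinear_at(grid: ClimateGrid, lat: float, lon: float, time) -> float:
    """Bilinear interpolation of the grid at one site and time slice."""
    t_idx = np.flatnonzero(grid.times == time)
    if t_idx.size != 1:
        raise ConfigError(f"time slice {time!r} not in grid")
    interp = RegularGridInterpolator(
        (grid.lats, grid.lons), grid.values[t_idx[0]],
        method="linear", bounds_error=True)
    try:
        return float(interp((lat, lon)))
    except ValueError as exc:
        raise OutOfDomainError(
            f"point ({lat}, {lon}) outside grid hull") from exc


def build_anomaly_pairs(phenology: pd.DataFrame, predictors: pd.DataFrame,
                        predictor_name: str) -> pd.DataFrame:
    """Match normalized SOS anomalies of year *y* with normalized anomalies
    of a previous-season predictor (year *y - 1*), per site.

    ``phenology`` needs columns (site_id, year, sos); ``predictors``
    (site_id, year, value).  Sites failing the >= 3-year / nonzero-spread
    normalization rule are dropped with a flag column in the output attrs.
    """
    rows = []
    dropped = []
    pred = predictors.set_index(["site_id", "year"])["value"]
    for site, grp in phenology.groupby("site_id"):
        sos = grp.set_index("year")["sos"].sort_index()
        pred_site = pred.loc[site] if site in pred.index.get_level_values(0) else None
        if pred_site is None:
            dropped.append((site, "no_predictor"))
            continue
        prev = pred_site.reindex(sos.index - 1)
        prev.index = sos.index
        paired = pd.DataFrame({"sos": sos, "prev": prev}).dropna()
        if len(paired) < 3:
            dropped.append((site, "too_few_years"))
            continue
        try:
            sos_anom = normalize_anomalies(paired["sos"])
            prev_anom = normalize_anomalies(paired["prev"])
        except ConfigError:
            dropped.append((site, "zero_variance"))
            continue
        for year in paired.index:
            rows.append({
                "site_id": site, "year": int(year),
                "sos_anom": sos_anom.loc[year],
                "predictor_anom": prev_anom.loc[year],
                "predictor_name": predictor_name,
                "sd_sos": paired["sos"].std(ddof=1),
                "sd_predictor": paired["prev"].std(ddof=1),
            })
    out = pd.DataFrame(rows)
    out.attrs["dropped_sites"] = dropped
    return out
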