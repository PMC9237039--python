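"""Site-level daily (or composited) time series.

All calendar handling uses a fixed 365-day year (DOY 1-365); leap days are
dropped on ingest.  Month boundaries on this calendar: May 1 = DOY 121,
Oct 1 = DOY 274, Nov 1 = DOY 305.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365
#: half-open growing-season window [May 1, Oct 1)
GROWING_SEASON = (121, 274)
NOV1_DOY = 305

_MONTH_START_DOY = np.array(
    [1, 32, 60, 91, 121, 152, 182, 213, 244, 274, 305, 335]
)


@dataclass
class DailySeries:
    """One site's time series of a single variable over multiple years.

    ``year`` and ``doy`` are parallel integer arrays; ``value`` holds the
    observations (NaN for missing days).  ``meta`` carries generator-side
    bookkeeping such as the implied curve maximum of a synthetic GPP year.
    """

    site_id: str
    variable: str
    year: np.ndarray
    doy: np.ndarray
    value: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.year = np.asarray(self.year, dtype=int)
        self.doy = np.asarray(self.doy, dtype=int)
        self.value = np.asarray(self.value, dtype=float)
        if not (self.year.shape == self.doy.shape == self.value.shape):
            raise ValueError("year, doy and value must have equal length")
        if self.doy.size and (self.doy.min() < 1 or self.doy.max() > DAYS_PER_YEAR):
            raise ValueError("doy must lie in [1, 365]")

    def __len__(self) -> int:
        return self.value.size

    @property
    def years(self) -> np.ndarray:
        return np.unique(self.year)

    def for_year(self, year: int) -> "DailySeries":
        mask = self.year == year
        return DailySeries(
            self.site_id, self.variable,
            self.year[mask], self.doy[mask], self.value[mask], dict(self.meta),
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy layout (site_id, date, variable, value) with ISO-8601 dates."""
        dates = doy_to_date(self.year, self.doy)
        return pd.DataFrame(
            {
                "site_id": self.site_id,
                "date": dates,
                "variable": self.variable,
                "value": self.value,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, site_id: str, variable: str) -> "DailySeries":
        """Build from the tidy CSV layout, dropping leap days."""
        sub = frame[(frame["site_id"] == site_id) & (frame["variable"] == variable)]
        dates = pd.to_datetime(sub["date"])
        keep = ~((dates.dt.month == 2) & (dates.dt.day == 29))
        dates = dates[keep]
        year = dates.dt.year.to_numpy()
        doy = date_to_doy(dates)
        order = np.lexsort((doy, year))
        return cls(site_id, variable, year[order], doy[order],
                   sub.loc[keep, "value"].to_numpy()[order])


def date_to_doy(dates: pd.Series) -> np.ndarray:
    """Map calendar dates onto the fixed 365-day DOY axis (leap-day-free)."""
    month = dates.dt.month.to_numpy()
    day = dates.dt.day.to_numpy()
    return _MONTH_START_DOY[month - 1] + day - 1


def doy_to_date(year: np.ndarray, doy: np.ndarray) -> np.ndarray:
    month = np.searchsorted(_MONTH_START_DOY, doy, side="right")
    day = doy - _MONTH_START_DOY[month - 1] + 1
    return np.array(
        [f"{y:04d}-{m:02d}-{d:02d}" for y, m, d in zip(year, month, day)]
    )


def concat_series(series_list: list["DailySeries"]) -> "DailySeries":
    """Concatenate per-year series of one site/variable into one record."""
    first = series_list[0]
    return DailySeries(
        first.site_id, first.variable,
        np.concatenate([s.year for s in series_list]),
        np.concatenate([s.doy for s in series_list]),
        np.concatenate([s.value for s in series_list]),
    )


def full_year_axis(start_year: int, n_years: int) -> tuple[np.ndarray, np.ndarray]:
    """(year, doy) arrays covering ``n_years`` complete 365-day years."""
    years = np.repeat(np.arange(start_year, start_year + n_years), DAYS_PER_YEAR)
    doys = np.tile(np.arange(1, DAYS_PER_YEAR + 1), n_years)
    return years, doys
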