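"""Record-screening rules applied before the statistical analyses.

Three screens are implemented: a robust outlier fence at ``k`` median
absolute deviations (MAD, unscaled — no normal-consistency constant),
a bare-land mask dropping records whose long-term mean NDVI falls below
0.1, and minimum-record-length filters (years of valid season starts, and
optionally a minimum number of daily observations per retained year).

Boundary conventions: values exactly at the MAD fence and NDVI exactly at
0.1 are retained.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyInputError
from .series import DailySeries


@dataclass
class FilterReport:
    """Audit trail of a screening pass; counts always reconcile."""

    n_input: int = 0
    n_removed_outlier: int = 0
    n_removed_mask: int = 0
    n_removed_short_record: int = 0
    detail: list = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return (self.n_input - self.n_removed_outlier - self.n_removed_mask
                - self.n_removed_short_record)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.detail)

    def summary(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_removed_outlier": self.n_removed_outlier,
            "n_removed_mask": self.n_removed_mask,
            "n_removed_short_record": self.n_removed_short_record,
            "n_retained": self.n_retained,
        }


def mad_outlier_filter(values, k: float = 2.5) -> np.ndarray:
    """Keep-mask fencing values beyond ``k`` median absolute deviations.

    A value ``v`` is kept iff ``|v - median| <= k * MAD`` with
    ``MAD = median(|v - median|)``.  When the MAD is zero only values equal
    to the median survive.
    """
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    if finite.sum() == 0:
        raise EmptyInputError("no finite values to filter")
    if finite.sum() < 3:
        raise EmptyInputError("need at least 3 finite values for a MAD fence")
    med = np.median(values[finite])
    mad = np.median(np.abs(values[finite] - med))
    if mad == 0:
        keep = values == med
    else:
        keep = np.abs(values - med) <= k * mad
    return keep & finite


def ndvi_bareland_mask(series: DailySeries, threshold: float = 0.1) -> bool:
    """Retain a site/pixel iff its mean annual-mean NDVI is >= ``threshold``."""
    if len(series) == 0:
        raise EmptyInputError("empty NDVI series")
    annual_means = pd.Series(series.value).groupby(series.year).mean()
    return bool(annual_means.mean() >= threshold)


def record_length_filter(records: pd.DataFrame, min_years: int,
                         min_daily_records_per_year: int | None = None,
                         daily_counts: pd.DataFrame | None = None,
                         group_cols: tuple = ("site_id",),
                         ) -> tuple[pd.DataFrame, FilterReport]:
    """Keep site(-species) series with enough valid years.

    ``records`` is a phenology table with columns ``site_id``, ``year``,
    ``sos`` (NaN marks an invalid year) and optionally the grouping columns.
    When ``min_daily_records_per_year`` is given, ``daily_counts`` must map
    (site_id, year) -> ``n_daily``; years at or below the threshold are
    dropped before the year count is taken (strictly-greater rule).
    """
    if min_years < 2:
        raise ValueError("min_years must be >= 2")
    report = FilterReport(n_input=len(records))
    work = records.copy()
    valid = work["sos"].notna()
    if min_daily_records_per_year is not None:
        if daily_counts is None:
            raise ValueError("daily_counts required with a per-year threshold")
        counts = daily_counts.set_index(["site_id", "year"])["n_daily"]
        idx = pd.MultiIndex.from_frame(work[["site_id", "year"]])
        n_daily = counts.reindex(idx).to_numpy()
        valid &= n_daily > min_daily_records_per_year
    work = work[valid]
    keep_frames = []
    for key, grp in work.groupby(list(group_cols)):
        n = grp["year"].nunique()
        if n >= min_years:
            keep_frames.append(grp)
            report.detail.append({"group": key, "n_years": n, "kept": True})
        else:
            report.detail.append({"group": key, "n_years": n, "kept": False})
    retained = (pd.concat(keep_frames, ignore_index=True) if keep_frames
                else records.iloc[0:0].copy())
    report.n_removed_short_record = report.n_input - len(retained)
    return retained, report
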