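"""Season start/end and carbon-uptake metrics from three curve families.

* Camera greenness: the green chromatic coordinate Gcc = G/(R+G+B) is
  composited to its 90th percentile in short windows; the season start is
  the first spring day the composited curve reaches half of its seasonal
  amplitude (baseline and peak taken as the 10th/90th percentiles of the
  year's curve).
* Satellite NDVI: Savitzky-Golay smoothing, a double-logistic fit, and the
  first/second local maxima of the fitted curve's second derivative as
  season start/end.
* Flux-tower GPP: singular-spectrum-analysis smoothing, a spring threshold
  at 15% of the multi-year daily maximum (with a 5-day persistence rule),
  the annual maximum of the smoothed curve (GPPmax), and the May-September
  mean.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import savgol_filter

from .curves import INFLECTION_OFFSET, double_logistic, double_logistic_d2
from .errors import ConfigError, EmptyInputError, GapError, NoSeasonalityError
from .series import DAYS_PER_YEAR, GROWING_SEASON, DailySeries


@dataclass
class ImageColorMeans:
    r_dn: float
    g_dn: float
    b_dn: float

    def __post_init__(self):
        if min(self.r_dn, self.g_dn, self.b_dn) < 0:
            raise ValueError("digital numbers must be non-negative")


@dataclass
class DoubleLogisticParams:
    """Fitted seasonal-curve parameters for one site-year.

    ``a`` amplitude, ``b`` winter background (so the summer plateau is
    about ``a + b``), ``k``/``m`` spring rate and inflection day,
    ``r_autumn``/``n`` autumn rate and inflection day.
    """

    a: float
    b: float
    k: float
    m: float
    r_autumn: float
    n: float

    def __post_init__(self):
        if self.a <= 0 or self.k <= 0 or self.r_autumn <= 0:
            raise ValueError("a, k and r_autumn must be positive")
        if not self.m < self.n:
            raise ValueError("spring inflection must precede autumn inflection")

    def curve(self, t):
        return double_logistic(t, self.a, self.b, self.k, self.m,
                               self.r_autumn, self.n)

    def second_derivative(self, t):
        return double_logistic_d2(t, self.a, self.b, self.k, self.m,
                                  self.r_autumn, self.n)


@dataclass
class FitDiagnostics:
    converged: bool
    rss: float
    n_obs: int
    n_restarts: int


@dataclass
class CarbonMetrics:
    site_id: str
    year: int
    gpp_max: float
    gpp_mean_gs: float


def gcc(c: ImageColorMeans) -> float:
    """Green chromatic coordinate G/(R+G+B) of mean camera digital numbers."""
    total = c.r_dn + c.g_dn + c.b_dn
    if total <= 0:
        raise ZeroDivisionError("all-zero digital numbers: Gcc undefined")
    return c.g_dn / total


def gcc_composite_90(series: DailySeries, window_days: int = 3,
                     quantile: float = 0.90) -> DailySeries:
    """Composite daily Gcc to its 90th percentile in non-overlapping windows
    (the Gcc_90 product), labelled at window centers."""
    out_year, out_doy, out_val = [], [], []
    for year in series.years:
        sub = series.for_year(year)
        order = np.argsort(sub.doy)
        doy, val = sub.doy[order], sub.value[order]
        for start in range(1, DAYS_PER_YEAR + 1, window_days):
            mask = (doy >= start) & (doy < start + window_days)
            if mask.any():
                out_year.append(year)
                out_doy.append(min(start + window_days // 2, DAYS_PER_YEAR))
                out_val.append(np.nanquantile(val[mask], quantile))
    return DailySeries(series.site_id, series.variable + "_90",
                       np.array(out_year), np.array(out_doy),
                       np.array(out_val))


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def gcc_sos(series: DailySeries, year: int, baseline_pct: float = 10.0,
            peak_pct: float = 90.0, min_amplitude: float = 1e-4) -> int:
    """Season start as the half-amplitude upcrossing of the greenness curve.

    Baseline and peak are the ``baseline_pct``/``peak_pct`` percentiles of
    the year's (already composited/smoothed) curve; the crossing day is
    linearly interpolated between the bracketing observations and rounded
    to the nearest day.
    """
    sub = series.for_year(year)
    if len(sub) == 0:
        raise EmptyInputError(f"no observations for year {year}")
    order = np.argsort(sub.doy)
    doy = sub.doy[order].astype(float)
    val = sub.value[order]
    ok = np.isfinite(val)
    doy, val = doy[ok], val[ok]
    baseline = np.percentile(val, baseline_pct)
    peak = np.percentile(val, peak_pct)
    if peak - baseline < min_amplitude:
        raise NoSeasonalityError(
            f"{series.site_id}/{year}: seasonal amplitude below tolerance")
    threshold = baseline + 0.5 * (peak - baseline)
    # spring segment: up to the curve's maximum
    i_peak = int(np.argmax(val))
    above = val[: i_peak + 1] >= threshold
    if not above.any():
        raise NoSeasonalityError(
            f"{series.site_id}/{year}: curve never reaches half amplitude")
    i = int(np.argmax(above))
    if i == 0:
        return _round_half_up(doy[0])
    t0, t1 = doy[i - 1], doy[i]
    v0, v1 = val[i - 1], val[i]
    t_cross = t0 + (threshold - v0) / (v1 - v0) * (t1 - t0)
    return _round_half_up(t_cross)


def savitzky_golay(series: DailySeries, window: int = 7,
                   polyorder: int = 2) -> DailySeries:
    """Savitzky-Golay least-squares local-polynomial smoothing.

    Output length equals input length; endpoints are handled by evaluating
    the polynomial fitted to the truncated edge window.
    """
    if window % 2 == 0 or window <= polyorder:
        raise ConfigError("window must be odd and exceed polyorder")
    if len(series) < window:
        raise ConfigError("series shorter than the smoothing window")
    smoothed = savgol_filter(series.value, window, polyorder, mode="interp")
    return DailySeries(series.site_id, series.variable, series.year,
                       series.doy, smoothed, dict(series.meta))


# --- double-logistic fitting -------------------------------------------------

def _initial_params(t, y):
    b0 = np.percentile(y, 5)
    a0 = max(np.percentile(y, 95) - b0, 1e-6)
    half = b0 + 0.5 * a0
    above = y >= half
    if above.any():
        m0 = float(t[np.argmax(above)])
        n0 = float(t[len(t) - 1 - np.argmax(above[::-1])])
    else:
        m0, n0 = 120.0, 280.0
    if n0 - m0 < 10:
        m0, n0 = max(m0 - 10, 1.0), min(n0 + 10, 365.0)
    return np.array([a0, b0, 0.1, m0, 0.1, n0])


def fit_double_logistic(series: DailySeries, year: int,
                        max_restarts: int = 5, seed: int = 0,
                        ) -> tuple[DoubleLogisticParams | None, FitDiagnostics]:
    """Nonlinear least-squares fit of the double-logistic seasonal model.

    Up to ``max_restarts`` jittered restarts on non-convergence; a fit
    failure is reported in the diagnostics (the site-year is then excluded
    downstream), not raised.
    """
    sub = series.for_year(year)
    ok = np.isfinite(sub.value)
    t = sub.doy[ok].astype(float)
    y = sub.value[ok]
    if t.size < 8:
        raise ConfigError(f"{series.site_id}/{year}: need >= 8 observations")

    lo = np.array([1e-8, -np.inf, 1e-4, 1.0, 1e-4, 1.0])
    hi = np.array([np.inf, np.inf, 5.0, 365.0, 5.0, 365.0])

    def residual(p):
        return double_logistic(t, *p) - y

    rng = np.random.default_rng(seed)
    x0 = _initial_params(t, y)
    best, best_rss, n_used = None, np.inf, 0
    for attempt in range(max_restarts + 1):
        start = x0 if attempt == 0 else x0 * rng.uniform(0.7, 1.3, size=6)
        start = np.clip(start, lo + 1e-9, hi - 1e-9)
        try:
            res = least_squares(residual, start, bounds=(lo, hi),
                                method="trf", max_nfev=2000)
        except Exception:
            continue
        rss = float(2 * res.cost)
        if res.success and res.x[3] < res.x[5] and rss < best_rss:
            best, best_rss, n_used = res.x, rss, attempt
            # accept immediately when the fit explains nearly everything
            tss = float(np.sum((y - y.mean()) ** 2))
            if tss > 0 and rss / tss < 1e-4:
                break
    if best is None:
        return None, FitDiagnostics(False, np.inf, t.size, max_restarts)
    params = DoubleLogisticParams(a=float(best[0]), b=float(best[1]),
                                  k=float(best[2]), m=float(best[3]),
                                  r_autumn=float(best[4]), n=float(best[5]))
    return params, FitDiagnostics(True, best_rss, t.size, n_used)


def extract_sos_eos_from_fit(params: DoubleLogisticParams,
                             grid_step: float = 0.1) -> tuple[int, int]:
    """Season start/end from the curvature of the fitted curve.

    The second derivative is evaluated on a ``grid_step``-day grid over the
    year; the season start is its first local maximum, the season end the
    second (for the double logistic these sit at
    ``m - ln(2+sqrt(3))/k`` and ``n + ln(2+sqrt(3))/r``).
    """
    t = np.arange(1.0, DAYS_PER_YEAR + grid_step, grid_step)
    d2 = params.second_derivative(t)
    interior = (d2[1:-1] > d2[:-2]) & (d2[1:-1] >= d2[2:])
    idx = np.flatnonzero(interior) + 1
    # keep only prominent maxima (positive curvature peaks)
    idx = idx[d2[idx] > 1e-12 * max(params.a, 1.0)]
    if idx.size < 2:
        raise NoSeasonalityError("fewer than two curvature maxima found")
    return _round_half_up(t[idx[0]]), _round_half_up(t[idx[1]])


def analytic_sos_offset(k: float) -> float:
    """Closed-form lead of the curvature maximum ahead of a logistic
    inflection: ln(2 + sqrt(3)) / k days."""
    return INFLECTION_OFFSET / k


# --- singular spectrum analysis ---------------------------------------------

def _fill_short_gaps(values: np.ndarray, max_gap: int = 30) -> np.ndarray:
    """Linearly interpolate NaN runs of at most ``max_gap`` days."""
    v = values.copy()
    isnan = ~np.isfinite(v)
    if not isnan.any():
        return v
    # locate NaN runs
    idx = np.flatnonzero(isnan)
    splits = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, splits + 1)
    longest = max(len(r) for r in runs)
    if longest > max_gap:
        raise GapError(f"gap of {longest} consecutive missing days (> {max_gap})")
    good = np.flatnonzero(~isnan)
    v[isnan] = np.interp(np.flatnonzero(isnan), good, v[good])
    return v


def ssa_smooth(series: DailySeries, window_length: int = 60,
               n_components: int = 4) -> DailySeries:
    """Singular-spectrum-analysis smoothing.

    Embeds the series in an L x K trajectory matrix (L = ``window_length``),
    reconstructs from the leading ``n_components`` singular triplets by
    diagonal averaging.  Gaps longer than 30 days raise; shorter gaps are
    linearly interpolated first.
    """
    n = len(series)
    if not 2 <= window_length < n / 2:
        raise ConfigError("window_length must satisfy 2 <= L < N/2")
    if not 1 <= n_components <= window_length:
        raise ConfigError("n_components must lie in [1, window_length]")
    values = _fill_short_gaps(series.value)
    L = window_length
    K = n - L + 1
    idx = np.arange(L)[:, None] + np.arange(K)[None, :]
    X = values[idx]
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    Xr = (U[:, :n_components] * s[:n_components]) @ Vt[:n_components]
    # diagonal (anti-diagonal) averaging back to a series
    recon = np.zeros(n)
    counts = np.zeros(n)
    anti = np.arange(L)[:, None] + np.arange(K)[None, :]  # index i+j
    np.add.at(recon, anti.ravel(), Xr.ravel())
    np.add.at(counts, anti.ravel(), 1.0)
    return DailySeries(series.site_id, series.variable, series.year,
                       series.doy, recon / counts, dict(series.meta))


def gpp_sos(smoothed_gpp: DailySeries, year: int, multi_year_max: float,
            threshold_frac: float = 0.15, persistence_days: int = 5,
            ) -> int | None:
    """Season start from smoothed GPP: the first day in the year's first
    half on which GPP exceeds ``threshold_frac`` of the multi-year daily
    maximum and stays above it for ``persistence_days`` consecutive days.
    Returns None (no-season flag) when the threshold is never sustained."""
    if multi_year_max <= 0:
        raise ConfigError("multi_year_max must be positive")
    sub = smoothed_gpp.for_year(year)
    order = np.argsort(sub.doy)
    doy, val = sub.doy[order], sub.value[order]
    threshold = threshold_frac * multi_year_max
    above = val > threshold
    half = doy <= DAYS_PER_YEAR // 2
    run = np.ones_like(above)
    for off in range(persistence_days):
        shifted = np.roll(above, -off)
        shifted[len(above) - off:] = False
        run &= shifted
    candidates = np.flatnonzero(run & half)
    if candidates.size == 0:
        return None
    return int(doy[candidates[0]])


def carbon_metrics(smoothed_gpp: DailySeries, year: int,
                   min_coverage: float = 0.9) -> CarbonMetrics:
    """Annual maximum and May-September mean of the smoothed daily GPP."""
    sub = smoothed_gpp.for_year(year)
    ok = np.isfinite(sub.value)
    if not ok.any():
        raise EmptyInputError(f"no GPP data in year {year}")
    lo, hi = GROWING_SEASON
    gs = (sub.doy >= lo) & (sub.doy < hi) & ok
    if gs.sum() < min_coverage * (hi - lo):
        raise EmptyInputError(
            f"{smoothed_gpp.site_id}/{year}: insufficient May-September coverage")
    return CarbonMetrics(smoothed_gpp.site_id, int(year),
                         gpp_max=float(np.max(sub.value[ok])),
                         gpp_mean_gs=float(np.mean(sub.value[gs])))


def extract_ndvi_phenology(series: DailySeries, year: int,
                           sg_window: int = 7, sg_polyorder: int = 2,
                           seed: int = 0) -> dict:
    """Full NDVI chain for one site-year: smooth, fit, curvature extraction.

    Returns a row dict with sos/eos (NaN on failure) and a quality flag.
    """
    sub = series.for_year(year)
    flags = []
    try:
        if len(sub) >= sg_window:
            sub = savitzky_golay(sub, sg_window, sg_polyorder)
        else:
            flags.append("unsmoothed")
        params, diag = fit_double_logistic(sub, year, seed=seed)
        if params is None:
            return {"site_id": series.site_id, "year": int(year),
                    "source": "ndvi", "sos": np.nan, "eos": np.nan,
                    "flags": "fit_failure"}
        sos, eos = extract_sos_eos_from_fit(params)
    except (ConfigError, NoSeasonalityError) as exc:
        flags.append(type(exc).__name__)
        return {"site_id": series.site_id, "year": int(year), "source": "ndvi",
                "sos": np.nan, "eos": np.nan, "flags": ";".join(flags)}
    return {"site_id": series.site_id, "year": int(year), "source": "ndvi",
            "sos": sos, "eos": eos, "flags": ";".join(flags)}
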