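"""Synthetic multi-site climate, greenness and productivity generator.

Every downstream stage of the pipeline is exercised against data from this
module because the generating truth — true season start/end dates, the
imposed previous-season temperature effect, and the causal path coefficients
of the climate -> GPPmax -> SOS graph — is recorded alongside the data.

Generated structure:

* daily temperature = seasonal cosine + linear warming trend + white noise;
* per-year truth: SOS of year *y* responds linearly (slope ``true_st``,
  days/degC) to the previous year's May-September mean temperature anomaly;
* seasonal NDVI / camera-greenness / GPP curves are double logistics with
  the spring inflection at the true SOS and the autumn inflection at the
  true EOS, plus additive Gaussian observation noise;
* the flux-site panel draws standardized, mutually independent climate
  drivers and builds GPPmax and SOS from linear structural equations, so
  the generating coefficients are exactly the standardized path
  coefficients a structural model should recover.

All operations are deterministic for a fixed seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curves import double_logistic, plateau_value
from .errors import ConfigError
from .series import DAYS_PER_YEAR, GROWING_SEASON, DailySeries, full_year_axis

#: climate drivers of the flux-panel causal graph
CLIMATE_VARS = ("temperature", "radiation", "precipitation", "swc", "co2")
DEFAULT_SEASON_LENGTH = 160

#: default observation-noise scales per curve kind (fixture choices)
CURVE_DEFAULTS = {
    "ndvi": dict(background=0.2, amplitude=0.5, rate=0.1, obs_noise_sd=0.02,
                 cadence_days=15),
    "gcc": dict(background=0.33, amplitude=0.12, rate=0.1, obs_noise_sd=0.005,
                cadence_days=1),
    "gpp": dict(background=0.5, amplitude=10.0, rate=0.1, obs_noise_sd=0.5,
                cadence_days=1),
}


@dataclass
class SiteConfig:
    site_id: str
    lat: float
    lon: float
    n_years: int
    start_year: int
    species_or_pft: str = "generic"

    def __post_init__(self):
        if self.n_years < 2:
            raise ConfigError(f"{self.site_id}: n_years must be >= 2")
        if not (-90 <= self.lat <= 90) or not (-180 <= self.lon <= 180):
            raise ConfigError(f"{self.site_id}: coordinates out of range")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.start_year + self.n_years)


@dataclass
class TruthRecord:
    """Ground truth for one site-year."""

    site_id: str
    year: int
    true_sos: float
    true_eos: float
    true_st: float
    true_paths: dict = field(default_factory=dict)
    has_prev_season: bool = True

    def __post_init__(self):
        if not (1 <= self.true_sos < self.true_eos <= 366):
            raise ConfigError(
                f"{self.site_id}/{self.year}: need 1 <= sos < eos <= 366"
            )


@dataclass
class ClimateGrid:
    """Regular lat-lon-time grid of one climate variable."""

    lats: np.ndarray
    lons: np.ndarray
    times: np.ndarray
    values: np.ndarray  # (time, lat, lon)

    def __post_init__(self):
        self.lats = np.asarray(self.lats, float)
        self.lons = np.asarray(self.lons, float)
        self.times = np.asarray(self.times)
        self.values = np.asarray(self.values, float)
        for name, ax in (("lats", self.lats), ("lons", self.lons)):
            if ax.size < 2 or np.any(np.diff(ax) <= 0):
                raise ConfigError(f"{name} must be strictly ascending, length >= 2")
        if self.values.shape != (self.times.size, self.lats.size, self.lons.size):
            raise ConfigError("values shape must be (time, lat, lon)")

    def to_frame(self) -> pd.DataFrame:
        tt, la, lo = np.meshgrid(self.times, self.lats, self.lons, indexing="ij")
        return pd.DataFrame(
            {"time": tt.ravel(), "lat": la.ravel(), "lon": lo.ravel(),
             "value": self.values.ravel()}
        )


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def generate_temperature(site: SiteConfig, mean_annual: float = 8.0,
                         amplitude: float = 10.0,
                         warming_trend: float = 0.0,
                         noise_sd: float = 2.0, seed: int = 0) -> DailySeries:
    """Daily mean temperature: seasonal cosine peaking at DOY 200, a linear
    warming trend (degC per decade), and white noise."""
    if amplitude <= 0:
        raise ConfigError("amplitude must be positive")
    if noise_sd < 0:
        raise ConfigError("noise_sd must be non-negative")
    years, doys = full_year_axis(site.start_year, site.n_years)
    year_index = years - site.start_year
    seasonal = amplitude * np.cos(2 * np.pi * (doys - 200) / DAYS_PER_YEAR)
    trend = warming_trend * (year_index / 10.0)
    noise = _rng(seed).normal(0.0, noise_sd, size=doys.size) if noise_sd else 0.0
    return DailySeries(site.site_id, "temperature", years, doys,
                       mean_annual + seasonal + trend + noise)


def _gs_mean_by_year(temp: DailySeries) -> pd.Series:
    lo, hi = GROWING_SEASON
    mask = (temp.doy >= lo) & (temp.doy < hi)
    return pd.Series(temp.value[mask]).groupby(temp.year[mask]).mean()


def generate_phenology_truth(site: SiteConfig, temp: DailySeries,
                             base_sos: float = 120.0, true_st: float = -2.0,
                             sos_noise_sd: float = 3.0, seed: int = 0,
                             season_length: float = DEFAULT_SEASON_LENGTH,
                             ) -> list[TruthRecord]:
    """Impose the previous-season temperature effect on SOS.

    For year *y* (second onward) the true SOS is
    ``base_sos + true_st * (T_GS(y-1) - mean T_GS) + noise``, where T_GS is
    the May-September mean temperature.  The first year has no previous
    season; its SOS is drawn around ``base_sos`` and flagged accordingly.
    """
    if not (60 <= base_sos <= 180):
        raise ConfigError("base_sos must lie in [60, 180]")
    missing = set(site.years) - set(temp.years)
    if missing:
        raise ConfigError(f"temperature series missing years {sorted(missing)}")
    tgs = _gs_mean_by_year(temp)
    tgs_mean = tgs.loc[list(site.years)].mean()
    rng = _rng(seed)
    records = []
    paths = {("T_GS_prev", "SOS"): true_st}
    for i, year in enumerate(site.years):
        if i == 0:
            shift = 0.0
        else:
            shift = true_st * (tgs.loc[year - 1] - tgs_mean)
        noise = rng.normal(0.0, sos_noise_sd) if sos_noise_sd else 0.0
        sos = base_sos + shift + noise
        # truncate noise so 1 <= sos < eos <= 366 always holds
        sos = float(np.clip(sos, 1.0, 366.0 - season_length - 1.0))
        records.append(TruthRecord(site.site_id, int(year), sos,
                                   sos + season_length, true_st, dict(paths),
                                   has_prev_season=(i > 0)))
    return records


def generate_seasonal_curve(truth: TruthRecord, curve_kind: str,
                            background: float | None = None,
                            amplitude: float | None = None,
                            rate: float | None = None,
                            obs_noise_sd: float | None = None,
                            cadence_days: int | None = None,
                            seed: int = 0) -> DailySeries:
    """Sample one site-year of a double-logistic seasonal curve.

    The spring inflection sits at ``true_sos`` and the autumn inflection at
    ``true_eos``.  For GPP curves the implied true annual maximum is stored
    in ``series.meta['true_peak']``.
    """
    if curve_kind not in CURVE_DEFAULTS:
        raise ConfigError(f"unknown curve kind {curve_kind!r}")
    d = CURVE_DEFAULTS[curve_kind]
    background = d["background"] if background is None else background
    amplitude = d["amplitude"] if amplitude is None else amplitude
    rate = d["rate"] if rate is None else rate
    obs_noise_sd = d["obs_noise_sd"] if obs_noise_sd is None else obs_noise_sd
    cadence_days = d["cadence_days"] if cadence_days is None else cadence_days
    if amplitude <= 0 or rate <= 0:
        raise ConfigError("amplitude and rate must be positive")
    if cadence_days not in (1, 15):
        raise ConfigError("cadence_days must be 1 or 15")
    sep = truth.true_eos - truth.true_sos
    if rate * sep < 10.0:
        raise ConfigError(
            "season too short to separate the two logistic limbs "
            f"(rate * separation = {rate * sep:.2f} < 10)"
        )
    doys = np.arange(1, DAYS_PER_YEAR + 1, cadence_days)
    clean = double_logistic(doys, amplitude, background, rate, truth.true_sos,
                            rate, truth.true_eos)
    noise = (_rng(seed).normal(0.0, obs_noise_sd, size=doys.size)
             if obs_noise_sd else 0.0)
    series = DailySeries(truth.site_id, curve_kind,
                         np.full(doys.size, truth.year), doys, clean + noise)
    if curve_kind == "gpp":
        series.meta["true_peak"] = plateau_value(
            amplitude, background, rate, truth.true_sos, rate, truth.true_eos)
    return series


def default_flux_edges() -> list[tuple[str, str]]:
    """Edge list of the climate -> GPPmax -> SOS causal graph."""
    edges = [(c, "gppmax") for c in CLIMATE_VARS]
    edges += [(c, "sos") for c in CLIMATE_VARS]
    edges.append(("gppmax", "sos"))
    return edges


def generate_flux_site_panel(sites: list[SiteConfig], sem_truth: dict,
                             noise_sds: dict | None = None, seed: int = 0,
                             edges: list[tuple[str, str]] | None = None,
                             ) -> tuple[pd.DataFrame, list[TruthRecord]]:
    """Site-year panel drawn from the linear structural model.

    Climate drivers are independent standard normals.  GPPmax and SOS are
    linear combinations per ``sem_truth`` plus Gaussian noise whose variance
    is chosen so each endogenous variable also has unit variance — the
    generating coefficients are then exactly the standardized paths.
    Explicit ``noise_sds`` override that calibration (the recorded true
    standardized paths are rescaled accordingly).
    """
    edges = default_flux_edges() if edges is None else list(edges)
    if set(sem_truth) != set(edges):
        missing = set(edges) - set(sem_truth)
        extra = set(sem_truth) - set(edges)
        raise ConfigError(
            f"sem_truth edge set mismatch: missing {sorted(missing)}, "
            f"unexpected {sorted(extra)}"
        )
    rng = _rng(seed)
    rows = []
    n_total = sum(s.n_years for s in sites)
    clim = {c: rng.normal(size=n_total) for c in CLIMATE_VARS}

    def _coef(src, dst):
        return sem_truth.get((src, dst), 0.0)

    b_g = np.array([_coef(c, "gppmax") for c in CLIMATE_VARS])
    var_g_struct = float(b_g @ b_g)
    if noise_sds is None:
        if var_g_struct >= 1.0:
            raise ConfigError("sum of squared gppmax coefficients must be < 1 "
                              "for unit-variance calibration")
        sd_g = float(np.sqrt(1.0 - var_g_struct))
    else:
        sd_g = float(noise_sds.get("gppmax", 1.0))
    gpp = sum(b_g[i] * clim[c] for i, c in enumerate(CLIMATE_VARS))
    gpp = gpp + rng.normal(0.0, sd_g, size=n_total)

    b_s = np.array([_coef(c, "sos") for c in CLIMATE_VARS])
    b_gs = _coef("gppmax", "sos")
    sd_gpp = float(np.sqrt(var_g_struct + sd_g ** 2))
    # structural variance of sos before its own noise
    var_s_struct = float(b_s @ b_s + (b_gs * sd_gpp) ** 2
                         + 2 * b_gs * (b_s @ b_g))
    if noise_sds is None:
        if var_s_struct >= 1.0:
            raise ConfigError("sos structural variance must be < 1 for "
                              "unit-variance calibration")
        sd_s = float(np.sqrt(1.0 - var_s_struct))
    else:
        sd_s = float(noise_sds.get("sos", 1.0))
    sos = sum(b_s[i] * clim[c] for i, c in enumerate(CLIMATE_VARS))
    sos = sos + b_gs * gpp + rng.normal(0.0, sd_s, size=n_total)

    sd_sos = float(np.sqrt(var_s_struct + sd_s ** 2))
    truths = []
    pos = 0
    for site in sites:
        for year in site.years:
            rows.append({"site_id": site.site_id, "year": int(year),
                         **{c: clim[c][pos] for c in CLIMATE_VARS},
                         "gppmax": gpp[pos], "sos": sos[pos]})
            pos += 1
    # standardized truth: coef * sd(parent) / sd(child)
    sds = {c: 1.0 for c in CLIMATE_VARS}
    sds["gppmax"] = sd_gpp
    sds["sos"] = sd_sos
    std_paths = {(u, v): (sem_truth[(u, v)] * sds[u] / sds[v]
                          if sds[v] > 0 else 0.0) for u, v in edges}
    for site in sites:
        for i, year in enumerate(site.years):
            truths.append(TruthRecord(site.site_id, int(year), 120.0, 280.0,
                                      0.0, dict(std_paths),
                                      has_prev_season=(i > 0)))
    return pd.DataFrame(rows), truths


def generate_climate_grid(extent: tuple[float, float, float, float],
                          resolution: float, field=None,
                          n_times: int = 1, seed: int = 0) -> ClimateGrid:
    """Regular grid whose values come from a known analytic ``field``
    (callable of lat, lon, time) so interpolation error is computable.
    ``field=None`` draws smooth random Fourier fields."""
    lat0, lat1, lon0, lon1 = extent
    if resolution <= 0:
        raise ConfigError("resolution must be positive")
    if lat1 <= lat0 or lon1 <= lon0:
        raise ConfigError("degenerate extent")
    lats = np.arange(lat0, lat1 + resolution / 2, resolution)
    lons = np.arange(lon0, lon1 + resolution / 2, resolution)
    times = np.arange(n_times)
    if field is None:
        rng = _rng(seed)
        a, b_, c = rng.normal(size=3)

        def field(lat, lon, t):  # noqa: ANN001 - smooth default field
            return (a * np.sin(np.deg2rad(lat)) + b_ * np.cos(np.deg2rad(lon))
                    + c * 0.1 * t)

    tt, la, lo = np.meshgrid(times, lats, lons, indexing="ij")
    return ClimateGrid(lats, lons, times, np.asarray(field(la, lo, tt), float))
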