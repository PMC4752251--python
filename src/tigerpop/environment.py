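"""Daily environmental drivers, photoperiod, and synthetic data generation.

The population model consumes four drivers per site and day: mean air
temperature (deg C), precipitation (mm/day, all types treated as rainfall),
human population density (persons/km^2, constant per site) and photoperiod
(hours, derived from latitude and date).

This module also generates the synthetic study conditions used throughout the
test suite: a sinusoid-plus-noise annual temperature cycle, intermittent
Bernoulli-Exponential rainfall, and biweekly May-October ovitrap summaries
with Gaussian observation error matching the calibration likelihood.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "EnvironmentSeries",
    "SurveillanceTable",
    "compute_photoperiod",
    "water_temperature",
    "read_climate_grid",
    "generate_synthetic_environment",
    "generate_synthetic_surveillance",
    "surveillance_windows",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Photoperiod (Forsythe-1995 daylength model)
# ---------------------------------------------------------------------------

def compute_photoperiod(latitude, day_of_year, coefficient: float = 0.0):
    """Daylength in hours for a latitude (degrees) and day of year.

    Uses the Forsythe et al. (1995) model.  ``coefficient`` is the daylength
    coefficient in degrees of solar elevation defining sunrise/sunset; the
    default 0.0 is the sun-centre convention of the standard geospatial
    daylength routine.  Above the polar circles the result clamps to 24 h
    (polar day) or 0 h (polar night).
    """
    lat = np.asarray(latitude, dtype=float)
    doy = np.asarray(day_of_year, dtype=float)
    if np.any(lat < -90.0) or np.any(lat > 90.0):
        raise ValueError("latitude must be within [-90, 90] degrees")
    if np.any(doy < 1) or np.any(doy > 366):
        raise ValueError("day_of_year must be within [1, 366]")

    # revolution angle and solar declination
    theta = 0.2163108 + 2.0 * np.arctan(0.9671396 * np.tan(0.00860 * (doy - 186.0)))
    phi = np.arcsin(0.39795 * np.cos(theta))

    p = np.radians(coefficient)
    latr = np.radians(lat)
    num = np.sin(p) + np.sin(latr) * np.sin(phi)
    den = np.cos(latr) * np.cos(phi)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.where(den != 0.0, num / den, np.sign(num) * np.inf)
    x = np.clip(x, -1.0, 1.0)
    hours = 24.0 - (24.0 / np.pi) * np.arccos(x)
    if np.ndim(hours) == 0:
        return float(hours)
    return hours


def water_temperature(T_a, delta_T: float):
    """Water temperature as a fixed offset below air temperature: T_a - delta_T."""
    return np.asarray(T_a, dtype=float) - delta_T if np.ndim(T_a) else float(T_a) - delta_T


# ---------------------------------------------------------------------------
# Environment series
# ---------------------------------------------------------------------------

@dataclass
class EnvironmentSeries:
    """Per-day driver record for one site.

    ``dates`` must be strictly consecutive calendar days; ``photoperiod`` is
    filled from latitude and date if not given.
    """

    dates: pd.DatetimeIndex
    T_a: np.ndarray
    precip: np.ndarray
    p_dens: float
    latitude: float
    photoperiod: np.ndarray = None

    def __post_init__(self):
        self.dates = pd.DatetimeIndex(self.dates)
        self.T_a = np.asarray(self.T_a, dtype=float)
        self.precip = np.asarray(self.precip, dtype=float)
        n = len(self.dates)
        if len(self.T_a) != n or len(self.precip) != n:
            raise ValueError("all per-day fields must have equal length")
        if n > 1:
            deltas = np.diff(self.dates.values).astype("timedelta64[D]").astype(int)
            if not np.all(deltas == 1):
                raise ValueError("dates must increase by exactly one day, no gaps")
        if np.any(self.precip < 0):
            raise ValueError("precipitation must be >= 0")
        if self.p_dens < 0:
            raise ValueError("population density must be >= 0")
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError("latitude must be within [-90, 90]")
        if self.photoperiod is None:
            self.photoperiod = compute_photoperiod(self.latitude, self.dates.dayofyear.values)
        self.photoperiod = np.asarray(self.photoperiod, dtype=float)
        if len(self.photoperiod) != n:
            raise ValueError("photoperiod length mismatch")
        if np.any((self.photoperiod < 0) | (self.photoperiod > 24)):
            raise ValueError("photoperiod must lie in [0, 24] hours")

    def __len__(self):
        return len(self.dates)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "date": self.dates, "T_a": self.T_a, "precip": self.precip,
            "photoperiod": self.photoperiod,
        })

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, p_dens: float, latitude: float) -> "EnvironmentSeries":
        pp = df["photoperiod"].values if "photoperiod" in df.columns else None
        return cls(pd.DatetimeIndex(df["date"]), df["T_a"].values, df["precip"].values,
                   p_dens, latitude, pp)


# ---------------------------------------------------------------------------
# Gridded climate input
# ---------------------------------------------------------------------------

def read_climate_grid(path, variable: str, bbox=None, dates=None,
                      mask: Optional[Callable[[float, float], bool]] = None):
    """Read one variable from a CF-convention NetCDF grid as day-by-cell series.

    Parameters
    ----------
    path : file path of a NetCDF dataset with (time, lat, lon) layout.
    variable : variable name; temperatures in kelvin are converted to deg C
        (detected from the ``units`` attribute, logged).
    bbox : optional (lat_min, lat_max, lon_min, lon_max) bounds.
    dates : optional (start, end) date range (inclusive).
    mask : optional predicate ``mask(lat, lon) -> bool``; cells failing it are
        dropped (e.g. a land/population mask).

    Returns
    -------
    (data, coords) : ``data`` is a float array of shape (n_days, n_cells) with
    missing values kept as NaN; ``coords`` is a list of (lat, lon) per cell.
    """
    import xarray as xr

    ds = xr.open_dataset(path, engine="scipy")
    try:
        if variable not in ds:
            raise KeyError(f"variable {variable!r} not present in {path}")
        da = ds[variable]
        latname = "latitude" if "latitude" in da.dims else "lat"
        lonname = "longitude" if "longitude" in da.dims else "lon"
        if bbox is not None:
            lat_min, lat_max, lon_min, lon_max = bbox
            da = da.where(
                (da[latname] >= lat_min) & (da[latname] <= lat_max)
                & (da[lonname] >= lon_min) & (da[lonname] <= lon_max), drop=True)
            if da.size == 0:
                raise ValueError("bbox intersects no grid cells")
        if dates is not None:
            da = da.sel(time=slice(dates[0], dates[1]))
        units = str(da.attrs.get("units", ""))
        values = da.transpose("time", latname, lonname).values.astype(float)
        if units.lower() in ("k", "kelvin"):
            logger.info("converting %s from kelvin to deg C", variable)
            values = values - 273.15
        lats = da[latname].values
        lons = da[lonname].values
        n_days = values.shape[0]
        cols, coords = [], []
        for i, la in enumerate(np.atleast_1d(lats)):
            for j, lo in enumerate(np.atleast_1d(lons)):
                if mask is not None and not mask(float(la), float(lo)):
                    continue
                cols.append(values[:, i, j])
                coords.append((float(la), float(lo)))
        if not cols:
            raise ValueError("mask removed all grid cells")
        return np.column_stack(cols).reshape(n_days, len(cols)), coords
    finally:
        ds.close()


# ---------------------------------------------------------------------------
# Synthetic environment
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSiteConfig:
    """Study conditions of one synthetic site.

    Defaults emulate a temperate southern-European ovitrap site: annual
    temperature sinusoid (mean 13 C, amplitude 11 C, coldest mid-January) with
    day-to-day Gaussian noise, wet days on ~35% of days with exponential
    (mean 6 mm) rain totals, and an urban population density of 1000 / km^2.
    """

    latitude: float = 44.5
    t_mean: float = 13.0
    t_amplitude: float = 11.0
    t_noise_sd: float = 1.5
    rain_prob: float = 0.35
    rain_mean: float = 6.0
    p_dens: float = 1000.0
    years: int = 3
    start_year: int = 2008
    coldest_doy: int = 15


def generate_synthetic_environment(config: SyntheticSiteConfig = None,
                                   seed: int = 0, **overrides) -> EnvironmentSeries:
    """Generate a reproducible synthetic driver series.

    T_a is an annual sinusoid plus iid Gaussian noise; precipitation is a
    Bernoulli(rain_prob) x Exponential(rain_mean) mixture per day; photoperiod
    is computed from latitude and the calendar (proleptic Gregorian, leap days
    included).
    """
    cfg = config or SyntheticSiteConfig()
    if overrides:
        cfg = SyntheticSiteConfig(**{**cfg.__dict__, **overrides})
    if cfg.years <= 0:
        raise ValueError("span of years must be positive")
    rng = np.random.default_rng(seed)
    start = pd.Timestamp(year=cfg.start_year, month=1, day=1)
    end = pd.Timestamp(year=cfg.start_year + cfg.years - 1, month=12, day=31)
    dates = pd.date_range(start, end, freq="D")
    doy = dates.dayofyear.values.astype(float)
    phase = 2.0 * np.pi * (doy - cfg.coldest_doy) / 365.25
    T_a = cfg.t_mean - cfg.t_amplitude * np.cos(phase)
    if cfg.t_noise_sd > 0:
        T_a = T_a + rng.normal(0.0, cfg.t_noise_sd, size=len(dates))
    wet = rng.random(len(dates)) < cfg.rain_prob
    precip = np.where(wet, rng.exponential(cfg.rain_mean, size=len(dates)), 0.0)
    return EnvironmentSeries(dates, T_a, precip, cfg.p_dens, cfg.latitude)


# ---------------------------------------------------------------------------
# Surveillance
# ---------------------------------------------------------------------------

@dataclass
class SurveillanceTable:
    """Province-by-window ovitrap summaries.

    Wraps a DataFrame with columns ``province, window_end, n_traps, mean_eggs,
    sem, first_of_year``.  Each window spans the 14 days up to and including
    ``window_end``; the first usable window of each province-year is flagged
    and carries no consecutive-difference likelihood term.
    """

    data: pd.DataFrame

    COLUMNS = ("province", "window_end", "n_traps", "mean_eggs", "sem", "first_of_year")

    def __post_init__(self):
        df = self.data.copy()
        missing = set(self.COLUMNS[:5]) - set(df.columns)
        if missing:
            raise ValueError(f"surveillance table missing columns {sorted(missing)}")
        df["window_end"] = pd.to_datetime(df["window_end"])
        if "first_of_year" not in df.columns:
            df = df.sort_values(["province", "window_end"])
            year = df["window_end"].dt.year
            df["first_of_year"] = df.groupby(["province", year]).cumcount() == 0
        if (df["n_traps"] < 1).any():
            raise ValueError("n_traps must be >= 1")
        if (df["mean_eggs"] < 0).any():
            raise ValueError("mean_eggs must be >= 0")
        if (df["sem"] <= 0).any():
            raise ValueError("sem must be > 0")
        df = df.sort_values(["province", "window_end"]).reset_index(drop=True)
        for (_, _), grp in df.groupby([df["province"], df["window_end"].dt.year]):
            ends = grp["window_end"].values
            if len(ends) > 1:
                gaps = np.diff(ends).astype("timedelta64[D]").astype(int)
                if np.any(gaps < 14):
                    raise ValueError("windows within a province-year overlap")
        self.data = df

    def __len__(self):
        return len(self.data)

    @property
    def provinces(self):
        return list(self.data["province"].unique())

    def to_csv(self, path):
        out = self.data.rename(columns={"mean_eggs": "mean_eggs"})
        out.to_csv(path, index=False,
                   columns=["province", "window_end", "n_traps", "mean_eggs", "sem"])

    @classmethod
    def from_csv(cls, path) -> "SurveillanceTable":
        return cls(pd.read_csv(path))


def surveillance_windows(year: int):
    """Biweekly May-October collection windows of one season.

    Returns the list of window end dates: 14-day windows starting May 1, the
    last one ending on or before October 31.
    """
    ends = []
    end = pd.Timestamp(year=year, month=5, day=14)
    last = pd.Timestamp(year=year, month=10, day=31)
    while end <= last:
        ends.append(end)
        end = end + pd.Timedelta(days=14)
    return ends


def generate_synthetic_surveillance(theta_true, envs: dict, n_traps: int = 25,
                                    noise_sd: float = 1.0, seed: int = 0,
                                    burn_in_years: int = 1) -> SurveillanceTable:
    """Simulate the model and emit noisy biweekly ovitrap summaries.

    ``envs`` maps province name to its :class:`EnvironmentSeries`; the first
    ``burn_in_years`` calendar years are treated as establishment and excluded
    from the table.  Observed means are the windowed egg observable plus
    Gaussian(0, noise_sd) noise (negative draws clamped to 0 and logged);
    the reported SEM is noise_sd / sqrt(n_traps).
    """
    from .population import simulate, windowed_egg_observable

    rng = np.random.default_rng(seed)
    sem = noise_sd / math.sqrt(n_traps) if noise_sd > 0 else 1e-9
    rows = []
    n_clamped = 0
    for province, env in envs.items():
        years = sorted(set(env.dates.year))
        if len(years) <= burn_in_years:
            raise ValueError("environment must cover burn-in plus at least one season")
        out = simulate(env, theta_true)
        for year in years[burn_in_years:]:
            ends = surveillance_windows(year)
            ends = [e for e in ends if e <= env.dates[-1]]
            for k, end in enumerate(ends):
                y = windowed_egg_observable(out, end)
                delta = y + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                if delta < 0:
                    n_clamped += 1
                    delta = 0.0
                rows.append({
                    "province": province, "window_end": end, "n_traps": n_traps,
                    "mean_eggs": delta, "sem": sem, "first_of_year": k == 0,
                })
    if n_clamped:
        logger.info("clamped %d negative synthetic observations to 0", n_clamped)
    return SurveillanceTable(pd.DataFrame(rows))
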