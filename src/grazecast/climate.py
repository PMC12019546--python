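"""Monthly climate series and delta-change projection to future horizons.

The analysis pipeline runs on a monthly cadence: soil carbon turnover and
the farm carbon accounting are monthly models, so daily weather input is
aggregated on read. Future climates (2030, 2050) are built from a
historical series by the delta-change method — an additive temperature
shift and multiplicative rain/evaporation factors per calendar month —
with an optional inflation of interannual rainfall variability.
Atmospheric CO2 is carried alongside the weather: 350 ppm for the
historical horizon, 450 ppm for 2030 and 530 ppm for 2050.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ClimateSeries",
    "ScalingFactorSet",
    "HORIZON_CO2_PPM",
    "read_climate_csv",
    "apply_scaling",
    "synth_historical",
]

HORIZON_CO2_PPM = {"historical": 350.0, "2030": 450.0, "2050": 530.0}

_REQUIRED_COLUMNS = ("date", "rain", "tmax", "tmin", "evap")


class ClimateFormatError(ValueError):
    """Raised when a climate CSV is malformed."""


class ContiguityError(ValueError):
    """Raised when a monthly series has a gap."""


@dataclass(frozen=True)
class ClimateSeries:
    """Contiguous monthly weather for one site.

    ``records`` has columns ``year, month, rain, tmean, pan_evap``
    (mm, °C, mm), one row per calendar month in order.
    """

    site_id: str
    records: pd.DataFrame
    co2_ppm: float = 350.0

    def __post_init__(self) -> None:
        df = self.records
        if (df["rain"] < 0).any() or (df["pan_evap"] < 0).any():
            raise ValueError("rain and pan_evap must be non-negative")
        _check_contiguous(df)

    @property
    def n_years(self) -> int:
        return len(self.records) // 12

    def year_blocks(self) -> list[pd.DataFrame]:
        """Split into calendar-year chunks of 12 rows (whole years only)."""
        df = self.records
        return [
            g for _, g in df.groupby("year", sort=True) if len(g) == 12
        ]


def _check_contiguous(df: pd.DataFrame) -> None:
    if len(df) == 0:
        return
    idx = df["year"].to_numpy() * 12 + (df["month"].to_numpy() - 1)
    gaps = np.flatnonzero(np.diff(idx) != 1)
    if gaps.size:
        i = gaps[0]
        missing = idx[i] + 1
        raise ContiguityError(
            f"gap in monthly series: first missing month is "
            f"{missing // 12}-{missing % 12 + 1:02d}"
        )


@dataclass(frozen=True)
class ScalingFactorSet:
    """Delta-change factors for one horizon.

    ``temp_delta_c`` is additive (°C); ``rain_factor`` and ``evap_factor``
    multiplicative; each is indexed by calendar month 1..12.
    ``variability_inflation`` adds extra interannual spread to rain via a
    clamped multiplicative annual perturbation (see :func:`apply_scaling`).
    """

    horizon: str
    temp_delta_c: dict[int, float] = field(default_factory=dict)
    rain_factor: dict[int, float] = field(default_factory=dict)
    evap_factor: dict[int, float] = field(default_factory=dict)
    variability_inflation: float = 0.0

    def __post_init__(self) -> None:
        if self.variability_inflation < 0:
            raise ValueError("variability_inflation must be >= 0")
        for m in range(1, 13):
            if self.rain_factor.get(m, 1.0) <= 0:
                raise ValueError(f"rain_factor for month {m} must be > 0")
            if self.evap_factor.get(m, 1.0) <= 0:
                raise ValueError(f"evap_factor for month {m} must be > 0")

    @classmethod
    def identity(cls, horizon: str = "historical") -> "ScalingFactorSet":
        return cls(horizon=horizon)

    @classmethod
    def uniform(
        cls,
        horizon: str,
        temp_delta_c: float = 0.0,
        rain_factor: float = 1.0,
        evap_factor: float = 1.0,
        variability_inflation: float = 0.0,
    ) -> "ScalingFactorSet":
        months = range(1, 13)
        return cls(
            horizon=horizon,
            temp_delta_c={m: temp_delta_c for m in months},
            rain_factor={m: rain_factor for m in months},
            evap_factor={m: evap_factor for m in months},
            variability_inflation=variability_inflation,
        )


def read_climate_csv(path, site_id: str) -> ClimateSeries:
    """Read a SILO-style weather CSV (daily or monthly) into monthly form.

    Expects header ``date,rain,tmax,tmin,evap`` with ISO dates; rain and
    evaporation in mm, temperatures in °C. Daily rows are aggregated:
    rain and evap summed, monthly mean temperature taken as the mean of
    the daily (tmax + tmin) / 2.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ClimateFormatError(f"empty climate file: {path}") from exc
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ClimateFormatError(f"missing required column: {col!r}")
    if len(df) == 0:
        raise ClimateFormatError(f"climate file has no data rows: {path}")
    dates = pd.to_datetime(df["date"])
    df = df.assign(year=dates.dt.year, month=dates.dt.month,
                   tmid=(df["tmax"] + df["tmin"]) / 2.0)
    monthly = (
        df.groupby(["year", "month"], sort=True)
        .agg(rain=("rain", "sum"), tmean=("tmid", "mean"),
             pan_evap=("evap", "sum"))
        .reset_index()
    )
    return ClimateSeries(site_id=site_id, records=monthly)


def apply_scaling(
    hist: ClimateSeries, factors: ScalingFactorSet, seed: int
) -> ClimateSeries:
    """Project a historical series to a horizon by delta-change scaling.

    Per month m of year y:
        tmean' = tmean + temp_delta_c[m]
        rain'  = rain * rain_factor[m] * max(0, 1 + inflation * z_y)
        evap'  = evap * evap_factor[m]
    where z_y is one standard-normal draw per year (seeded), shared by the
    12 months of that year so that the inflation perturbs annual totals.
    CO2 is set from the horizon label.
    """
    rng = np.random.default_rng(seed)
    df = hist.records.copy()
    years = np.sort(df["year"].unique())
    z = dict(zip(years, rng.standard_normal(len(years))))
    infl = factors.variability_inflation
    m = df["month"].to_numpy()
    tdelta = np.array([factors.temp_delta_c.get(mm, 0.0) for mm in m])
    rfac = np.array([factors.rain_factor.get(mm, 1.0) for mm in m])
    efac = np.array([factors.evap_factor.get(mm, 1.0) for mm in m])
    year_mult = np.array(
        [max(0.0, 1.0 + infl * z[y]) for y in df["year"].to_numpy()]
    )
    df["tmean"] = df["tmean"] + tdelta
    df["rain"] = df["rain"] * rfac * year_mult
    df["pan_evap"] = df["pan_evap"] * efac
    co2 = HORIZON_CO2_PPM.get(factors.horizon, hist.co2_ppm)
    return ClimateSeries(site_id=hist.site_id, records=df, co2_ppm=co2)


@dataclass(frozen=True)
class SiteStatistics:
    """Targets for the synthetic historical weather generator."""

    annual_rain_mean: float  # mm
    annual_rain_sd: float  # mm
    monthly_rain_fraction: tuple[float, ...]  # 12 values summing to 1
    monthly_tmean: tuple[float, ...]  # °C, Jan..Dec
    monthly_pan_evap: tuple[float, ...]  # mm, Jan..Dec

    def __post_init__(self) -> None:
        if self.annual_rain_mean <= 0 or self.annual_rain_sd < 0:
            raise ValueError("annual rain mean must be > 0, sd >= 0")
        for name in ("monthly_rain_fraction", "monthly_tmean",
                     "monthly_pan_evap"):
            if len(getattr(self, name)) != 12:
                raise ValueError(f"{name} must have 12 entries")


def synth_historical(
    params: SiteStatistics, n_years: int, seed: int, start_year: int = 2000
) -> ClimateSeries:
    """Generate a seeded synthetic historical monthly series.

    Annual rain totals are drawn normal(mean, sd) truncated at zero and
    spread over months by the site's climatological monthly fractions;
    temperature and pan evaporation follow the monthly profiles with
    small seeded noise.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    rng = np.random.default_rng(seed)
    annual = np.maximum(
        0.0, rng.normal(params.annual_rain_mean, params.annual_rain_sd,
                        n_years)
    )
    frac = np.asarray(params.monthly_rain_fraction)
    frac = frac / frac.sum()
    rows = []
    for iy in range(n_years):
        t_noise = rng.normal(0.0, 0.5, 12)
        for im in range(12):
            rows.append(
                (start_year + iy, im + 1,
                 annual[iy] * frac[im],
                 params.monthly_tmean[im] + t_noise[im],
                 params.monthly_pan_evap[im])
            )
    df = pd.DataFrame(
        rows, columns=["year", "month", "rain", "tmean", "pan_evap"]
    )
    return ClimateSeries(site_id="synthetic", records=df, co2_ppm=350.0)


def project(hist: ClimateSeries, factors: ScalingFactorSet,
            seed: int) -> ClimateSeries:
    """Alias for :func:`apply_scaling` (reads better at call sites)."""
    return apply_scaling(hist, factors, seed)
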