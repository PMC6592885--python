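"""Toy rice-yield model and the percent-impact endpoint.

The crop simulator is a deliberately transparent stand-in for a full
process-based rice model, driven only by the generated variables
(temperature and precipitation):

* thermal time: daily growing-degree days ``GDD = max(0, Tmean - Tb)``
  accumulate from sowing to a maturity sum (default 1600 degC d) or a
  210-day cap;
* radiation: daily solar radiation is estimated from the diurnal range
  (Hargreaves-Samani, ``Rs = krs sqrt(Tmax - Tmin) Ra``);
* biomass: ``dB = RUE * 0.5 * Rs * fT(Tmean) * fW`` with a trapezoidal
  temperature factor on cardinal temperatures (12/26/32/42 degC) and a
  water factor ``fW = min(1, P30 / PET30)`` over a trailing 30-day window;
* yield: final biomass times a harvest index, in t/ha.

It is pluggable behind this module's interface so a real crop model can be
substituted.  Season counting is pinned to the convention that a 20-year
series yields 19 growing seasons in either hemisphere: a season counts
only if it is complete within the series and ends after the first
calendar year (the first year serves as spin-up in the northern
hemisphere; southern-hemisphere seasons cross the new year).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DailySeries
from .indices import extraterrestrial_radiation, hargreaves_et0

__all__ = ["CropConfig", "SeasonWindow", "YieldResult",
           "extract_seasons", "simulate_yield", "impact_percent"]


@dataclass(frozen=True)
class CropConfig:
    """Parameters of the toy rice model.

    ``sowing_doy`` defaults hemisphere-aware: day 121 (early May) north,
    day 305 (early November) south, so the season tracks local summer.
    """

    sowing_doy: int | None = None
    base_temperature: float = 12.0          # degC
    thermal_time_maturity: float = 1600.0   # degC d
    rue: float = 2.2                        # g biomass per MJ intercepted
    harvest_index: float = 0.45
    cardinal_temps: tuple = (12.0, 26.0, 32.0, 42.0)
    krs: float = 0.17                       # Hargreaves radiation coefficient
    max_season_days: int = 210
    water_limited: bool = True
    temperature_limited: bool = True

    def __post_init__(self):
        if not 0.0 < self.harvest_index < 1.0:
            raise ValueError("harvest index must be in (0, 1)")
        if not all(a < b for a, b in zip(self.cardinal_temps,
                                         self.cardinal_temps[1:])):
            raise ValueError("cardinal temperatures must be strictly increasing")

    def sowing_day(self, latitude: float) -> int:
        if self.sowing_doy is not None:
            return self.sowing_doy
        return 121 if latitude >= 0 else 305


@dataclass(frozen=True)
class SeasonWindow:
    """Half-open day-index window [start, end) of one growing season."""

    year: int
    start: int
    end: int
    reached_maturity: bool


def _temperature_factor(tmean: np.ndarray, cardinals) -> np.ndarray:
    tb, to1, to2, tc = cardinals
    f = np.zeros_like(tmean)
    up = (tmean > tb) & (tmean < to1)
    f[up] = (tmean[up] - tb) / (to1 - tb)
    f[(tmean >= to1) & (tmean <= to2)] = 1.0
    dn = (tmean > to2) & (tmean < tc)
    f[dn] = (tc - tmean[dn]) / (tc - to2)
    return f


def extract_seasons(series: DailySeries, crop: CropConfig) -> list[SeasonWindow]:
    """Sow once per calendar year and delimit each growing season.

    A season runs from the sowing day to thermal-time maturity or the
    210-day cap, whichever comes first.  Seasons that would extend past
    the series end are excluded with a warning; seasons ending within the
    first calendar year are excluded as spin-up.  A 20-year series yields
    19 seasons in both hemispheres under this convention.
    """
    if len(np.unique(series.years)) < 2:
        raise ValueError("need at least 2 calendar years to extract seasons")
    tmean = series.tmean
    gdd = np.maximum(tmean - crop.base_temperature, 0.0)
    doy = series.dates.dayofyear.values
    years = series.years
    first_year = int(years.min())
    sow_doy = crop.sowing_day(series.latitude)
    seasons = []
    for y in np.unique(years):
        idx = np.nonzero((years == y) & (doy == sow_doy))[0]
        if idx.size == 0:
            continue
        start = int(idx[0])
        horizon = min(start + crop.max_season_days, len(series))
        csum = np.cumsum(gdd[start:horizon])
        hit = np.nonzero(csum >= crop.thermal_time_maturity)[0]
        if hit.size:
            end = start + int(hit[0]) + 1
            matured = True
        else:
            end = start + crop.max_season_days
            matured = False
        if end > len(series):
            warnings.warn(f"season sown {y}-{sow_doy:03d} exceeds series end; "
                          "excluded", stacklevel=2)
            continue
        if int(years[end - 1]) == first_year:
            continue  # spin-up year
        seasons.append(SeasonWindow(year=int(y), start=start, end=end,
                                    reached_maturity=matured))
    return seasons


@dataclass
class YieldResult:
    """Per-season yields and their mean for one series."""

    series_label: str
    seasons: pd.DataFrame = field(repr=False)  # year, start_date, yield_t_ha

    @property
    def yields(self) -> np.ndarray:
        return self.seasons["yield_t_ha"].to_numpy()

    @property
    def mean_yield(self) -> float:
        return float(self.yields.mean())

    def summary(self) -> str:
        return (f"Yield simulation [{self.series_label}]: "
                f"{len(self.seasons)} seasons, "
                f"mean {self.mean_yield:.2f} t/ha, "
                f"range {self.yields.min():.2f}-{self.yields.max():.2f} t/ha")


def simulate_yield(series: DailySeries, crop: CropConfig | None = None,
                   latitude: float | None = None) -> YieldResult:
    """Run the toy rice model over every extracted season (deterministic)."""
    crop = crop or CropConfig()
    lat = series.latitude if latitude is None else latitude
    seasons = extract_seasons(series, crop)
    ra = extraterrestrial_radiation(lat, series.dates.dayofyear.values)
    rs = crop.krs * np.sqrt(np.maximum(series.tmax - series.tmin, 0.0)) * ra
    tmean = series.tmean
    ft = (_temperature_factor(tmean, crop.cardinal_temps)
          if crop.temperature_limited else np.ones_like(tmean))
    if crop.water_limited:
        pet = hargreaves_et0(series.tmax, series.tmin, lat, series.dates)
        p30 = pd.Series(series.prcp).rolling(30, min_periods=1).sum().to_numpy()
        pet30 = pd.Series(pet).rolling(30, min_periods=1).sum().to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            fw = np.where(pet30 > 0, np.minimum(1.0, p30 / pet30), 1.0)
    else:
        fw = np.ones_like(tmean)
    daily_gain = crop.rue * 0.5 * rs * ft * fw  # g/m2/day
    rows = []
    for s in seasons:
        biomass = float(daily_gain[s.start:s.end].sum())
        rows.append({"year": s.year,
                     "start_date": series.dates[s.start].date().isoformat(),
                     "reached_maturity": s.reached_maturity,
                     "yield_t_ha": biomass * crop.harvest_index * 0.01})
    return YieldResult(series_label=series.site_id,
                       seasons=pd.DataFrame(rows, columns=["year", "start_date",
                                                           "reached_maturity",
                                                           "yield_t_ha"]))


def impact_percent(future: YieldResult, baseline: YieldResult) -> float:
    """Percent change of future mean yield against the baseline mean:
    ``100 (mean_f - mean_b) / mean_b``; NaN when the baseline mean is 0."""
    mb = baseline.mean_yield
    if mb == 0:
        return float("nan")
    return 100.0 * (future.mean_yield - mb) / mb
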