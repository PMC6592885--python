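"""Core domain types for daily weather series: I/O, validation and QC.

A :class:`DailySeries` is one site's contiguous daily record of maximum
temperature, minimum temperature and precipitation.  Every other module in
the package consumes and produces this type, either in memory or through
the on-disk CSV interchange format (columns ``date,tmax,tmin,prcp``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DailySeries",
    "QCReport",
    "FormatError",
    "IntegrityError",
    "read_daily_csv",
    "write_daily_csv",
    "qc_series",
    "wet_mask",
]


class FormatError(ValueError):
    """Raised when an input file does not have the expected layout."""


class IntegrityError(ValueError):
    """Raised when a daily record violates a series invariant (gap,
    duplicate date, missing value)."""


@dataclass(frozen=True)
class DailySeries:
    """A contiguous daily weather record for one site.

    Parameters
    ----------
    site_id : str
        Free-text site label.
    latitude : float
        Site latitude in decimal degrees, in [-90, 90].
    dates : pandas.DatetimeIndex
        Strictly increasing daily dates with no gaps (real proleptic
        Gregorian calendar; Feb 29 is an ordinary day).
    tmax, tmin : numpy.ndarray
        Daily maximum / minimum air temperature, deg C.
    prcp : numpy.ndarray
        Daily precipitation total, mm/day, non-negative.
    """

    site_id: str
    latitude: float
    dates: pd.DatetimeIndex
    tmax: np.ndarray
    tmin: np.ndarray
    prcp: np.ndarray
    validate: bool = field(default=True, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "dates", pd.DatetimeIndex(self.dates).as_unit("s"))
        for name in ("tmax", "tmin", "prcp"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.dates)
        if not (len(self.tmax) == len(self.tmin) == len(self.prcp) == n):
            raise IntegrityError("tmax, tmin, prcp and dates must have equal length")
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if self.validate:
            self._check()

    def _check(self) -> None:
        step = np.diff(self.dates.values).astype("timedelta64[D]").astype(int)
        bad = np.nonzero(step != 1)[0]
        if bad.size:
            i = bad[0]
            if step[i] > 1:
                missing = (self.dates[i] + pd.Timedelta(days=1)).date()
                raise IntegrityError(f"gap in series: missing date {missing}")
            raise IntegrityError(
                f"dates not strictly increasing at {self.dates[i + 1].date()}"
            )
        for name in ("tmax", "tmin", "prcp"):
            arr = getattr(self, name)
            if np.isnan(arr).any():
                d = self.dates[int(np.nonzero(np.isnan(arr))[0][0])].date()
                raise IntegrityError(f"missing {name} value on {d}")
        if (self.tmax < self.tmin).any():
            d = self.dates[int(np.nonzero(self.tmax < self.tmin)[0][0])].date()
            raise IntegrityError(f"tmax < tmin on {d}")
        if (self.prcp < 0).any():
            d = self.dates[int(np.nonzero(self.prcp < 0)[0][0])].date()
            raise IntegrityError(f"negative precipitation on {d}")

    # -- convenience ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def tmean(self) -> np.ndarray:
        return 0.5 * (self.tmax + self.tmin)

    @property
    def years(self) -> np.ndarray:
        return self.dates.year.values

    @property
    def months(self) -> np.ndarray:
        return self.dates.month.values

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"tmax": self.tmax, "tmin": self.tmin, "prcp": self.prcp},
            index=self.dates.rename("date"),
        )

    def equals(self, other: "DailySeries") -> bool:
        return (
            self.site_id == other.site_id
            and self.latitude == other.latitude
            and self.dates.equals(other.dates)
            and np.array_equal(self.tmax, other.tmax)
            and np.array_equal(self.tmin, other.tmin)
            and np.array_equal(self.prcp, other.prcp)
        )


@dataclass(frozen=True)
class QCReport:
    """Counts of invariant violations found in a daily record."""

    n_days: int
    n_violations_tmax_lt_tmin: int
    n_negative_prcp: int
    n_gaps: int

    @property
    def passed(self) -> bool:
        return (
            self.n_violations_tmax_lt_tmin == 0
            and self.n_negative_prcp == 0
            and self.n_gaps == 0
        )


def read_daily_csv(path, site_id: str, latitude: float) -> DailySeries:
    """Read a ``date,tmax,tmin,prcp`` CSV into a validated :class:`DailySeries`.

    Rows are sorted by date before validation; a duplicated or missing
    calendar day raises :class:`IntegrityError` naming the offending date.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"date", "tmax", "tmin", "prcp"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"missing column(s) {sorted(missing)} in {path}")
    try:
        dates = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"unparseable date in {path}: {exc}") from exc
    order = np.argsort(dates.values, kind="stable")
    dates = pd.DatetimeIndex(dates.values[order])
    if dates.has_duplicates:
        dup = dates[dates.duplicated()][0].date()
        raise IntegrityError(f"duplicate date {dup}")
    return DailySeries(
        site_id=site_id,
        latitude=latitude,
        dates=dates,
        tmax=df["tmax"].to_numpy(float)[order],
        tmin=df["tmin"].to_numpy(float)[order],
        prcp=df["prcp"].to_numpy(float)[order],
    )


def write_daily_csv(series: DailySeries, path) -> None:
    """Write a series to the interchange CSV (ISO dates, '.' decimal)."""
    df = series.to_frame().reset_index()
    df["date"] = df["date"].dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False, float_format="%.17g")


def qc_series(series: DailySeries) -> QCReport:
    """Count invariant violations without mutating or raising."""
    step = np.diff(series.dates.values).astype("timedelta64[D]").astype(int)
    return QCReport(
        n_days=len(series),
        n_violations_tmax_lt_tmin=int((series.tmax < series.tmin).sum()),
        n_negative_prcp=int((series.prcp < 0).sum()),
        n_gaps=int((step != 1).sum()),
    )


def wet_mask(series: DailySeries, threshold: float) -> np.ndarray:
    """Boolean mask of wet days: ``prcp >= threshold`` (threshold in mm > 0)."""
    if threshold <= 0:
        raise ValueError(f"wet-day threshold must be > 0, got {threshold}")
    return series.prcp >= threshold


#: Default wet-day threshold (mm) used when calibrating generators.
WET_THRESHOLD_MM = 0.1
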