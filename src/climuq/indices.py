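"""The 33-metric climate/agro-climatic index battery.

27 standard climate-extremes indices (ETCCDI list: frost days, warm-day
percentage TX90p, cold-spell duration CSDI, maximum 1-day precipitation
Rx1day, ...) plus six agro-meteorological metrics: monthly Hargreaves
reference evapotranspiration (ET0), SPEI, the de Martonne-Gottman aridity
index, the UNEP aridity index, the monthly climatic water balance
P - PET, and a simple monthly aridity measure (SAM = P/PET).

Index values are returned as a long-form "index table" with one row per
(site, series label, index code, year, period), period being a calendar
month for monthly indices and ``"annual"`` otherwise.

Conventions (documented, applied identically to every compared series):

* Percentile thresholds use median-unbiased interpolation and a 5-day
  window centred on each calendar day, pooled over the base-period years.
  Feb 29 is excluded from pooling and borrows the Feb 28 thresholds.
* The in-base/out-of-base bootstrap for exceedance indices is not applied.
* The wet-day threshold for precipitation indices is 1.0 mm (the
  customary index convention), independent of the 0.1 mm generator
  calibration threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gamma as _gamma_fn

from .core import DailySeries

__all__ = [
    "ETCCDI_CODES",
    "AGRO_CODES",
    "ALL_CODES",
    "MONTHLY_CODES",
    "BasePeriodPercentiles",
    "compute_etccdi",
    "hargreaves_et0",
    "extraterrestrial_radiation",
    "spei",
    "aridity_metrics",
    "de_martonne",
    "index_battery",
]

ETCCDI_CODES = (
    "FD", "SU", "ID", "TR", "GSL",
    "TXx", "TNx", "TXn", "TNn",
    "TN10p", "TX10p", "TN90p", "TX90p",
    "WSDI", "CSDI", "DTR",
    "Rx1day", "Rx5day", "SDII",
    "R10mm", "R20mm", "Rnnmm",
    "CDD", "CWD", "R95pTOT", "R99pTOT", "PRCPTOT",
)

AGRO_CODES = ("ET0", "SPEI", "deMartonneGottman", "UNEP_AI", "WaterBalance", "SAM")

ALL_CODES = ETCCDI_CODES + AGRO_CODES

#: Codes reported per calendar month; all others are annual.
MONTHLY_CODES = frozenset({
    "TXx", "TNx", "TXn", "TNn", "DTR", "Rx1day", "Rx5day",
    "TN10p", "TX10p", "TN90p", "TX90p",
    "ET0", "SPEI", "WaterBalance", "SAM",
})

PERCENTILE_CODES = frozenset({"TN10p", "TX10p", "TN90p", "TX90p", "WSDI", "CSDI",
                              "R95pTOT", "R99pTOT"})

#: Wet-day threshold (mm) for the precipitation indices.
INDEX_WET_MM = 1.0

_Q = dict(method="median_unbiased")


# ---------------------------------------------------------------------------
# Base-period percentiles
# ---------------------------------------------------------------------------

def _calendar_index(dates: pd.DatetimeIndex) -> np.ndarray:
    """Map each date to a 0..364 calendar-day slot; Feb 29 maps to Feb 28."""
    doy = dates.dayofyear.values.copy()
    leap = np.asarray(dates.is_leap_year)
    feb29 = leap & (dates.month.values == 2) & (dates.day.values == 29)
    after = leap & (doy > 60)  # post-Feb-29 days of leap years
    doy[after] -= 1
    doy[feb29] = 59  # Feb 28 slot (1-based doy 59)
    return doy - 1


@dataclass
class BasePeriodPercentiles:
    """Calendar-day temperature percentiles and whole-period wet-day
    precipitation percentiles from a base-period record."""

    p10_tmax: np.ndarray  # (365,)
    p90_tmax: np.ndarray
    p10_tmin: np.ndarray
    p90_tmin: np.ndarray
    wet_p95: float
    wet_p99: float
    n_base_years: int

    @classmethod
    def from_series(cls, series: DailySeries,
                    wet_threshold: float = INDEX_WET_MM) -> "BasePeriodPercentiles":
        cal = _calendar_index(series.dates)
        feb29 = (series.dates.month.values == 2) & (series.dates.day.values == 29)
        use = ~feb29  # keep 365 x n_years pooled values exactly
        by_day_tmax: list = [[] for _ in range(365)]
        by_day_tmin: list = [[] for _ in range(365)]
        for c, tx, tn in zip(cal[use], series.tmax[use], series.tmin[use]):
            by_day_tmax[c].append(tx)
            by_day_tmin[c].append(tn)
        p10x = np.empty(365)
        p90x = np.empty(365)
        p10n = np.empty(365)
        p90n = np.empty(365)
        for c in range(365):
            win = [(c + k) % 365 for k in range(-2, 3)]
            px = np.concatenate([by_day_tmax[w] for w in win])
            pn = np.concatenate([by_day_tmin[w] for w in win])
            p10x[c], p90x[c] = np.quantile(px, [0.1, 0.9], **_Q)
            p10n[c], p90n[c] = np.quantile(pn, [0.1, 0.9], **_Q)
        wet = series.prcp[series.prcp >= wet_threshold]
        if len(wet):
            w95, w99 = np.quantile(wet, [0.95, 0.99], **_Q)
        else:
            w95 = w99 = np.nan
        n_years = len(np.unique(series.years))
        return cls(p10_tmax=p10x, p90_tmax=p90x, p10_tmin=p10n, p90_tmin=p90n,
                   wet_p95=float(w95), wet_p99=float(w99), n_base_years=n_years)

    def thresholds_for(self, dates: pd.DatetimeIndex, which: str) -> np.ndarray:
        cal = _calendar_index(dates)
        return getattr(self, which)[cal]


# ---------------------------------------------------------------------------
# Run-length helpers
# ---------------------------------------------------------------------------

def _run_lengths(mask: np.ndarray) -> np.ndarray:
    """Lengths of maximal True runs."""
    if mask.size == 0:
        return np.array([], dtype=int)
    m = mask.astype(int)
    change = np.nonzero(np.diff(m))[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(m)]])
    return np.array([e - s for s, e in zip(starts, ends) if mask[s]], dtype=int)


def _max_run(mask: np.ndarray) -> int:
    runs = _run_lengths(mask)
    return int(runs.max()) if runs.size else 0


def _days_in_runs_ge(mask: np.ndarray, min_len: int = 6) -> int:
    runs = _run_lengths(mask)
    return int(runs[runs >= min_len].sum()) if runs.size else 0


# ---------------------------------------------------------------------------
# ETCCDI indices
# ---------------------------------------------------------------------------

def _rows(site, label, code, groups) -> pd.DataFrame:
    recs = [{"site": site, "series": label, "code": code,
             "year": int(y), "period": p, "value": v}
            for (y, p), v in groups]
    return pd.DataFrame.from_records(
        recs, columns=["site", "series", "code", "year", "period", "value"])


def _annual_stat(df, col_values, func):
    return [((y, "annual"), func(v)) for y, v in
            pd.Series(col_values).groupby(df["year"].values)]


def _monthly_stat(df, col_values, func):
    out = []
    for (y, m), v in pd.Series(col_values).groupby([df["year"].values,
                                                    df["month"].values]):
        out.append(((y, int(m)), func(v)))
    return out


def _gsl_one_span(tmean: np.ndarray) -> float:
    """Growing season length within one (possibly hemisphere-shifted) span:
    from the first 6-day run with Tmean > 5 degC to the first 6-day run
    with Tmean < 5 degC starting after mid-span."""
    n = len(tmean)
    warm = tmean > 5.0
    cold = tmean < 5.0
    start = None
    run = 0
    for i, w in enumerate(warm):
        run = run + 1 if w else 0
        if run >= 6:
            start = i - 5
            break
    if start is None:
        return 0.0
    mid = n // 2
    end = n
    run = 0
    for i in range(mid, n):
        run = run + 1 if cold[i] else 0
        if run >= 6:
            end = i - 5
            break
    return float(max(end - start, 0))


def _gsl(series: DailySeries, site, label) -> pd.DataFrame:
    tmean = series.tmean
    years = series.years
    out = []
    if series.latitude >= 0:
        for y in np.unique(years):
            out.append(((y, "annual"), _gsl_one_span(tmean[years == y])))
    else:
        # southern hemisphere: Jul 1 of year y to Jun 30 of year y+1
        months = series.months
        for y in np.unique(years)[:-1]:
            sel = ((years == y) & (months >= 7)) | ((years == y + 1) & (months <= 6))
            out.append(((y, "annual"), _gsl_one_span(tmean[sel])))
    return _rows(site, label, "GSL", out)


def compute_etccdi(series: DailySeries, code: str,
                   base: BasePeriodPercentiles | None = None,
                   wet_threshold: float = INDEX_WET_MM,
                   rnn_mm: float = 25.0, label: str | None = None) -> pd.DataFrame:
    """Compute one ETCCDI index as long-form index-table rows."""
    if code not in ETCCDI_CODES:
        raise ValueError(f"unknown ETCCDI code {code!r}")
    if code in PERCENTILE_CODES and base is None:
        raise ValueError(f"index {code} needs base-period percentiles")
    site = series.site_id
    label = label if label is not None else site
    df = pd.DataFrame({"year": series.years, "month": series.months})
    tx, tn, pr = series.tmax, series.tmin, series.prcp
    wet = pr >= wet_threshold

    if code == "FD":
        return _rows(site, label, code, _annual_stat(df, (tn < 0).astype(float),
                                                     lambda v: float(v.sum())))
    if code == "SU":
        return _rows(site, label, code, _annual_stat(df, (tx > 25).astype(float),
                                                     lambda v: float(v.sum())))
    if code == "ID":
        return _rows(site, label, code, _annual_stat(df, (tx < 0).astype(float),
                                                     lambda v: float(v.sum())))
    if code == "TR":
        return _rows(site, label, code, _annual_stat(df, (tn > 20).astype(float),
                                                     lambda v: float(v.sum())))
    if code == "GSL":
        return _gsl(series, site, label)
    if code in ("TXx", "TNx", "TXn", "TNn", "DTR"):
        vals = {"TXx": tx, "TNx": tn, "TXn": tx, "TNn": tn, "DTR": tx - tn}[code]
        func = {"TXx": np.max, "TNx": np.max, "TXn": np.min, "TNn": np.min,
                "DTR": np.mean}[code]
        return _rows(site, label, code,
                     _monthly_stat(df, vals, lambda v: float(func(v))))
    if code in ("TN10p", "TX10p", "TN90p", "TX90p"):
        var = tn if code.startswith("TN") else tx
        which = {"TN10p": "p10_tmin", "TX10p": "p10_tmax",
                 "TN90p": "p90_tmin", "TX90p": "p90_tmax"}[code]
        thr = base.thresholds_for(series.dates, which)
        exceed = (var < thr) if "10p" in code else (var > thr)
        return _rows(site, label, code,
                     _monthly_stat(df, exceed.astype(float),
                                   lambda v: float(100.0 * v.mean())))
    if code in ("WSDI", "CSDI"):
        if code == "WSDI":
            mask = tx > base.thresholds_for(series.dates, "p90_tmax")
        else:
            mask = tn < base.thresholds_for(series.dates, "p10_tmin")
        years = series.years
        out = [((y, "annual"), float(_days_in_runs_ge(mask[years == y], 6)))
               for y in np.unique(years)]
        return _rows(site, label, code, out)
    if code == "Rx1day":
        return _rows(site, label, code, _monthly_stat(df, pr, lambda v: float(v.max())))
    if code == "Rx5day":
        r5 = pd.Series(pr).rolling(5, min_periods=5).sum().values
        out = []
        for (y, m), v in pd.Series(r5).groupby([df["year"].values, df["month"].values]):
            vv = v.dropna()
            out.append(((y, int(m)), float(vv.max()) if len(vv) else np.nan))
        return _rows(site, label, code, out)
    if code == "SDII":
        out = []
        for y, sel in pd.Series(np.arange(len(pr))).groupby(df["year"].values):
            idx = sel.values
            w = wet[idx]
            out.append(((y, "annual"),
                        float(pr[idx][w].sum() / w.sum()) if w.sum() else np.nan))
        return _rows(site, label, code, out)
    if code in ("R10mm", "R20mm", "Rnnmm"):
        t = {"R10mm": 10.0, "R20mm": 20.0, "Rnnmm": rnn_mm}[code]
        return _rows(site, label, code, _annual_stat(df, (pr >= t).astype(float),
                                                     lambda v: float(v.sum())))
    if code in ("CDD", "CWD"):
        years = series.years
        out = []
        for y in np.unique(years):
            m = wet[years == y] if code == "CWD" else ~wet[years == y]
            out.append(((y, "annual"), float(_max_run(m))))
        return _rows(site, label, code, out)
    if code in ("R95pTOT", "R99pTOT"):
        thr = base.wet_p95 if code == "R95pTOT" else base.wet_p99
        mask = wet & (pr > thr)
        return _rows(site, label, code,
                     _annual_stat(df, np.where(mask, pr, 0.0),
                                  lambda v: float(v.sum())))
    if code == "PRCPTOT":
        return _rows(site, label, code,
                     _annual_stat(df, np.where(wet, pr, 0.0),
                                  lambda v: float(v.sum())))
    raise AssertionError(code)


# ---------------------------------------------------------------------------
# Hargreaves ET0 and extraterrestrial radiation
# ---------------------------------------------------------------------------

_GSC = 0.0820  # solar constant, MJ m-2 min-1


def extraterrestrial_radiation(latitude: float, doy: np.ndarray) -> np.ndarray:
    """Daily extraterrestrial radiation Ra (MJ m-2 day-1), FAO-56 eq. 21-25.

    Uses the solar declination, sunset-hour angle and inverse relative
    Earth-Sun distance; valid equatorward of the polar circles.
    """
    if abs(latitude) >= 66.5:
        raise ValueError(f"latitude {latitude} poleward of 66.5 deg unsupported")
    phi = np.deg2rad(latitude)
    doy = np.asarray(doy, dtype=float)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * doy / 365.0)
    delta = 0.409 * np.sin(2.0 * np.pi * doy / 365.0 - 1.39)
    ws = np.arccos(np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0))
    return (24.0 * 60.0 / np.pi) * _GSC * dr * (
        ws * np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.sin(ws))


def hargreaves_et0(tmax: np.ndarray, tmin: np.ndarray, latitude: float,
                   dates: pd.DatetimeIndex) -> np.ndarray:
    """Daily Hargreaves-Samani reference evapotranspiration (mm/day):
    ``ET0 = 0.0023 (Tmean + 17.8) sqrt(Tmax - Tmin) * 0.408 Ra``."""
    tmax = np.asarray(tmax, dtype=float)
    tmin = np.asarray(tmin, dtype=float)
    if (tmax < tmin).any():
        raise ValueError("tmax < tmin in ET0 input")
    ra = extraterrestrial_radiation(latitude, pd.DatetimeIndex(dates).dayofyear.values)
    tmean = 0.5 * (tmax + tmin)
    et0 = 0.0023 * (tmean + 17.8) * np.sqrt(tmax - tmin) * 0.408 * ra
    return np.maximum(et0, 0.0)


def _monthly_p_pet(series: DailySeries, latitude: float | None = None):
    lat = series.latitude if latitude is None else latitude
    et0 = hargreaves_et0(series.tmax, series.tmin, lat, series.dates)
    df = pd.DataFrame({"year": series.years, "month": series.months,
                       "p": series.prcp, "pet": et0, "tmean": series.tmean})
    g = df.groupby(["year", "month"], sort=True)
    out = g.agg(P=("p", "sum"), PET=("pet", "sum"), T=("tmean", "mean")).reset_index()
    return out


# ---------------------------------------------------------------------------
# SPEI
# ---------------------------------------------------------------------------

# rational normal-quantile approximation constants
_C0, _C1, _C2 = 2.515517, 0.802853, 0.010328
_D1, _D2, _D3 = 1.432788, 0.189269, 0.001308


def _pwm(x: np.ndarray):
    """Unbiased probability-weighted moments b0, b1, b2."""
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    i = np.arange(1, n + 1)
    b0 = x.mean()
    b1 = np.sum((i - 1) / (n - 1) * x) / n
    b2 = np.sum((i - 1) * (i - 2) / ((n - 1) * (n - 2)) * x) / n
    return b0, b1, b2


def _loglogistic_fit(x: np.ndarray):
    """3-parameter log-logistic (alpha scale, beta shape, gamma origin) by
    unbiased PWMs; returns None on a degenerate fit."""
    if len(np.unique(x)) < 4:
        return None
    b0, b1, b2 = _pwm(x)
    # reverse-order moments w_s = E[X (1-F)^s] from the b_s = E[X F^s]
    w0, w1, w2 = b0, b0 - b1, b0 - 2.0 * b1 + b2
    den = 6.0 * w1 - w0 - 6.0 * w2
    if den == 0:
        return None
    beta = (2.0 * w1 - w0) / den
    if not np.isfinite(beta) or beta <= 1.0:
        return None
    g = _gamma_fn(1.0 + 1.0 / beta) * _gamma_fn(1.0 - 1.0 / beta)
    alpha = (w0 - 2.0 * w1) * beta / g
    if not np.isfinite(alpha) or alpha <= 0:
        return None
    gam = w0 - alpha * g
    return alpha, beta, gam


def _std_normal_from_prob(p_ex: np.ndarray) -> np.ndarray:
    """Standardize an exceedance probability via the rational approximation."""
    p_ex = np.clip(p_ex, 1e-8, 1.0 - 1e-8)
    z = np.empty_like(p_ex)
    lower = p_ex <= 0.5
    for sel, p, sign in ((lower, p_ex, 1.0), (~lower, 1.0 - p_ex, -1.0)):
        if not sel.any():
            continue
        w = np.sqrt(-2.0 * np.log(p[sel]))
        z[sel] = sign * (w - (_C0 + _C1 * w + _C2 * w ** 2)
                         / (1.0 + _D1 * w + _D2 * w ** 2 + _D3 * w ** 3))
    return z


def spei(series: DailySeries, latitude: float | None = None, scale: int = 3,
         label: str | None = None) -> pd.DataFrame:
    """Standardized precipitation-evapotranspiration index at a monthly
    time scale.

    The monthly climatic balance D = P - PET (PET = monthly-summed
    Hargreaves ET0) is aggregated over ``scale``-month rolling windows, a
    3-parameter log-logistic law is fitted per calendar month by unbiased
    probability-weighted moments, and probabilities are mapped to standard
    normal deviates.  The first ``scale - 1`` months are undefined and not
    reported; a calendar month whose fit degenerates yields NaN rows.
    """
    mp = _monthly_p_pet(series, latitude)
    n_years = len(np.unique(mp["year"]))
    if n_years < 20:
        import warnings
        warnings.warn(f"SPEI fitted on {n_years} years; PWM fits are unstable "
                      "below ~20 years", stacklevel=2)
    d = (mp["P"] - mp["PET"]).to_numpy()
    dk = pd.Series(d).rolling(scale, min_periods=scale).sum().to_numpy()
    z = np.full(len(dk), np.nan)
    months = mp["month"].to_numpy()
    for m in range(1, 13):
        sel = (months == m) & ~np.isnan(dk)
        x = dk[sel]
        if len(x) == 0:
            continue
        fit = _loglogistic_fit(x)
        if fit is not None:
            alpha, beta, gam = fit
            xc = x - gam
            F = np.where(xc > 0,
                         1.0 / (1.0 + (alpha / np.maximum(xc, 1e-12)) ** beta), 0.0)
        else:
            # left-skewed sample: fit the mirrored variable, F(x) = 1 - F~(-x)
            fit = _loglogistic_fit(-x)
            if fit is None:
                continue
            alpha, beta, gam = fit
            xc = -x - gam
            F = 1.0 - np.where(
                xc > 0, 1.0 / (1.0 + (alpha / np.maximum(xc, 1e-12)) ** beta), 0.0)
        z[sel] = _std_normal_from_prob(1.0 - F)
    out = mp[["year", "month"]].copy()
    out.insert(0, "site", series.site_id)
    out.insert(1, "series", label if label is not None else series.site_id)
    out.insert(2, "code", "SPEI")
    out = out.rename(columns={"month": "period"})
    out["value"] = z
    return out[~np.isnan(dk)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Aridity metrics
# ---------------------------------------------------------------------------

def de_martonne(p_annual: float, t_annual: float) -> float:
    """Classical de Martonne aridity index I = P / (T + 10)."""
    if t_annual <= -10.0:
        return np.nan
    return p_annual / (t_annual + 10.0)


def aridity_metrics(series: DailySeries, latitude: float | None = None,
                    label: str | None = None) -> pd.DataFrame:
    """Annual de Martonne-Gottman and UNEP aridity indices; monthly water
    balance (P - PET) and simple aridity measure (SAM = P/PET)."""
    site = series.site_id
    label = label if label is not None else site
    mp = _monthly_p_pet(series, latitude)
    rows = []
    for y, grp in mp.groupby("year"):
        if len(grp) < 12:
            continue  # incomplete calendar year
        p_ann = grp["P"].sum()
        t_ann = grp["T"].mean()
        pet_ann = grp["PET"].sum()
        i_dm = de_martonne(p_ann, t_ann)
        dri = grp["P"].idxmin()
        p_dri, t_dri = grp.loc[dri, "P"], grp.loc[dri, "T"]
        if np.isnan(i_dm) or t_dri <= -10.0:
            i_dmg = np.nan
        else:
            i_dmg = 0.5 * (i_dm + 12.0 * p_dri / (t_dri + 10.0))
        rows.append({"site": site, "series": label, "code": "deMartonneGottman",
                     "year": int(y), "period": "annual", "value": float(i_dmg)})
        rows.append({"site": site, "series": label, "code": "UNEP_AI",
                     "year": int(y), "period": "annual",
                     "value": float(p_ann / pet_ann) if pet_ann > 0 else np.nan})
    for _, r in mp.iterrows():
        rows.append({"site": site, "series": label, "code": "WaterBalance",
                     "year": int(r["year"]), "period": int(r["month"]),
                     "value": float(r["P"] - r["PET"])})
        rows.append({"site": site, "series": label, "code": "SAM",
                     "year": int(r["year"]), "period": int(r["month"]),
                     "value": float(r["P"] / r["PET"]) if r["PET"] > 0 else np.nan})
    return pd.DataFrame.from_records(
        rows, columns=["site", "series", "code", "year", "period", "value"])


def _et0_monthly(series: DailySeries, latitude: float | None = None,
                 label: str | None = None) -> pd.DataFrame:
    mp = _monthly_p_pet(series, latitude)
    out = mp[["year", "month"]].copy()
    out.insert(0, "site", series.site_id)
    out.insert(1, "series", label if label is not None else series.site_id)
    out.insert(2, "code", "ET0")
    out = out.rename(columns={"month": "period"})
    out["value"] = mp["PET"].to_numpy()
    return out


# ---------------------------------------------------------------------------
# Battery
# ---------------------------------------------------------------------------

def index_battery(series: DailySeries, base: BasePeriodPercentiles | None = None,
                  codes=None, wet_threshold: float = INDEX_WET_MM,
                  rnn_mm: float = 25.0, spei_scale: int = 3,
                  label: str | None = None) -> pd.DataFrame:
    """Compute the full 33-code battery (or a subset) for one series.

    ``base`` defaults to percentiles computed from the series itself; when
    comparing a generated series against a reference, pass the reference's
    base so both sides use identical thresholds.
    """
    codes = tuple(codes) if codes is not None else ALL_CODES
    if base is None and any(c in PERCENTILE_CODES for c in codes):
        base = BasePeriodPercentiles.from_series(series, wet_threshold)
    parts = []
    for code in codes:
        if code in ETCCDI_CODES:
            parts.append(compute_etccdi(series, code, base, wet_threshold,
                                        rnn_mm, label))
        elif code == "ET0":
            parts.append(_et0_monthly(series, label=label))
        elif code == "SPEI":
            parts.append(spei(series, scale=spei_scale, label=label))
        elif code in ("deMartonneGottman", "UNEP_AI", "WaterBalance", "SAM"):
            continue  # computed in one pass below
        else:
            raise ValueError(f"unknown index code {code!r}")
    wanted_arid = [c for c in codes
                   if c in ("deMartonneGottman", "UNEP_AI", "WaterBalance", "SAM")]
    if wanted_arid:
        arid = aridity_metrics(series, label=label)
        parts.append(arid[arid["code"].isin(wanted_arid)])
    out = pd.concat(parts, ignore_index=True)
    return out
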