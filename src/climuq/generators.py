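"""Stochastic weather generators.

Two structurally different single-site generators are provided, standing in
for the main families in use:

* :class:`ParametricWG` ("PWG") — the WGEN-type parametric family:
  first-order two-state Markov chain for precipitation occurrence per
  calendar month, gamma-distributed wet-day amounts, and wet/dry-state
  conditioned daily temperatures whose standardized residuals follow a
  Matalas lag-1 bivariate autoregression.
* :class:`SemiEmpiricalWG` ("SEWG") — the LARS-WG-type semi-empirical
  family: seasonal wet/dry spell-length histograms, monthly empirical
  quantile tables for wet-day amounts, and month-by-state temperature
  normals with lag-1 autocorrelated residuals.

A third generator level used by the factorial analyses, ``pwg_noac``, is
the parametric generator with the temperature autoregression switched off
(propagation matrix A = 0), giving three structurally distinct generators.

Calibration follows the statsmodels convention: a model object is built
from data and ``fit()`` returns a results object that carries the fitted
parameters and exposes ``generate`` and ``summary``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .core import DailySeries, WET_THRESHOLD_MM, wet_mask

__all__ = [
    "GenerationFailure",
    "PWGParams",
    "SEWGParams",
    "ParametricWG",
    "SemiEmpiricalWG",
    "WGResults",
    "fit_markov",
    "fit_gamma",
    "fit_temperature",
    "pwg_generate",
    "sewg_fit",
    "sewg_generate",
    "WG_NAMES",
]

#: Generator levels used in the factorial experiment.
WG_NAMES = ("pwg", "sewg", "pwg_noac")

SEASON_OF_MONTH = {12: "DJF", 1: "DJF", 2: "DJF", 3: "MAM", 4: "MAM", 5: "MAM",
                   6: "JJA", 7: "JJA", 8: "JJA", 9: "SON", 10: "SON", 11: "SON"}
SEASONS = ("DJF", "MAM", "JJA", "SON")

_EIG_FLOOR = 1e-8


class GenerationFailure(RuntimeError):
    """A generator cannot produce a series because calibration left
    undefined parameter cells.  The failure is a first-class outcome:
    the pipeline records it and the balance rules act on it."""

    def __init__(self, cells):
        self.cells = list(cells)
        super().__init__(f"cannot generate: undefined parameter cells {self.cells}")


# ---------------------------------------------------------------------------
# Parametric generator (Markov / gamma / lag-1 bivariate temperature)
# ---------------------------------------------------------------------------


@dataclass
class PWGParams:
    """Fitted parameters of the parametric generator.

    Monthly arrays are indexed 0..11 (January..December); state axes are
    ordered (dry, wet).  ``M0`` and ``M1`` are the lag-0 and lag-1
    correlation matrices of the standardized (tmax, tmin) residual vector;
    the propagation matrix ``A = M1 M0^-1`` and innovation factor ``B``
    with ``B B' = M0 - M1 M0^-1 M1'`` are derived on demand.  Undefined
    cells (insufficient data, degenerate amounts) are NaN, never silent
    zeros.
    """

    p01: np.ndarray
    p11: np.ndarray
    gamma_shape: np.ndarray
    gamma_scale: np.ndarray
    mean_tmax: np.ndarray  # (12, 2): dry, wet
    mean_tmin: np.ndarray
    sd_tmax: np.ndarray
    sd_tmin: np.ndarray
    M0: np.ndarray
    M1: np.ndarray

    def __post_init__(self):
        # defensive copies: parameter sets must never alias caller arrays
        for name in ("p01", "p11", "gamma_shape", "gamma_scale"):
            setattr(self, name, np.array(getattr(self, name), dtype=float))
        for name in ("mean_tmax", "mean_tmin", "sd_tmax", "sd_tmin"):
            arr = np.array(getattr(self, name), dtype=float)
            if arr.ndim == 1:  # state-invariant specification
                arr = np.column_stack([arr, arr])
            setattr(self, name, arr)
        self.M0 = np.array(self.M0, dtype=float)
        self.M1 = np.array(self.M1, dtype=float)

    # -- derived autoregression matrices --------------------------------

    @property
    def A(self) -> np.ndarray:
        return self.M1 @ np.linalg.inv(self.M0)

    @property
    def B(self) -> np.ndarray:
        bbt = self.M0 - self.M1 @ np.linalg.inv(self.M0) @ self.M1.T
        bbt = 0.5 * (bbt + bbt.T)
        w, v = np.linalg.eigh(bbt)
        w = np.maximum(w, _EIG_FLOOR)  # floor sampling-noise negatives
        return v @ np.diag(np.sqrt(w))

    def undefined_cells(self) -> list[str]:
        cells = []
        for name in ("p01", "p11", "gamma_shape", "gamma_scale",
                     "mean_tmax", "mean_tmin", "sd_tmax", "sd_tmin"):
            arr = getattr(self, name)
            bad = np.argwhere(np.isnan(arr))
            for idx in bad:
                cells.append(f"{name}[{','.join(str(i) for i in idx)}]")
        if np.isnan(self.M0).any() or np.isnan(self.M1).any():
            cells.append("residual_correlations")
        return cells

    def without_temperature_autocorrelation(self) -> "PWGParams":
        """The 'pwg_noac' variant: A forced to zero (M1 = 0), so daily
        temperature residuals are serially independent."""
        return replace(self, M1=np.zeros((2, 2)))

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {k: np.asarray(getattr(self, k)).tolist()
                for k in ("p01", "p11", "gamma_shape", "gamma_scale",
                          "mean_tmax", "mean_tmin", "sd_tmax", "sd_tmin",
                          "M0", "M1")}

    @classmethod
    def from_dict(cls, d: dict) -> "PWGParams":
        return cls(**{k: np.asarray(v, dtype=float) for k, v in d.items()})

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "PWGParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def fit_markov(series: DailySeries, threshold: float = WET_THRESHOLD_MM):
    """Monthly first-order Markov occurrence probabilities.

    A transition is attributed to the calendar month of its *second* day.
    ``p01[m]`` is the wet-after-dry probability, ``p11[m]`` wet-after-wet.
    Months with no eligible transitions get NaN, never a silent zero.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 days to fit a Markov chain")
    wet = wet_mask(series, threshold)
    prev, cur = wet[:-1], wet[1:]
    month = series.months[1:] - 1
    p01 = np.full(12, np.nan)
    p11 = np.full(12, np.nan)
    for m in range(12):
        sel = month == m
        n0 = np.sum(sel & ~prev)
        n1 = np.sum(sel & prev)
        if n0 > 0:
            p01[m] = np.sum(sel & ~prev & cur) / n0
        if n1 > 0:
            p11[m] = np.sum(sel & prev & cur) / n1
    return p01, p11


def fit_gamma(series: DailySeries, threshold: float = WET_THRESHOLD_MM,
              min_wet_days: int = 5):
    """Monthly gamma wet-day amount parameters by the Thom closed-form
    maximum-likelihood approximation.

    With sample statistic ``s = ln(mean) - mean(ln)`` over wet-day amounts
    of a calendar month, ``shape = (1 + sqrt(1 + 4 s / 3)) / (4 s)`` and
    ``scale = mean / shape``.  Months with fewer than ``min_wet_days`` wet
    days, or with degenerate (all-equal) amounts (s -> 0), yield NaN.
    """
    wet = wet_mask(series, threshold)
    month = series.months - 1
    shape = np.full(12, np.nan)
    scale = np.full(12, np.nan)
    for m in range(12):
        x = series.prcp[wet & (month == m)]
        if len(x) < min_wet_days:
            continue
        mean = x.mean()
        s = np.log(mean) - np.mean(np.log(x))
        if s <= 1e-12:  # degenerate amounts
            continue
        a = (1.0 + np.sqrt(1.0 + 4.0 * s / 3.0)) / (4.0 * s)
        shape[m] = a
        scale[m] = mean / a
    return shape, scale


def fit_temperature(series: DailySeries, threshold: float = WET_THRESHOLD_MM,
                    min_cell_days: int = 10):
    """State-conditioned temperature normals and the Matalas lag-1 residual
    structure.

    Returns the dict of arrays that fills the temperature block of
    :class:`PWGParams`: per month x (dry, wet) means and standard
    deviations, and the lag-0 / lag-1 correlation matrices M0, M1 of the
    standardized (tmax, tmin) residual pair.
    """
    wet = wet_mask(series, threshold).astype(int)
    month = series.months - 1
    shape = (12, 2)
    out = {k: np.full(shape, np.nan)
           for k in ("mean_tmax", "mean_tmin", "sd_tmax", "sd_tmin")}
    for m in range(12):
        for s in (0, 1):
            sel = (month == m) & (wet == s)
            if sel.sum() < min_cell_days:
                continue
            for var, key in ((series.tmax, "tmax"), (series.tmin, "tmin")):
                x = var[sel]
                sd = x.std(ddof=1)
                out[f"mean_{key}"][m, s] = x.mean()
                out[f"sd_{key}"][m, s] = sd if sd > 0 else np.nan
    # standardized residuals over the full record
    rx = np.full(len(series), np.nan)
    rn = np.full(len(series), np.nan)
    for m in range(12):
        for s in (0, 1):
            sel = (month == m) & (wet == s)
            if np.isnan(out["mean_tmax"][m, s]) or np.isnan(out["mean_tmin"][m, s]):
                continue
            rx[sel] = (series.tmax[sel] - out["mean_tmax"][m, s]) / out["sd_tmax"][m, s]
            rn[sel] = (series.tmin[sel] - out["mean_tmin"][m, s]) / out["sd_tmin"][m, s]
    ok = ~(np.isnan(rx) | np.isnan(rn))
    if ok.sum() < 2 * min_cell_days:
        return {**out, "M0": np.full((2, 2), np.nan), "M1": np.full((2, 2), np.nan)}
    z = np.column_stack([rx, rn])
    zok = z[ok]
    M0 = np.corrcoef(zok.T)
    cond = np.linalg.cond(M0)
    if cond > 1e8:
        raise np.linalg.LinAlgError(
            f"singular lag-0 residual correlation matrix (condition number {cond:.3g})")
    lagpair = ok[1:] & ok[:-1]
    zc, zp = z[1:][lagpair], z[:-1][lagpair]
    M1 = (zc.T @ zp) / len(zc)
    return {**out, "M0": M0, "M1": M1}


def _fit_pwg(series: DailySeries, threshold: float = WET_THRESHOLD_MM) -> PWGParams:
    p01, p11 = fit_markov(series, threshold)
    shape, scale = fit_gamma(series, threshold)
    temp = fit_temperature(series, threshold)
    return PWGParams(p01=p01, p11=p11, gamma_shape=shape, gamma_scale=scale, **temp)


def pwg_generate(params: PWGParams, latitude: float, n_years: int, seed: int,
                 site_id: str = "pwg", start_year: int = 2001,
                 wet_threshold: float = WET_THRESHOLD_MM,
                 burn_in_days: int = 30) -> DailySeries:
    """Generate a daily series from fitted parametric-generator parameters.

    The chain starts dry with zero temperature residual; the first
    ``burn_in_days`` days are discarded.  Amounts below the wet threshold
    are raised to it so that a generated wet day is wet under the same
    threshold used for calibration.  Raises :class:`GenerationFailure`
    naming the undefined cells if calibration was incomplete.
    """
    cells = params.undefined_cells()
    if cells:
        raise GenerationFailure(cells)
    dates = pd.date_range(f"{start_year}-01-01", f"{start_year + n_years - 1}-12-31",
                          freq="D", unit="s")
    full = pd.date_range(dates[0] - pd.Timedelta(days=burn_in_days),
                         periods=burn_in_days + len(dates), freq="D", unit="s")
    months = full.month.values - 1
    n = len(full)
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    eps = rng.standard_normal((n, 2))
    A, B = params.A, params.B
    a00, a01, a10, a11 = A[0, 0], A[0, 1], A[1, 0], A[1, 1]
    b00, b01, b10, b11 = B[0, 0], B[0, 1], B[1, 0], B[1, 1]
    p01, p11 = params.p01, params.p11
    gsh, gsc = params.gamma_shape, params.gamma_scale
    mtx, mtn = params.mean_tmax, params.mean_tmin
    stx, stn = params.sd_tmax, params.sd_tmin
    prcp = np.zeros(n)
    tmax = np.empty(n)
    tmin = np.empty(n)
    state = 0
    z0 = z1 = 0.0
    for i in range(n):
        m = months[i]
        p = p11[m] if state else p01[m]
        state = 1 if u[i] < p else 0
        if state:
            prcp[i] = max(rng.gamma(gsh[m]) * gsc[m], wet_threshold)
        e0, e1 = eps[i]
        z0, z1 = (a00 * z0 + a01 * z1 + b00 * e0 + b01 * e1,
                  a10 * z0 + a11 * z1 + b10 * e0 + b11 * e1)
        tx = mtx[m, state] + stx[m, state] * z0
        tn = mtn[m, state] + stn[m, state] * z1
        if tx < tn:
            tx, tn = tn, tx
        tmax[i] = tx
        tmin[i] = tn
    k = burn_in_days
    return DailySeries(site_id=site_id, latitude=latitude, dates=dates,
                       tmax=tmax[k:], tmin=tmin[k:], prcp=prcp[k:])


# ---------------------------------------------------------------------------
# Semi-empirical generator (spell histograms / quantile tables)
# ---------------------------------------------------------------------------


@dataclass
class SEWGParams:
    """Fitted parameters of the semi-empirical generator.

    ``spells[season][kind]`` maps a season label (DJF/MAM/JJA/SON) and kind
    ('wet'/'dry') to a fixed-bin-count histogram (integer bin edges,
    proportions); seasons with too few observed spells map to None.  ``amount_quantiles[m]`` is the sorted
    wet-day amount sample of calendar month m (the empirical quantile
    table; possibly empty).  Temperature blocks mirror the parametric
    generator but the residual model is an independent lag-1
    autoregression per variable.
    """

    spells: dict
    amount_quantiles: list
    mean_tmax: np.ndarray
    mean_tmin: np.ndarray
    sd_tmax: np.ndarray
    sd_tmin: np.ndarray
    ar1_tmax: float
    ar1_tmin: float

    def undefined_cells(self) -> list[str]:
        cells = []
        for season in SEASONS:
            for kind in ("wet", "dry"):
                if self.spells.get(season, {}).get(kind) is None:
                    cells.append(f"spells[{season}][{kind}]")
        for m in range(12):
            if len(self.amount_quantiles[m]) == 0:
                cells.append(f"amount_quantiles[{m}]")
        for name in ("mean_tmax", "mean_tmin", "sd_tmax", "sd_tmin"):
            for idx in np.argwhere(np.isnan(getattr(self, name))):
                cells.append(f"{name}[{','.join(str(i) for i in idx)}]")
        if np.isnan(self.ar1_tmax) or np.isnan(self.ar1_tmin):
            cells.append("ar1")
        return cells

    def to_dict(self) -> dict:
        return {
            "spells": {s: {k: None if v is None else
                           {"edges": v[0].tolist(), "props": v[1].tolist()}
                           for k, v in kinds.items()}
                       for s, kinds in self.spells.items()},
            "amount_quantiles": [np.asarray(q).tolist() for q in self.amount_quantiles],
            "mean_tmax": self.mean_tmax.tolist(),
            "mean_tmin": self.mean_tmin.tolist(),
            "sd_tmax": self.sd_tmax.tolist(),
            "sd_tmin": self.sd_tmin.tolist(),
            "ar1_tmax": float(self.ar1_tmax),
            "ar1_tmin": float(self.ar1_tmin),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SEWGParams":
        spells = {s: {k: None if v is None else
                      (np.asarray(v["edges"], dtype=int), np.asarray(v["props"]))
                      for k, v in kinds.items()}
                  for s, kinds in d["spells"].items()}
        return cls(spells=spells,
                   amount_quantiles=[np.asarray(q, dtype=float)
                                     for q in d["amount_quantiles"]],
                   mean_tmax=np.asarray(d["mean_tmax"]),
                   mean_tmin=np.asarray(d["mean_tmin"]),
                   sd_tmax=np.asarray(d["sd_tmax"]),
                   sd_tmin=np.asarray(d["sd_tmin"]),
                   ar1_tmax=d["ar1_tmax"], ar1_tmin=d["ar1_tmin"])

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "SEWGParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _spell_table(series: DailySeries, threshold: float):
    """(kind, season, length) for every maximal wet/dry run; season taken
    from the spell's first day."""
    wet = wet_mask(series, threshold)
    months = series.months
    change = np.nonzero(np.diff(wet.astype(int)))[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(wet)]])
    rows = []
    for s, e in zip(starts, ends):
        rows.append(("wet" if wet[s] else "dry",
                     SEASON_OF_MONTH[int(months[s])], e - s))
    return rows


#: Number of spell-length histogram bins (the semi-empirical family uses a
#: fixed, fairly coarse bin count; lengths are drawn uniformly within a bin).
SPELL_BINS = 10


def _spell_histogram(lens: np.ndarray, n_bins: int = SPELL_BINS):
    """Fixed-bin-count spell-length histogram: integer bin edges spanning
    [1, max length + 1), proportions per bin."""
    lmax = int(lens.max())
    edges = np.unique(np.linspace(1, lmax + 1, min(n_bins, lmax) + 1)
                      .round().astype(int))
    counts, _ = np.histogram(lens, bins=edges)
    return edges, counts / counts.sum()


def sewg_fit(series: DailySeries, threshold: float = WET_THRESHOLD_MM,
             min_spells: int = 5, min_cell_days: int = 10,
             n_bins: int = SPELL_BINS) -> SEWGParams:
    """Calibrate the semi-empirical generator."""
    rows = _spell_table(series, threshold)
    spells: dict = {s: {} for s in SEASONS}
    for season in SEASONS:
        for kind in ("wet", "dry"):
            lens = np.array([l for k, s, l in rows if k == kind and s == season])
            if len(lens) < min_spells:
                spells[season][kind] = None
                continue
            spells[season][kind] = _spell_histogram(lens, n_bins)
    wet = wet_mask(series, threshold)
    month = series.months - 1
    amount_quantiles = [np.sort(series.prcp[wet & (month == m)]) for m in range(12)]
    temp = fit_temperature(series, threshold, min_cell_days)
    # independent lag-1 autocorrelation per standardized temperature variable
    M1 = temp.pop("M1")
    temp.pop("M0")
    return SEWGParams(spells=spells, amount_quantiles=amount_quantiles,
                      ar1_tmax=float(M1[0, 0]), ar1_tmin=float(M1[1, 1]), **temp)


def sewg_generate(params: SEWGParams, latitude: float, n_years: int, seed: int,
                  site_id: str = "sewg", start_year: int = 2001,
                  wet_threshold: float = WET_THRESHOLD_MM) -> DailySeries:
    """Generate a daily series by alternating sampled dry and wet spells.

    Spell lengths are drawn from the seasonal histogram of the season the
    spell starts in (support capped at the longest observed spell by
    construction); wet amounts by inverse-CDF interpolation of the monthly
    quantile table; temperatures from month-by-state normals with lag-1
    autocorrelated residuals.
    """
    cells = params.undefined_cells()
    if cells:
        raise GenerationFailure(cells)
    dates = pd.date_range(f"{start_year}-01-01", f"{start_year + n_years - 1}-12-31",
                          freq="D", unit="s")
    months = dates.month.values - 1
    n = len(dates)
    rng = np.random.default_rng(seed)
    wet = np.zeros(n, dtype=bool)
    i = 0
    kind = "dry"
    while i < n:
        season = SEASON_OF_MONTH[int(months[i]) + 1]
        edges, props = params.spells[season][kind]
        k = int(rng.choice(len(props), p=props))
        L = int(rng.integers(edges[k], edges[k + 1]))
        L = min(L, n - i)
        if kind == "wet":
            wet[i:i + L] = True
        i += L
        kind = "wet" if kind == "dry" else "dry"
    prcp = np.zeros(n)
    for m in range(12):
        sel = wet & (months == m)
        k = int(sel.sum())
        if k == 0:
            continue
        q = params.amount_quantiles[m]
        u = rng.random(k)
        if len(q) == 1:
            vals = np.full(k, q[0])
        else:
            vals = np.interp(u * (len(q) - 1), np.arange(len(q)), q)
        prcp[sel] = np.maximum(vals, 0.0)
    # temperatures
    eps_x = rng.standard_normal(n)
    eps_n = rng.standard_normal(n)
    phix, phin = params.ar1_tmax, params.ar1_tmin
    sx = np.sqrt(max(1.0 - phix ** 2, 0.0))
    sn = np.sqrt(max(1.0 - phin ** 2, 0.0))
    tmax = np.empty(n)
    tmin = np.empty(n)
    rx = rn = 0.0
    st = wet.astype(int)
    for i in range(n):
        m = months[i]
        rx = phix * rx + sx * eps_x[i]
        rn = phin * rn + sn * eps_n[i]
        tx = params.mean_tmax[m, st[i]] + params.sd_tmax[m, st[i]] * rx
        tn = params.mean_tmin[m, st[i]] + params.sd_tmin[m, st[i]] * rn
        if tx < tn:
            tx, tn = tn, tx
        tmax[i] = tx
        tmin[i] = tn
    return DailySeries(site_id=site_id, latitude=latitude, dates=dates,
                       tmax=tmax, tmin=tmin, prcp=prcp)


# ---------------------------------------------------------------------------
# Model / Results surface
# ---------------------------------------------------------------------------


@dataclass
class WGResults:
    """Calibration results: fitted parameters plus a generate method."""

    model: object
    params: object
    series: DailySeries = field(repr=False)

    @property
    def wg_name(self) -> str:
        return self.model.name

    def generate(self, n_years: int, seed: int, site_id: str | None = None,
                 start_year: int = 2001) -> DailySeries:
        label = site_id or f"{self.series.site_id}:{self.wg_name}"
        if isinstance(self.params, PWGParams):
            return pwg_generate(self.params, self.series.latitude, n_years, seed,
                                site_id=label, start_year=start_year,
                                wet_threshold=self.model.wet_threshold)
        return sewg_generate(self.params, self.series.latitude, n_years, seed,
                             site_id=label, start_year=start_year,
                             wet_threshold=self.model.wet_threshold)

    def summary(self) -> str:
        buf = io.StringIO()
        buf.write(f"Weather generator calibration [{self.wg_name}]\n")
        buf.write(f"site: {self.series.site_id}  days: {len(self.series)}\n")
        cells = self.params.undefined_cells()
        buf.write(f"undefined parameter cells: {len(cells)}\n")
        if isinstance(self.params, PWGParams):
            df = pd.DataFrame({
                "p01": self.params.p01, "p11": self.params.p11,
                "gamma_shape": self.params.gamma_shape,
                "gamma_scale": self.params.gamma_scale,
                "mean_tmax_dry": self.params.mean_tmax[:, 0],
                "mean_tmax_wet": self.params.mean_tmax[:, 1],
            }, index=pd.Index(range(1, 13), name="month"))
            buf.write(df.round(3).to_string())
            buf.write(f"\nA = {np.round(self.params.A, 3).tolist()}\n")
        else:
            for season in SEASONS:
                for kind in ("wet", "dry"):
                    h = self.params.spells[season][kind]
                    desc = "undefined" if h is None else f"{len(h[1])} bins"
                    buf.write(f"spells[{season}][{kind}]: {desc}\n")
        return buf.getvalue()


class ParametricWG:
    """Markov/gamma/AR(1) parametric weather generator model.

    Parameters
    ----------
    series : DailySeries
        Calibration record.
    wet_threshold : float
        Wet-day threshold in mm (default 0.1).
    temperature_autocorrelation : bool
        If False, the fitted lag-1 matrix is zeroed ('pwg_noac' level).
    """

    def __init__(self, series: DailySeries, wet_threshold: float = WET_THRESHOLD_MM,
                 temperature_autocorrelation: bool = True):
        self.series = series
        self.wet_threshold = wet_threshold
        self.temperature_autocorrelation = temperature_autocorrelation

    @property
    def name(self) -> str:
        return "pwg" if self.temperature_autocorrelation else "pwg_noac"

    def fit(self) -> WGResults:
        params = _fit_pwg(self.series, self.wet_threshold)
        if not self.temperature_autocorrelation:
            params = params.without_temperature_autocorrelation()
        return WGResults(model=self, params=params, series=self.series)


class SemiEmpiricalWG:
    """Spell-length / empirical-quantile semi-empirical generator model."""

    name = "sewg"

    def __init__(self, series: DailySeries, wet_threshold: float = WET_THRESHOLD_MM):
        self.series = series
        self.wet_threshold = wet_threshold

    def fit(self) -> WGResults:
        params = sewg_fit(self.series, self.wet_threshold)
        return WGResults(model=self, params=params, series=self.series)


def make_wg(name: str, series: DailySeries,
            wet_threshold: float = WET_THRESHOLD_MM):
    """Factory for the three generator levels by name."""
    if name == "pwg":
        return ParametricWG(series, wet_threshold)
    if name == "pwg_noac":
        return ParametricWG(series, wet_threshold, temperature_autocorrelation=False)
    if name == "sewg":
        return SemiEmpiricalWG(series, wet_threshold)
    raise ValueError(f"unknown weather generator {name!r}; expected one of {WG_NAMES}")
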