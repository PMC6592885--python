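"""Synthetic reference climates and plausible change-factor tables.

Real multi-decadal station records and per-site GCM change factors are not
needed to exercise the pipeline: this module provides site archetypes with
known "truth" parameters (the same parametric family the parametric
generator fits, so parameter recovery is well posed) and scenario
archetypes emulating moderate- and high-forcing pathway change factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from zlib import crc32

from .core import DailySeries
from .generators import PWGParams, pwg_generate

__all__ = [
    "TruthParams",
    "ScenarioSpec",
    "SITE_PRESETS",
    "SCENARIO_PRESETS",
    "make_truth",
    "simulate_series",
    "make_change_factors",
    "read_change_factors_csv",
    "write_change_factors_csv",
]

_MONTHS = np.arange(12)


@dataclass
class TruthParams:
    """Known generative parameters of a synthetic site.

    Monthly arrays indexed 0..11.  Temperature means are conditioned on the
    day's wet/dry state; standard deviations are state-invariant.  The
    residual structure is summarized by the contemporaneous correlation
    ``lag0_corr`` between the tmax and tmin residuals and the lag-1
    autocorrelations of each.
    """

    latitude: float
    p01: np.ndarray
    p11: np.ndarray
    gamma_shape: np.ndarray
    gamma_scale: np.ndarray
    mean_tmax: np.ndarray  # (12, 2): dry, wet
    mean_tmin: np.ndarray
    sd_tmax: np.ndarray  # (12,)
    sd_tmin: np.ndarray
    lag0_corr: float
    lag1_corr_tmax: float
    lag1_corr_tmin: float

    def __post_init__(self):
        for name in ("p01", "p11", "gamma_shape", "gamma_scale",
                     "mean_tmax", "mean_tmin", "sd_tmax", "sd_tmin"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.validate()

    def validate(self) -> None:
        if not (((self.p01 >= 0) & (self.p01 <= 1)).all()
                and ((self.p11 >= 0) & (self.p11 <= 1)).all()):
            raise ValueError("occurrence probabilities must lie in [0, 1]")
        if (self.gamma_shape <= 0).any() or (self.gamma_scale <= 0).any():
            raise ValueError("gamma parameters must be positive")
        if (self.sd_tmax <= 0).any() or (self.sd_tmin <= 0).any():
            raise ValueError("temperature standard deviations must be positive")
        if (self.mean_tmax < self.mean_tmin).any():
            raise ValueError("mean_tmax must be >= mean_tmin in every month/state")
        for r in (self.lag0_corr, self.lag1_corr_tmax, self.lag1_corr_tmin):
            if not -1.0 < r < 1.0:
                raise ValueError("correlations must lie in (-1, 1)")
        # implied innovation covariance must be PSD
        w = np.linalg.eigvalsh(self._bbt())
        if (w < -1e-10).any():
            raise ValueError("implied innovation covariance not positive semi-definite")

    def _m0m1(self):
        r0 = self.lag0_corr
        r1x, r1n = self.lag1_corr_tmax, self.lag1_corr_tmin
        M0 = np.array([[1.0, r0], [r0, 1.0]])
        c = r0 * np.sqrt(abs(r1x * r1n)) * np.sign(r1x * r1n or 1.0)
        M1 = np.array([[r1x, c], [c, r1n]])
        return M0, M1

    def _bbt(self):
        M0, M1 = self._m0m1()
        return M0 - M1 @ np.linalg.inv(M0) @ M1.T

    def to_pwg(self) -> PWGParams:
        """The equivalent parametric-generator parameter set."""
        M0, M1 = self._m0m1()
        return PWGParams(
            p01=self.p01, p11=self.p11,
            gamma_shape=self.gamma_shape, gamma_scale=self.gamma_scale,
            mean_tmax=self.mean_tmax, mean_tmin=self.mean_tmin,
            sd_tmax=np.column_stack([self.sd_tmax, self.sd_tmax]),
            sd_tmin=np.column_stack([self.sd_tmin, self.sd_tmin]),
            M0=M0, M1=M1,
        )

    def to_dict(self) -> dict:
        d = {k: np.asarray(getattr(self, k)).tolist()
             for k in ("p01", "p11", "gamma_shape", "gamma_scale",
                       "mean_tmax", "mean_tmin", "sd_tmax", "sd_tmin")}
        d.update(latitude=float(self.latitude), lag0_corr=float(self.lag0_corr),
                 lag1_corr_tmax=float(self.lag1_corr_tmax),
                 lag1_corr_tmin=float(self.lag1_corr_tmin))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TruthParams":
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "TruthParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _annual_cycle(mean: float, amplitude: float, peak_month: int) -> np.ndarray:
    """Sinusoidal monthly cycle peaking at ``peak_month`` (1-based)."""
    return mean + amplitude * np.cos(2 * np.pi * (_MONTHS - (peak_month - 1)) / 12.0)


def _preset_temperate_north():
    tmax_dry = _annual_cycle(16.0, 12.0, 7)
    return dict(
        latitude=45.0,
        p01=np.full(12, 0.28) + 0.05 * np.cos(2 * np.pi * (_MONTHS - 10) / 12),
        p11=np.full(12, 0.55) + 0.05 * np.cos(2 * np.pi * (_MONTHS - 10) / 12),
        gamma_shape=np.full(12, 0.8),
        gamma_scale=_annual_cycle(7.0, 2.0, 6),
        tmax_dry=tmax_dry, dtr=_annual_cycle(10.0, 2.0, 7),
        wet_cooling=2.0, sd_tmax=_annual_cycle(3.0, 0.8, 1),
        sd_tmin=_annual_cycle(2.5, 0.5, 1),
        lag0_corr=0.6, lag1_corr_tmax=0.65, lag1_corr_tmin=0.55,
    )


def _preset_monsoon():
    return dict(
        latitude=23.0,
        p01=np.clip(_annual_cycle(0.25, 0.22, 7), 0.02, 0.95),
        p11=np.clip(_annual_cycle(0.5, 0.3, 7), 0.05, 0.95),
        gamma_shape=np.full(12, 0.7),
        gamma_scale=np.clip(_annual_cycle(10.0, 7.0, 7), 1.0, None),
        tmax_dry=_annual_cycle(31.0, 5.0, 5), dtr=_annual_cycle(11.0, 2.0, 3),
        wet_cooling=3.0, sd_tmax=np.full(12, 2.2), sd_tmin=np.full(12, 1.8),
        lag0_corr=0.55, lag1_corr_tmax=0.6, lag1_corr_tmin=0.5,
    )


def _preset_mediterranean():
    return dict(
        latitude=40.0,
        p01=np.clip(_annual_cycle(0.2, 0.12, 12), 0.02, 0.95),
        p11=np.clip(_annual_cycle(0.45, 0.15, 12), 0.05, 0.95),
        gamma_shape=np.full(12, 0.75),
        gamma_scale=np.clip(_annual_cycle(8.0, 3.0, 11), 1.0, None),
        tmax_dry=_annual_cycle(22.0, 10.0, 7), dtr=_annual_cycle(10.0, 1.5, 7),
        wet_cooling=2.5, sd_tmax=np.full(12, 2.8), sd_tmin=np.full(12, 2.2),
        lag0_corr=0.6, lag1_corr_tmax=0.6, lag1_corr_tmin=0.5,
    )


def _preset_tropical_south():
    # Southern hemisphere: annual cycle phase-shifted by six months
    return dict(
        latitude=-12.0,
        p01=np.clip(_annual_cycle(0.35, 0.2, 1), 0.02, 0.95),
        p11=np.clip(_annual_cycle(0.55, 0.2, 1), 0.05, 0.95),
        gamma_shape=np.full(12, 0.75),
        gamma_scale=np.clip(_annual_cycle(9.0, 4.0, 1), 1.0, None),
        tmax_dry=_annual_cycle(31.0, 3.0, 1), dtr=_annual_cycle(9.0, 1.0, 7),
        wet_cooling=2.0, sd_tmax=np.full(12, 1.8), sd_tmin=np.full(12, 1.5),
        lag0_corr=0.5, lag1_corr_tmax=0.55, lag1_corr_tmin=0.45,
    )


SITE_PRESETS = {
    "temperate_north": _preset_temperate_north,
    "monsoon": _preset_monsoon,
    "mediterranean": _preset_mediterranean,
    "tropical_south": _preset_tropical_south,
}


def make_truth(preset: str, seed: int) -> TruthParams:
    """Deterministic truth parameters for a site archetype.

    The seed adds small reproducible site-to-site jitter around the
    archetype climatology so that multiple sites of the same archetype are
    distinct: up to +-1 degC on temperature means, +-0.03 on occurrence
    probabilities and +-10% on the gamma scale.
    """
    if preset not in SITE_PRESETS:
        raise ValueError(
            f"unknown site preset {preset!r}; expected one of {sorted(SITE_PRESETS)}")
    raw = SITE_PRESETS[preset]()
    rng = np.random.default_rng([seed, crc32(preset.encode())])
    tmax_dry = raw["tmax_dry"] + rng.uniform(-1.0, 1.0)
    dtr = raw["dtr"]
    wetc = raw["wet_cooling"]
    mean_tmax = np.column_stack([tmax_dry, tmax_dry - wetc])
    mean_tmin = mean_tmax - np.column_stack([dtr, dtr * 0.8])
    return TruthParams(
        latitude=raw["latitude"],
        p01=np.clip(raw["p01"] + rng.uniform(-0.03, 0.03, 12), 0.02, 0.95),
        p11=np.clip(raw["p11"] + rng.uniform(-0.03, 0.03, 12), 0.05, 0.95),
        gamma_shape=raw["gamma_shape"],
        gamma_scale=raw["gamma_scale"] * rng.uniform(0.9, 1.1),
        mean_tmax=mean_tmax, mean_tmin=mean_tmin,
        sd_tmax=raw["sd_tmax"], sd_tmin=raw["sd_tmin"],
        lag0_corr=raw["lag0_corr"],
        lag1_corr_tmax=raw["lag1_corr_tmax"],
        lag1_corr_tmin=raw["lag1_corr_tmin"],
    )


def simulate_series(truth: TruthParams, latitude: float | None = None,
                    n_years: int = 20, seed: int = 0,
                    site_id: str = "synthetic", start_year: int = 1986) -> DailySeries:
    """Simulate a reference daily record from known truth parameters.

    Occurrence follows the monthly two-state Markov chain, wet amounts the
    monthly gamma law, and temperatures the state-conditioned normals with
    a lag-1 bivariate residual autoregression — exactly the parametric
    generator's family, so fitting that generator to the output is a
    well-posed recovery problem.  Deterministic per seed.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    truth.validate()
    lat = truth.latitude if latitude is None else latitude
    return pwg_generate(truth.to_pwg(), lat, n_years, seed,
                        site_id=site_id, start_year=start_year)


# ---------------------------------------------------------------------------
# Change-factor scenarios
# ---------------------------------------------------------------------------


@dataclass
class ScenarioSpec:
    """Monthly delta-change factors for one GCM x RCP combination:
    additive temperature deltas (degC) and multiplicative precipitation
    ratios (dimensionless, >= 0)."""

    gcm_label: str
    rcp_label: str
    dT_max: np.ndarray
    dT_min: np.ndarray
    rP: np.ndarray

    def __post_init__(self):
        for name in ("dT_max", "dT_min", "rP"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (12,):
                raise ValueError(f"{name} must have 12 monthly entries")
            setattr(self, name, arr)
        if (self.rP < 0).any():
            raise ValueError("precipitation ratios must be >= 0")

    @property
    def label(self) -> str:
        return f"{self.gcm_label}x{self.rcp_label}"


#: Scenario archetypes: (dT low, dT high, rP low, rP high).
SCENARIO_PRESETS = {
    "null": (0.0, 0.0, 1.0, 1.0),
    "rcp45_like": (0.8, 1.5, 0.8, 1.2),
    "rcp85_like": (1.5, 2.5, 0.8, 1.2),
}

#: Half-widths of the GCM-specific offsets around the pathway-level
#: monthly factors (degC, dimensionless).  Kept small relative to the
#: pathway separation: the emulated GCM pair agrees closely on the forced
#: response, so scenario combinations cluster tightly.
_GCM_DT_JITTER = 0.05
_GCM_RP_JITTER = 0.015


def make_change_factors(scenario: str, seed: int, gcm_label: str = "gcm_a",
                        rcp_label: str | None = None) -> ScenarioSpec:
    """Deterministic plausible monthly change factors for a scenario
    archetype.

    The pathway (RCP-like) level sets monthly baseline deltas drawn from
    the archetype range; each GCM then perturbs them with a smaller
    model-specific offset, reflecting that different climate models
    project the same forced pathway with only moderate disagreement.  The
    combined factors always stay inside the archetype ranges.
    """
    if scenario not in SCENARIO_PRESETS:
        raise ValueError(f"unknown scenario {scenario!r}; "
                         f"expected one of {sorted(SCENARIO_PRESETS)}")
    lo, hi, rlo, rhi = SCENARIO_PRESETS[scenario]
    jt = min(_GCM_DT_JITTER, (hi - lo) / 2.0)
    jr = min(_GCM_RP_JITTER, (rhi - rlo) / 2.0)
    rcp_rng = np.random.default_rng([seed, crc32(scenario.encode())])
    gcm_rng = np.random.default_rng([seed, crc32(scenario.encode()),
                                     crc32(gcm_label.encode())])
    dt_base_max = rcp_rng.uniform(lo + jt, hi - jt, 12)
    dt_base_min = rcp_rng.uniform(lo + jt, hi - jt, 12)
    rp_base = rcp_rng.uniform(rlo + jr, rhi - jr, 12)
    return ScenarioSpec(
        gcm_label=gcm_label,
        rcp_label=rcp_label or scenario,
        dT_max=dt_base_max + gcm_rng.uniform(-jt, jt, 12),
        dT_min=dt_base_min + gcm_rng.uniform(-jt, jt, 12),
        rP=np.clip(rp_base + gcm_rng.uniform(-jr, jr, 12), 0.0, None),
    )


def write_change_factors_csv(specs, path) -> None:
    """Write one or more :class:`ScenarioSpec` to the interchange CSV
    (columns ``gcm,rcp,month,dtmax,dtmin,rp``)."""
    if isinstance(specs, ScenarioSpec):
        specs = [specs]
    rows = []
    for sp in specs:
        for m in range(12):
            rows.append({"gcm": sp.gcm_label, "rcp": sp.rcp_label, "month": m + 1,
                         "dtmax": sp.dT_max[m], "dtmin": sp.dT_min[m], "rp": sp.rP[m]})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_change_factors_csv(path) -> list[ScenarioSpec]:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"gcm", "rcp", "month", "dtmax", "dtmin", "rp"}
    if not required <= set(df.columns):
        raise ValueError(f"change-factor CSV must have columns {sorted(required)}")
    out = []
    for (gcm, rcp), grp in df.groupby(["gcm", "rcp"], sort=False):
        grp = grp.sort_values("month")
        if list(grp["month"]) != list(range(1, 13)):
            raise ValueError(f"scenario {gcm}x{rcp} must have months 1..12")
        out.append(ScenarioSpec(gcm_label=str(gcm), rcp_label=str(rcp),
                                dT_max=grp["dtmax"].to_numpy(),
                                dT_min=grp["dtmin"].to_numpy(),
                                rP=grp["rp"].to_numpy()))
    return out
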