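"""End-to-end experiment orchestration.

One config drives the whole uncertainty experiment: simulate reference
baselines for each site archetype, calibrate the three generator levels,
generate baseline and scenario ensembles, compute the 33-index battery,
agreement profiles and scenario proximities, run the baseline and future
rank ANOVAs under the balance rules, and propagate to rice-yield impacts.
All stage outputs are plain CSV plus one JSON summary; everything is
deterministic in the master seed (per-combination seeds are derived by a
stable hash, so adding a site never changes existing outputs).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from zlib import crc32

import pandas as pd

from .agreement import agreement_profile, scenario_proximity
from .core import qc_series, WET_THRESHOLD_MM
from .delta import apply_delta
from .generators import GenerationFailure, WG_NAMES, make_wg
from .impact import CropConfig, impact_percent, simulate_yield
from .indices import BasePeriodPercentiles, index_battery
from .ranova import apply_exclusion_rules, ranova_by_index
from .synthetic import make_change_factors, make_truth, simulate_series

__all__ = ["SiteSpec", "ExperimentConfig", "ExperimentReport",
           "run_experiment", "fig_analogs", "derive_seed", "annualize"]


def derive_seed(master_seed: int, *parts) -> int:
    """Stable per-combination seed below 2^31."""
    key = "|".join(str(p) for p in parts)
    return (int(master_seed) * 1000003 + crc32(key.encode())) % (2 ** 31)


@dataclass(frozen=True)
class SiteSpec:
    """A site in the experiment: archetype preset plus a label."""

    label: str
    preset: str


@dataclass
class ExperimentConfig:
    """Full experiment specification (defaults give the shipped
    demonstration: 2 sites x 3 generator levels x 2 GCMs x 2 RCPs x 20
    years, one realization per combination)."""

    sites: tuple = (SiteSpec("site_tn", "temperate_north"),
                    SiteSpec("site_ts", "tropical_south"))
    wgs: tuple = WG_NAMES
    gcms: tuple = ("gcm_a", "gcm_b")
    rcps: tuple = ("rcp45_like", "rcp85_like")
    n_years: int = 20
    runs: int = 1
    master_seed: int = 1
    wet_threshold: float = WET_THRESHOLD_MM
    spei_scale: int = 3
    rnn_mm: float = 25.0
    bins: int | None = None
    crop: CropConfig = field(default_factory=CropConfig)
    #: (site_label, wg, gcm, rcp) combinations forced to fail ("baseline"
    #: for the gcm/rcp slots), exercising the balance rules.
    force_failures: tuple = ()

    def validate(self) -> None:
        if len(self.sites) < 1:
            raise ValueError("need at least 1 site")
        if len(self.wgs) < 2:
            raise ValueError("need at least 2 weather generators for WG analyses")
        if self.n_years < 2:
            raise ValueError("need at least 2 years")

    def digest(self) -> str:
        d = asdict(self)
        return f"{crc32(json.dumps(d, sort_keys=True, default=str).encode()):08x}"


@dataclass
class ExperimentReport:
    """All experiment outputs as data frames, plus provenance."""

    config: ExperimentConfig
    ledger: pd.DataFrame = field(repr=False)
    index_table: pd.DataFrame = field(repr=False)
    baseline_agreement: pd.DataFrame = field(repr=False)
    proximity: pd.DataFrame = field(repr=False)
    baseline_ranova: pd.DataFrame = field(repr=False)
    future_ranova: pd.DataFrame = field(repr=False)
    impacts: pd.DataFrame = field(repr=False)
    balance: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def summary_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "n_combinations_attempted": int(len(self.ledger)),
            "n_generation_failures": int((~self.ledger["success"]).sum()),
            "balance": self.balance,
            "median_baseline_overlap": (
                float(self.baseline_agreement["overlap"].median())
                if len(self.baseline_agreement) else None),
            "median_scenario_proximity": (
                float(self.proximity["overlap"].median())
                if len(self.proximity) else None),
            "impact_pct_range": (
                [float(self.impacts["impact_pct"].min()),
                 float(self.impacts["impact_pct"].max())]
                if len(self.impacts) else None),
        }

    def save(self, outdir) -> list:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        for name in ("ledger", "index_table", "baseline_agreement", "proximity",
                     "baseline_ranova", "future_ranova", "impacts"):
            path = out / f"{name}.csv"
            getattr(self, name).to_csv(path, index=False)
            written.append(path)
        path = out / "summary.json"
        path.write_text(json.dumps(self.summary_dict(), indent=2, sort_keys=True))
        written.append(path)
        return written


#: Annual aggregation of monthly index values, following the standard
#: annual variants of the extremes indices (annual maximum of monthly
#: maxima, annual minimum of monthly minima, mean otherwise).
_ANNUAL_AGG = {"TXx": "max", "TNx": "max", "Rx1day": "max", "Rx5day": "max",
               "TXn": "min", "TNn": "min"}


def annualize(table: pd.DataFrame, extra_keys=()) -> pd.DataFrame:
    """One value per (site, series, code, year): monthly codes aggregated
    within the year by each index's natural annual statistic, annual codes
    passed through."""
    t = table.dropna(subset=["value"]).copy()
    t["_agg"] = t["code"].map(_ANNUAL_AGG).fillna("mean")
    keys = ["site", "series", "code", "year"] + list(extra_keys)
    parts = []
    for agg, grp in t.groupby("_agg"):
        parts.append(grp.groupby(keys, as_index=False, observed=True)["value"]
                     .agg(agg))
    return pd.concat(parts, ignore_index=True)


def _label(wg: str, gcm: str, rcp: str) -> str:
    return f"{wg}|{gcm}x{rcp}" if gcm != "baseline" else f"{wg}|baseline"


def run_experiment(config: ExperimentConfig,
                   outdir=None) -> ExperimentReport:
    """Run the full experiment; see the module docstring for stages."""
    config.validate()
    ms = config.master_seed
    forced = {tuple(f) for f in config.force_failures}
    ledger_rows = []
    index_parts = []
    agree_rows = []
    prox_parts = []
    impact_rows = []
    yields = {}

    # one seed for all change factors: the pathway-level draws are shared
    # between GCMs, so the GCM contrast is only the model-specific offset
    scen_seed = derive_seed(ms, "scenario")
    scenarios = {}
    for gcm in config.gcms:
        for rcp in config.rcps:
            scenarios[(gcm, rcp)] = make_change_factors(
                rcp, seed=scen_seed, gcm_label=gcm, rcp_label=rcp)

    for site in config.sites:
        truth = make_truth(site.preset, seed=derive_seed(ms, "truth", site.label))
        ref = simulate_series(truth, n_years=config.n_years,
                              seed=derive_seed(ms, "reference", site.label),
                              site_id=site.label)
        assert qc_series(ref).passed
        base_pct = BasePeriodPercentiles.from_series(ref)
        ref_idx = index_battery(ref, base_pct, spei_scale=config.spei_scale,
                                rnn_mm=config.rnn_mm, label="reference")
        ref_idx.insert(0, "wg", "reference")
        ref_idx.insert(1, "gcm", "reference")
        ref_idx.insert(2, "rcp", "reference")
        index_parts.append(ref_idx)
        yields[(site.label, "reference", "reference", "reference")] = \
            simulate_yield(ref, config.crop)
        site_scen_tables = {}
        for wg in config.wgs:
            fit_res = make_wg(wg, ref, config.wet_threshold).fit()
            for run in range(config.runs):
                combos = [("baseline", "baseline")] + [
                    (g, r) for g in config.gcms for r in config.rcps]
                for gcm, rcp in combos:
                    key = (site.label, wg, gcm, rcp)
                    entry = {"site": site.label, "wg": wg, "gcm": gcm,
                             "rcp": rcp, "run": run}
                    if key in forced:
                        ledger_rows.append({**entry, "success": False,
                                            "error": "forced failure"})
                        continue
                    try:
                        params = fit_res.params
                        if gcm != "baseline":
                            params = apply_delta(params, scenarios[(gcm, rcp)],
                                                 source_wg=wg).params
                            gen = _generate_from(fit_res, params, config,
                                                 site, wg, gcm, rcp, run, ms)
                        else:
                            gen = fit_res.generate(
                                config.n_years,
                                seed=derive_seed(ms, site.label, wg, gcm, rcp, run),
                                site_id=site.label,
                                start_year=int(ref.years.min()))
                    except (GenerationFailure, ValueError) as exc:
                        ledger_rows.append({**entry, "success": False,
                                            "error": str(exc)})
                        continue
                    ledger_rows.append({**entry, "success": True, "error": ""})
                    lab = _label(wg, gcm, rcp)
                    tab = index_battery(gen, base_pct, spei_scale=config.spei_scale,
                                        rnn_mm=config.rnn_mm, label=lab)
                    tab.insert(0, "wg", wg)
                    tab.insert(1, "gcm", gcm)
                    tab.insert(2, "rcp", rcp)
                    index_parts.append(tab)
                    yields[(site.label, wg, gcm, rcp)] = simulate_yield(gen,
                                                                       config.crop)
                    if gcm == "baseline":
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            prof = agreement_profile(ref_idx, tab, bins=config.bins)
                        for _, r in prof.scores.iterrows():
                            agree_rows.append({"site": site.label, "wg": wg,
                                               "code": r["code"],
                                               "overlap": r["overlap"],
                                               "n_a": r["n_a"], "n_b": r["n_b"],
                                               "bins": r["bins"]})
                    else:
                        site_scen_tables[(wg, gcm, rcp)] = tab
        if site_scen_tables:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                prox = scenario_proximity(site_scen_tables, bins=config.bins)
            prox.insert(0, "site", site.label)
            prox_parts.append(prox)

    ledger = pd.DataFrame(ledger_rows)
    index_table = pd.concat(index_parts, ignore_index=True)
    balance = apply_exclusion_rules(ledger)
    if not balance["baseline_sites"] and not balance["future_sites"]:
        raise RuntimeError("no site survives the balance rules; nothing to analyse: "
                           + json.dumps(balance["dropped"]))

    baseline_ranova = _baseline_analysis(index_table, balance["baseline_sites"])
    future_ranova = _future_analysis(index_table, balance["future_sites"],
                                     len(config.sites), len(config.gcms),
                                     len(config.rcps))

    for (site_l, wg, gcm, rcp), yr in yields.items():
        if gcm in ("baseline", "reference"):
            continue
        base = yields.get((site_l, wg, "baseline", "baseline"))
        if base is None:
            continue
        impact_rows.append({"site": site_l, "wg": wg, "gcm": gcm, "rcp": rcp,
                            "baseline_yield_t_ha": base.mean_yield,
                            "future_yield_t_ha": yr.mean_yield,
                            "impact_pct": impact_percent(yr, base)})

    report = ExperimentReport(
        config=config,
        ledger=ledger,
        index_table=index_table,
        baseline_agreement=pd.DataFrame(
            agree_rows, columns=["site", "wg", "code", "overlap",
                                 "n_a", "n_b", "bins"]),
        proximity=(pd.concat(prox_parts, ignore_index=True) if prox_parts
                   else pd.DataFrame(columns=["site", "wg", "scenario_a",
                                              "scenario_b", "code", "overlap"])),
        baseline_ranova=baseline_ranova,
        future_ranova=future_ranova,
        impacts=pd.DataFrame(impact_rows,
                             columns=["site", "wg", "gcm", "rcp",
                                      "baseline_yield_t_ha",
                                      "future_yield_t_ha", "impact_pct"]),
        balance=balance,
        provenance={"master_seed": ms, "config_digest": config.digest(),
                    "n_years": config.n_years},
    )
    if outdir is not None:
        report.save(outdir)
    return report


def _generate_from(fit_res, params, config, site, wg, gcm, rcp, run, ms):
    from .generators import PWGParams, pwg_generate, sewg_generate
    seed = derive_seed(ms, site.label, wg, gcm, rcp, run)
    lab = site.label
    start = int(fit_res.series.years.min())
    if isinstance(params, PWGParams):
        return pwg_generate(params, fit_res.series.latitude, config.n_years, seed,
                            site_id=lab, start_year=start,
                            wet_threshold=config.wet_threshold)
    return sewg_generate(params, fit_res.series.latitude, config.n_years, seed,
                         site_id=lab, start_year=start,
                         wet_threshold=config.wet_threshold)


def _baseline_analysis(index_table: pd.DataFrame, sites) -> pd.DataFrame:
    """Per-index rank ANOVA of per-year (generated - reference) differences
    with factors site, wg and their interaction."""
    if not sites:
        return pd.DataFrame(columns=["index_code", "term", "stat", "df1", "df2", "p"])
    t = index_table[index_table["site"].isin(sites)]
    ann = annualize(t)
    ref = ann[ann["series"] == "reference"].rename(columns={"value": "ref_value"})
    gen = ann[ann["series"].str.endswith("|baseline")].copy()
    gen["wg"] = gen["series"].str.split("|").str[0]
    merged = gen.merge(ref[["site", "code", "year", "ref_value"]],
                       on=["site", "code", "year"], how="inner")
    merged["diff"] = merged["value"] - merged["ref_value"]
    factors = ["site", "wg"] if merged["site"].nunique() > 1 else ["wg"]
    inters = ["site:wg"] if "site" in factors else None
    return ranova_by_index(merged, "diff", factors, inters)


def _future_analysis(index_table: pd.DataFrame, sites,
                     n_sites: int, n_gcms: int, n_rcps: int) -> pd.DataFrame:
    """Per-index rank ANOVA of future index values with the factorial
    site/gcm/rcp/wg structure and all two-way interactions among the
    varied factors."""
    if not sites:
        return pd.DataFrame(columns=["index_code", "term", "stat", "df1", "df2", "p"])
    t = index_table[index_table["site"].isin(sites)
                    & ~index_table["gcm"].isin(["baseline", "reference"])]
    ann = annualize(t[["site", "series", "code", "year", "value",
                       "wg", "gcm", "rcp"]], extra_keys=("wg", "gcm", "rcp"))
    factors = [f for f, k in (("site", len(sites)), ("wg", 3),
                              ("gcm", n_gcms), ("rcp", n_rcps))
               if ann[f].nunique() > 1]
    inters = [f"{a}:{b}" for i, a in enumerate(factors) for b in factors[i + 1:]]
    return ranova_by_index(ann, "value", factors, inters)


def fig_analogs(report: ExperimentReport, outdir, plots: bool = False) -> list:
    """Write the five figure-analog artifacts (impact scatter, baseline
    agreement profile, baseline ANOVA heat table, scenario proximity,
    future ANOVA heat table) as CSV; optionally also plot them."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts = []

    def _write(df, name):
        path = out / name
        df.to_csv(path, index=False)
        artifacts.append(path)

    _write(report.impacts, "fig2_impact_by_wg_scenario.csv")
    _write(report.baseline_agreement, "fig3_baseline_agreement_profile.csv")
    _write(report.baseline_ranova, "fig4_baseline_ranova_pvalues.csv")
    _write(report.proximity, "fig5_scenario_proximity.csv")
    _write(report.future_ranova, "fig6_future_ranova_pvalues.csv")
    if plots:
        artifacts.extend(_plots(report, out))
    return artifacts


def _plots(report: ExperimentReport, out: Path) -> list:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    made = []
    if len(report.impacts):
        fig, ax = plt.subplots(figsize=(7, 4))
        for wg, grp in report.impacts.groupby("wg"):
            x = grp["site"] + "/" + grp["gcm"] + "x" + grp["rcp"]
            ax.scatter(x, grp["impact_pct"], label=wg, alpha=0.8)
        ax.axhline(0, color="k", lw=0.5)
        ax.set_ylabel("yield impact (%)")
        ax.legend()
        ax.tick_params(axis="x", rotation=90)
        fig.tight_layout()
        p = out / "fig2_impact_by_wg_scenario.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        made.append(p)
    if len(report.baseline_agreement):
        fig, ax = plt.subplots(figsize=(8, 4))
        for (site, wg), grp in report.baseline_agreement.groupby(["site", "wg"]):
            ax.plot(grp["code"], grp["overlap"], marker="o", ms=3,
                    label=f"{site}/{wg}")
        ax.set_ylabel("overlap with reference")
        ax.tick_params(axis="x", rotation=90)
        ax.legend(fontsize=7)
        fig.tight_layout()
        p = out / "fig3_baseline_agreement_profile.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        made.append(p)
    return made
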