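import numpy as np
import pandas as pd
import pytest

import climuq as cq
from climuq.indices import (ALL_CODES, MONTHLY_CODES, BasePeriodPercentiles,
                            aridity_metrics, compute_etccdi, de_martonne,
                            extraterrestrial_radiation, hargreaves_et0,
                            index_battery, spei)

# ---------------------------------------------------------------------------
# Naive reference implementations, written directly from the definitions and
# kept deliberately loop-based and separate from the package's vectorized
# code paths.
# ---------------------------------------------------------------------------


def naive_txx_monthly(series):
    out = {}
    for i in range(len(series)):
        key = (series.years[i], series.months[i])
        out[key] = max(out.get(key, -1e9), series.tmax[i])
    return out


def naive_tnn_monthly(series):
    out = {}
    for i in range(len(series)):
        key = (series.years[i], series.months[i])
        out[key] = min(out.get(key, 1e9), series.tmin[i])
    return out


def naive_rx1day_monthly(series):
    out = {}
    for i in range(len(series)):
        key = (series.years[i], series.months[i])
        out[key] = max(out.get(key, 0.0), series.prcp[i])
    return out


def naive_cdd_annual(series, wet_mm=1.0):
    out = {}
    for y in np.unique(series.years):
        run = best = 0
        for p in series.prcp[series.years == y]:
            run = run + 1 if p < wet_mm else 0
            best = max(best, run)
        out[y] = best
    return out


def naive_prcptot_annual(series, wet_mm=1.0):
    out = {}
    for y in np.unique(series.years):
        out[y] = sum(p for p in series.prcp[series.years == y] if p >= wet_mm)
    return out


def naive_sdii_annual(series, wet_mm=1.0):
    out = {}
    for y in np.unique(series.years):
        wet = [p for p in series.prcp[series.years == y] if p >= wet_mm]
        out[y] = sum(wet) / len(wet) if wet else np.nan
    return out


def _rows_to_dict(df, monthly=True):
    if monthly:
        return {(r["year"], r["period"]): r["value"] for _, r in df.iterrows()}
    return {r["year"]: r["value"] for _, r in df.iterrows()}


@pytest.fixture(scope="module")
def five_series():
    out = []
    for i, preset in enumerate(["temperate_north", "monsoon",
                                "mediterranean", "tropical_south",
                                "temperate_north"]):
        truth = cq.make_truth(preset, 10 + i)
        out.append(cq.simulate_series(truth, n_years=5, seed=50 + i,
                                      site_id=f"s{i}"))
    return out


class TestAgainstNaiveReference:
    def test_subset_matches_reference(self, five_series):
        for s in five_series:
            base = BasePeriodPercentiles.from_series(s)
            for code, naive, monthly in [
                    ("TXx", naive_txx_monthly, True),
                    ("TNn", naive_tnn_monthly, True),
                    ("Rx1day", naive_rx1day_monthly, True),
                    ("CDD", naive_cdd_annual, False),
                    ("PRCPTOT", naive_prcptot_annual, False),
                    ("SDII", naive_sdii_annual, False)]:
                got = _rows_to_dict(compute_etccdi(s, code, base),
                                    monthly=monthly)
                expected = naive(s)
                assert set(got) == set(expected)
                for k in expected:
                    assert got[k] == pytest.approx(expected[k], abs=1e-9), \
                        (code, k)

    def test_percentile_exceedance_partition(self, five_series):
        """TN10p, TN90p and the in-between fraction partition the month."""
        s = five_series[0]
        base = BasePeriodPercentiles.from_series(s)
        tn10 = _rows_to_dict(compute_etccdi(s, "TN10p", base))
        tn90 = _rows_to_dict(compute_etccdi(s, "TN90p", base))
        lo = base.thresholds_for(s.dates, "p10_tmin")
        hi = base.thresholds_for(s.dates, "p90_tmin")
        mid = pd.Series(((s.tmin >= lo) & (s.tmin <= hi)).astype(float)) \
            .groupby([s.years, s.months]).mean() * 100
        for key in tn10:
            assert tn10[key] + tn90[key] + mid[key] == pytest.approx(100.0)


class TestFixtures:
    def test_txx_on_ramp_january(self, series_factory):
        tmax = np.concatenate([np.arange(1.0, 32.0), np.full(334, 5.0)])
        s = series_factory(tmax=tmax, tmin=tmax - 5, prcp=np.zeros(365))
        rows = compute_etccdi(s, "TXx")
        jan = rows[(rows["year"] == 2001) & (rows["period"] == 1)]
        assert jan["value"].iloc[0] == 31.0

    def test_rx1day_single_event(self, series_factory):
        prcp = np.zeros(365)
        prcp[2] = 12.5
        prcp[3] = 3.0
        s = series_factory(tmax=np.full(365, 10.0), tmin=np.zeros(365),
                           prcp=prcp)
        rows = compute_etccdi(s, "Rx1day")
        jan = rows[(rows["year"] == 2001) & (rows["period"] == 1)]
        assert jan["value"].iloc[0] == 12.5

    def test_sdii_ratio(self, series_factory):
        # 60 wet days of 5 mm -> PRCPTOT 300 over 60 wet days -> SDII 5.0
        prcp = np.zeros(365)
        prcp[:60] = 5.0
        s = series_factory(tmax=np.full(365, 10.0), tmin=np.zeros(365),
                           prcp=prcp)
        rows = compute_etccdi(s, "SDII")
        assert rows["value"].iloc[0] == pytest.approx(5.0)
        tot = compute_etccdi(s, "PRCPTOT")
        assert tot["value"].iloc[0] == pytest.approx(300.0)

    def test_csdi_counts_a_seven_day_spell(self, series_factory):
        # base: 20 years with deterministic +-0.5 degC year-to-year wiggle so
        # the 10th percentile sits below the climatological value
        years = 20
        n = 365 * years
        clim = 10.0 + 5.0 * np.sin(2 * np.pi * np.arange(365) / 365.0)
        wiggle = np.tile(np.linspace(-0.5, 0.5, years)[:, None], (1, 365))
        tmin = (clim[None, :] + wiggle).ravel()
        base_s = series_factory(tmax=tmin + 10, tmin=tmin, prcp=np.zeros(n),
                                start="1981-01-01")
        base = BasePeriodPercentiles.from_series(base_s)
        # test year: at climatology (above p10) except one 7-day cold dip
        t = clim + 0.6
        t[100:107] -= 15.0
        s = series_factory(tmax=t + 10, tmin=t, prcp=np.zeros(365),
                           start="2001-01-01")
        rows = compute_etccdi(s, "CSDI", base)
        assert rows["value"].iloc[0] == 7.0
        # oracle: direct run-length scan
        below = s.tmin < base.thresholds_for(s.dates, "p10_tmin")
        run = best_total = 0
        total = 0
        for b in below:
            run = run + 1 if b else 0
            if run == 6:
                total += 6
            elif run > 6:
                total += 1
        assert total == 7

    def test_tx90p_on_base_period_is_ten_percent(self, ref20, base20):
        rows = compute_etccdi(ref20, "TX90p", base20)
        assert rows["value"].mean() == pytest.approx(10.0, abs=1.5)

    def test_unknown_code(self, ref20):
        with pytest.raises(ValueError, match="unknown ETCCDI code"):
            compute_etccdi(ref20, "XXX")

    def test_percentile_code_needs_base(self, ref20):
        with pytest.raises(ValueError, match="base-period"):
            compute_etccdi(ref20, "TX90p", base=None)


class TestHargreaves:
    def test_zero_range_gives_zero_et0(self):
        dates = pd.date_range("2001-06-01", periods=5)
        et0 = hargreaves_et0(np.full(5, 20.0), np.full(5, 20.0), 45.0, dates)
        assert (et0 == 0).all()

    def test_fao56_worked_computation(self):
        """Step-by-step extraterrestrial radiation + Hargreaves formula,
        composed independently, mid-July day at 45 N."""
        doy = 196
        phi = np.deg2rad(45.0)
        dr = 1 + 0.033 * np.cos(2 * np.pi * doy / 365)
        delta = 0.409 * np.sin(2 * np.pi * doy / 365 - 1.39)
        ws = np.arccos(-np.tan(phi) * np.tan(delta))
        ra = (24 * 60 / np.pi) * 0.0820 * dr * (
            ws * np.sin(phi) * np.sin(delta)
            + np.cos(phi) * np.cos(delta) * np.sin(ws))
        expected = 0.0023 * (24.0 + 17.8) * np.sqrt(30.0 - 18.0) * 0.408 * ra
        dates = pd.DatetimeIndex([pd.Timestamp("2001-01-01")
                                  + pd.Timedelta(days=doy - 1)])
        got = hargreaves_et0(np.array([30.0]), np.array([18.0]), 45.0, dates)
        assert got[0] == pytest.approx(expected, abs=1e-3)

    def test_equatorial_equinox_near_symmetry(self):
        # declination is ~0 at both equinoxes; the Earth-Sun distance term
        # differs by <1%, so equality holds only to that order
        ra = extraterrestrial_radiation(0.0, np.array([79, 266]))
        assert ra[0] == pytest.approx(ra[1], rel=0.02)

    def test_polar_latitude_unsupported(self):
        with pytest.raises(ValueError, match="66.5"):
            extraterrestrial_radiation(70.0, np.array([100]))

    def test_nonnegative_everywhere(self, ref20):
        et0 = hargreaves_et0(ref20.tmax, ref20.tmin, ref20.latitude, ref20.dates)
        assert (et0 >= 0).all()


class TestSPEI:
    def test_calibration_standardization(self, ref20):
        tab = spei(ref20)
        g = tab.groupby("period")["value"]
        assert np.all(np.abs(g.mean()) < 0.05)
        assert np.all(np.abs(g.std() - 1.0) < 0.1)

    def test_monotone_in_precipitation(self, series_factory):
        """One calendar month with strictly increasing precipitation across
        years and identical temperatures gives strictly increasing SPEI."""
        dates = pd.date_range("2001-01-01", "2025-12-31", freq="D")
        n = len(dates)
        doy = dates.dayofyear.values
        t = 10.0 + 8.0 * np.sin(2 * np.pi * doy / 365.0)
        prcp = np.zeros(n)
        july = dates.month.values == 7
        yidx = dates.year.values - 2001
        prcp[july] = 2.0 + 0.4 * yidx[july]
        s = series_factory(tmax=t + 5, tmin=t - 5, prcp=prcp)
        tab = spei(s, scale=1)
        july_vals = tab[tab["period"] == 7].sort_values("year")["value"]
        assert july_vals.is_monotonic_increasing

    def test_warns_below_twenty_years(self, series_factory):
        rng = np.random.default_rng(0)
        n = 5 * 365
        t = 10 + 8 * np.sin(2 * np.pi * (np.arange(n) % 365) / 365)
        s = series_factory(tmax=t + 5, tmin=t - 5, prcp=rng.gamma(0.7, 5, n))
        with pytest.warns(UserWarning, match="unstable"):
            spei(s)

    def test_undefined_head_not_reported(self, ref20):
        tab = spei(ref20, scale=3)
        first = tab.sort_values(["year", "period"]).iloc[0]
        assert (first["year"], first["period"]) == (ref20.years.min(), 3)


class TestAridity:
    def test_de_martonne_direct(self):
        assert de_martonne(600.0, 20.0) == pytest.approx(20.0)

    def test_p_equals_pet_gives_unit_indices(self, series_factory):
        n = 2 * 365
        t = 15.0 + 8.0 * np.sin(2 * np.pi * (np.arange(n) % 365) / 365.0)
        tmax, tmin = t + 6, t - 6
        dates = pd.date_range("2001-01-01", periods=n)
        pet = hargreaves_et0(tmax, tmin, 45.0, dates)
        s = series_factory(tmax=tmax, tmin=tmin, prcp=pet)
        tab = aridity_metrics(s)
        unep = tab[tab["code"] == "UNEP_AI"]["value"]
        wb = tab[tab["code"] == "WaterBalance"]["value"]
        sam = tab[tab["code"] == "SAM"]["value"]
        assert np.allclose(unep, 1.0)
        assert np.allclose(wb, 0.0, atol=1e-9)
        assert np.allclose(sam, 1.0)

    def test_doubling_precipitation_scales_linearly(self, ref20, series_factory):
        s2 = series_factory(tmax=ref20.tmax, tmin=ref20.tmin,
                            prcp=2 * ref20.prcp, start=str(ref20.dates[0].date()),
                            latitude=ref20.latitude)
        a = aridity_metrics(ref20)
        b = aridity_metrics(s2)
        for code in ("UNEP_AI", "SAM"):
            va = a[a["code"] == code]["value"].to_numpy()
            vb = b[b["code"] == code]["value"].to_numpy()
            assert np.allclose(vb, 2 * va)
        wa = a[a["code"] == "WaterBalance"].set_index(["year", "period"])["value"]
        wb = b[b["code"] == "WaterBalance"].set_index(["year", "period"])["value"]
        mp = ref20.to_frame().assign(year=ref20.years, month=ref20.months) \
            .groupby(["year", "month"])["prcp"].sum()
        mp.index.names = ["year", "period"]
        assert np.allclose(wb - wa, mp.loc[wa.index])

    def test_cold_year_undefined(self, series_factory):
        t = np.full(730, -20.0)
        s = series_factory(tmax=t + 2, tmin=t - 2, prcp=np.zeros(730))
        tab = aridity_metrics(s)
        dm = tab[tab["code"] == "deMartonneGottman"]["value"]
        assert dm.isna().all()


class TestBattery:
    def test_exactly_33_codes(self, battery20):
        assert battery20["code"].nunique() == 33
        assert set(battery20["code"]) == set(ALL_CODES)

    def test_monthly_codes_have_twelve_periods_per_year(self, battery20):
        for code in MONTHLY_CODES - {"SPEI"}:
            sub = battery20[battery20["code"] == code]
            per_year = sub.groupby("year")["period"].nunique()
            assert (per_year == 12).all(), code

    def test_annual_codes_single_row_per_year(self, battery20, ref20):
        for code in set(ALL_CODES) - MONTHLY_CODES - {"GSL"}:
            sub = battery20[battery20["code"] == code]
            assert len(sub) == len(np.unique(ref20.years)), code
            assert (sub["period"] == "annual").all()

    def test_keys_unique(self, battery20):
        keys = battery20[["site", "series", "code", "year", "period"]]
        assert not keys.duplicated().any()

    def test_subset_selection(self, ref20, base20):
        tab = index_battery(ref20, base20, codes=("TXx", "PRCPTOT", "SAM"))
        assert set(tab["code"]) == {"TXx", "PRCPTOT", "SAM"}

    def test_gsl_southern_hemisphere_spans_new_year(self, ref20_south):
        rows = compute_etccdi(ref20_south, "GSL")
        # warm tropical site: season runs essentially year-round
        assert (rows["value"] > 300).all()
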