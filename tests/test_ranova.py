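import numpy as np
import pandas as pd
import pytest
from itertools import product
from scipy import stats

from climuq.ranova import (RankLM, apply_exclusion_rules, build_design,
                           check_balance, drop_in_dispersion, ranova_table,
                           rank_transform_anova)


def _factorial(reps=5, sites="AB", wgs="XYZ", gcms="GH", rcps="45"):
    rows = [dict(site=s, wg=w, gcm=g, rcp=r)
            for s, w, g, r in product(sites, wgs, gcms, rcps)]
    return pd.DataFrame(rows * reps).reset_index(drop=True)


class TestRankLM:
    def test_exact_linear_recovery(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((60, 3))
        beta = np.array([1.5, -2.0, 0.5])
        y = 3.0 + X @ beta
        res = RankLM(y, X).fit()
        assert np.allclose(res.params, beta, atol=1e-6)
        assert res.dispersion == pytest.approx(0.0, abs=1e-8)

    def test_location_invariance(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((80, 2))
        y = X @ [1.0, -1.0] + rng.standard_normal(80)
        a = RankLM(y, X).fit()
        b = RankLM(y + 100.0, X).fit()
        assert np.allclose(a.params, b.params, atol=1e-6)
        assert a.dispersion == pytest.approx(b.dispersion, abs=1e-8)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(2)
        df = _factorial(reps=3)
        df["y"] = rng.standard_normal(len(df))
        res_a = ranova_table(df, "y", ["site", "wg", "gcm", "rcp"])
        perm = rng.permutation(len(df))
        res_b = ranova_table(df.iloc[perm].reset_index(drop=True), "y",
                             ["site", "wg", "gcm", "rcp"])
        assert np.allclose(res_a["stat"], res_b["stat"], atol=1e-6)

    def test_dispersion_not_worse_than_least_squares_start(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((100, 4))
        y = X @ [1, 0, -1, 2] + rng.standard_t(2, 100)
        model = RankLM(y, X)
        ols_beta, *_ = np.linalg.lstsq(model._xc, y - y.mean(), rcond=None)
        res = model.fit()
        assert res.dispersion <= model._objective(ols_beta) + 1e-12

    def test_pairwise_lad_oracle(self):
        """The Wilcoxon dispersion minimizer equals the median regression on
        all pairwise differences (independent formulation)."""
        import statsmodels.api as sm
        rng = np.random.default_rng(4)
        n = 90
        X = rng.standard_normal((n, 3))
        y = X @ [1.0, 0.5, -0.5] + rng.standard_normal(n)
        res = RankLM(y, X).fit()
        iu, ju = np.triu_indices(n, k=1)
        qr = sm.QuantReg(y[iu] - y[ju], X[iu] - X[ju]).fit(q=0.5, p_tol=1e-10)
        from climuq.ranova import _dispersion
        d_oracle = _dispersion(y - (X - X.mean(0)) @ qr.params)
        assert res.dispersion <= d_oracle * (1 + 1e-4) + 1e-8

    def test_rank_deficiency_names_columns(self):
        X = np.ones((30, 2))
        X[:, 1] = 2.0  # second column aliased with the first
        with pytest.raises(ValueError, match="x1"):
            RankLM(np.arange(30.0), X, ["x0", "x1"])

    def test_standard_errors_and_summary(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((200, 2))
        y = X @ [2.0, 0.0] + rng.standard_normal(200)
        res = RankLM(y, X, ["a", "b"]).fit()
        assert res.bse.shape == (2,)
        assert abs(res.params[0] - 2.0) < 4 * res.bse[0]
        txt = res.summary()
        assert "tau" in txt and "a" in txt


class TestDropInDispersion:
    def test_one_way_matches_rank_sum_oracle(self):
        rng = np.random.default_rng(6)
        for shift in (0.0, 0.2, 0.5):
            y1 = rng.standard_normal(150)
            y2 = rng.standard_normal(150) + shift
            df = pd.DataFrame({"g": ["a"] * 150 + ["b"] * 150,
                               "y": np.r_[y1, y2]})
            p_rank = ranova_table(df, "y", ["g"])["p"].iloc[0]
            p_ws = stats.ranksums(y1, y2).pvalue
            assert abs(p_rank - p_ws) < 0.02

    def test_reduction_nonnegative(self):
        rng = np.random.default_rng(7)
        df = _factorial(reps=4)
        df["y"] = rng.standard_normal(len(df))
        res = ranova_table(df, "y", ["site", "wg", "gcm", "rcp"],
                           interactions=["site:wg"])
        assert (res["rd"] >= 0).all()
        assert ((res["p"] >= 0) & (res["p"] <= 1)).all()

    def test_requires_nested_models(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((50, 2))
        y = rng.standard_normal(50)
        full = RankLM(y, X).fit()
        with pytest.raises(ValueError):
            drop_in_dispersion(full, full)


class TestBalance:
    def test_complete_design_is_balanced(self):
        df = _factorial(reps=20)
        rep = check_balance(df, ["site", "wg", "gcm", "rcp"])
        assert rep.balanced
        assert (rep.cell_counts["n"] == 20).all()

    def test_missing_cell_detected(self):
        df = _factorial(reps=20)
        df = df[~((df["site"] == "B") & (df["wg"] == "Z")
                  & (df["gcm"] == "G") & (df["rcp"] == "5"))]
        rep = check_balance(df, ["site", "wg", "gcm", "rcp"])
        assert not rep.balanced
        assert len(rep.incomplete_cells) == 1

    def _ledger(self):
        rows = []
        for site in ("s1", "s2"):
            for wg in ("w1", "w2", "w3"):
                rows.append(dict(site=site, wg=wg, gcm="baseline",
                                 rcp="baseline", success=True))
                for gcm in ("g1", "g2"):
                    for rcp in ("r45", "r85"):
                        rows.append(dict(site=site, wg=wg, gcm=gcm, rcp=rcp,
                                         success=True))
        return pd.DataFrame(rows)

    def test_all_successful_keeps_everything(self):
        out = apply_exclusion_rules(self._ledger())
        assert out["baseline_sites"] == ["s1", "s2"]
        assert out["future_sites"] == ["s1", "s2"]

    def test_future_failure_drops_whole_site_from_future_only(self):
        led = self._ledger()
        sel = ((led["site"] == "s2") & (led["wg"] == "w3")
               & (led["gcm"] == "g1") & (led["rcp"] == "r85"))
        led.loc[sel, "success"] = False
        out = apply_exclusion_rules(led)
        assert out["future_sites"] == ["s1"]
        assert out["baseline_sites"] == ["s1", "s2"]

    def test_baseline_failure_drops_site_from_baseline_only(self):
        led = self._ledger()
        sel = ((led["site"] == "s1") & (led["wg"] == "w2")
               & (led["gcm"] == "baseline"))
        led.loc[sel, "success"] = False
        out = apply_exclusion_rules(led)
        assert out["baseline_sites"] == ["s2"]
        assert out["future_sites"] == ["s1", "s2"]

    def test_unbalanced_design_refused(self):
        rng = np.random.default_rng(9)
        df = _factorial(reps=3)
        df = df.iloc[:-1]
        df["y"] = rng.standard_normal(len(df))
        with pytest.raises(ValueError, match="not balanced"):
            ranova_table(df, "y", ["site", "wg", "gcm", "rcp"])


class TestRankTransform:
    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(10)
        df = _factorial(reps=4)
        df["y"] = rng.gamma(2.0, 1.0, len(df))
        a = rank_transform_anova(df, "y", ["site", "wg"])
        df["y"] = np.exp(df["y"])
        b = rank_transform_anova(df, "y", ["site", "wg"])
        assert np.allclose(a["stat"], b["stat"])

    def test_two_group_matches_kruskal_wallis(self):
        rng = np.random.default_rng(11)
        y1 = rng.standard_normal(40)
        y2 = rng.standard_normal(40) + 0.6
        df = pd.DataFrame({"g": ["a"] * 40 + ["b"] * 40, "y": np.r_[y1, y2]})
        res = rank_transform_anova(df, "y", ["g"])
        kw = stats.kruskal(y1, y2)
        assert (res["p"].iloc[0] < 0.05) == (kw.pvalue < 0.05)
        assert res["p"].iloc[0] == pytest.approx(kw.pvalue, abs=0.02)

    def test_concordance_with_rank_fit(self):
        """Term-level significance decisions of the two ANOVA drivers agree
        on most simulated balanced datasets."""
        rng = np.random.default_rng(12)
        agree = total = 0
        for rep in range(100):
            df = _factorial(reps=3)
            effect = {"X": 0.0, "Y": 0.8, "Z": -0.8}
            df["y"] = rng.standard_normal(len(df)) \
                + df["wg"].map(effect) * (rep % 2)
            a = ranova_table(df, "y", ["site", "wg", "gcm", "rcp"]) \
                .set_index("term")["p"] < 0.05
            b = rank_transform_anova(df, "y", ["site", "wg", "gcm", "rcp"]) \
                .set_index("term")["p"] < 0.05
            agree += int((a == b).sum())
            total += len(a)
        assert agree / total >= 0.9


class TestBuildDesign:
    def test_interaction_columns(self):
        df = _factorial(reps=1)
        X, names, slices = build_design(df, ["site", "wg", "site:wg"])
        assert X.shape[1] == 1 + 2 + 2
        assert slices["site:wg"] == slice(3, 5)
        assert any(":" in n for n in names)

    def test_single_level_factor_rejected(self):
        df = pd.DataFrame({"a": ["x"] * 10, "y": np.arange(10.0)})
        with pytest.raises(ValueError, match="fewer than 2 levels"):
            build_design(df, ["a"])
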