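"""Rank-based linear models and robust ANOVA for uncertainty attribution.

The estimator minimizes Jaeckel's dispersion with Wilcoxon scores,

    D(beta) = sum_i a(R(e_i)) e_i,   a(i) = sqrt(12) (i/(n+1) - 1/2),

where e are residuals and R their ranks (midranks under ties).  D is
convex, non-negative and location-invariant, so the intercept is
estimated separately as the median of residuals.  Effects of factors are
tested by drop-in-dispersion: with reduction in dispersion RD between a
reduced and the full model,

    F_phi = (RD / q) / (tau_hat / 2)

is referred to an F(q, n - p - 1) distribution, where tau_hat is the
Koul-Sievers-McKean window estimate of the scale parameter
tau = (sqrt(12) integral f^2)^(-1).

Two ANOVA drivers are provided: :func:`ranova_table` (drop-in-dispersion
on the rank fit) and :func:`rank_transform_anova` (classical least-squares
F tests on midrank-transformed responses) as a cross-check, plus the
balanced-design bookkeeping used by the experiment pipeline: a site that
failed any generator x scenario combination is excluded from the
future-scenario analysis, and a site that failed only baseline generation
is excluded only from the baseline analysis.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RankLM",
    "RankLMResults",
    "BalanceReport",
    "build_design",
    "check_balance",
    "apply_exclusion_rules",
    "drop_in_dispersion",
    "ranova_table",
    "rank_transform_anova",
    "wilcoxon_tau",
]


# ---------------------------------------------------------------------------
# Dispersion machinery
# ---------------------------------------------------------------------------

def _wilcoxon_scores_of(e: np.ndarray) -> np.ndarray:
    n = len(e)
    r = stats.rankdata(e)  # midranks
    return np.sqrt(12.0) * (r / (n + 1.0) - 0.5)


def _dispersion(e: np.ndarray) -> float:
    n = len(e)
    srt = np.sort(e)
    sc = np.sqrt(12.0) * (np.arange(1, n + 1) / (n + 1.0) - 0.5)
    return float(sc @ srt)


def wilcoxon_tau(resid: np.ndarray, p: int) -> float:
    """Koul-Sievers-McKean window estimator of the Wilcoxon scale tau.

    The density of pairwise residual differences at zero estimates
    ``integral f^2``; the window is the delta-quantile of the absolute
    differences shrunk by sqrt(n) (delta = 0.8, or 0.95 in small samples),
    and a degrees-of-freedom correction sqrt(n / (n - p - 1)) is applied.
    """
    e = np.asarray(resid, dtype=float)
    n = len(e)
    delta = 0.80 if n > 5 * (p + 1) else 0.95
    diffs = np.abs(e[:, None] - e[None, :])[np.triu_indices(n, k=1)]
    diffs = np.sort(diffs)
    diffs = diffs[p:]  # discard the p smallest (near-ties from fitting)
    t = np.quantile(diffs, delta) / np.sqrt(n)
    if t <= 0:
        raise ValueError("degenerate residuals: zero KSM window")
    w = (diffs <= t).sum()
    cn = 2.0 / (n * (n - 1))
    fdelta = cn * w / (2.0 * t)
    tau = 1.0 / (np.sqrt(12.0) * fdelta)
    return float(tau * np.sqrt(n / (n - p - 1.0)))


@dataclass
class RankLMResults:
    """Results of a Wilcoxon rank regression fit."""

    model: "RankLM"
    params: np.ndarray
    intercept: float
    dispersion: float
    tau: float
    resid: np.ndarray = field(repr=False)
    converged: bool = True
    n_iter: int = 0

    @property
    def bse(self) -> np.ndarray:
        """Asymptotic standard errors tau * sqrt(diag((Xc'Xc)^-1))."""
        xc = self.model._xc
        xtx_inv = np.linalg.inv(xc.T @ xc)
        return self.tau * np.sqrt(np.diag(xtx_inv))

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.model.endog - self.resid

    def summary(self) -> str:
        buf = io.StringIO()
        buf.write("Rank-based linear model (Wilcoxon scores)\n")
        buf.write(f"n = {self.model.nobs}, p = {self.model.nparams}, "
                  f"dispersion = {self.dispersion:.4f}, tau = {self.tau:.4f}\n")
        df = pd.DataFrame({"coef": self.params, "std err": self.bse},
                          index=self.model.exog_names)
        df["t"] = df["coef"] / df["std err"]
        df["P>|t|"] = 2 * stats.t.sf(np.abs(df["t"]),
                                     self.model.nobs - self.model.nparams - 1)
        buf.write(df.to_string(float_format=lambda v: f"{v:.4f}"))
        buf.write(f"\nintercept (median residual offset): {self.intercept:.4f}\n")
        return buf.getvalue()


class RankLM:
    """Rank-regression model: response ``endog`` on columns ``exog``
    (no intercept column; the design is centred internally and the
    intercept is the median of the residuals).
    """

    def __init__(self, endog, exog, exog_names=None):
        self.endog = np.asarray(endog, dtype=float)
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        self.exog = X
        n, p = X.shape
        if n <= p:
            raise ValueError(f"n = {n} must exceed number of columns p = {p}")
        rank = np.linalg.matrix_rank(X)
        if rank < p:
            aliased = _aliased_columns(X, exog_names)
            raise ValueError(f"design matrix is rank deficient; aliased columns: "
                             f"{aliased}")
        self.exog_names = list(exog_names) if exog_names is not None else [
            f"x{i}" for i in range(p)]
        self._xc = X - X.mean(axis=0)

    @property
    def nobs(self) -> int:
        return len(self.endog)

    @property
    def nparams(self) -> int:
        return self.exog.shape[1]

    def _objective(self, beta: np.ndarray) -> float:
        return _dispersion(self.endog - self._xc @ beta)

    def _gradient(self, beta: np.ndarray) -> np.ndarray:
        e = self.endog - self._xc @ beta
        return -self._xc.T @ _wilcoxon_scores_of(e)

    def fit(self, tol: float = 1e-8, maxiter: int = 500) -> RankLMResults:
        """Minimize the Wilcoxon dispersion by scored Newton-type steps.

        From the least-squares start, each iteration takes the step
        ``tau0 * (Xc'Xc)^-1 Xc' a(R(e))`` (the negative-gradient direction
        preconditioned by the design cross-product, scaled by an initial
        scale estimate) with step-halving/doubling so the convex dispersion
        decreases monotonely.  Convergence is declared when the relative
        dispersion change falls below ``tol``.
        """
        y, xc = self.endog, self._xc
        beta, *_ = np.linalg.lstsq(xc, y - y.mean(), rcond=None)
        h = np.linalg.inv(xc.T @ xc)
        e = y - xc @ beta
        try:
            tau0 = wilcoxon_tau(e - np.median(e), self.nparams)
        except ValueError:
            tau0 = 1.0
        d = _dispersion(e)
        converged = False
        it = 0
        step = 1.0
        for it in range(1, maxiter + 1):
            g = xc.T @ _wilcoxon_scores_of(e)
            delta = tau0 * (h @ g)
            d_old = d
            s = min(step * 2.0, 4.0)
            while s > 1e-12:
                cand = beta + s * delta
                dn = _dispersion(y - xc @ cand)
                if dn < d_old:
                    beta, d, step = cand, dn, s
                    e = y - xc @ beta
                    break
                s /= 2.0
            else:  # no step length improves: at the minimum
                converged = True
                break
            if (d_old - d) <= tol * max(abs(d_old), 1.0):
                converged = True
                break
        intercept = float(np.median(e))
        disp = _dispersion(e)
        tau = wilcoxon_tau(e - intercept, self.nparams)
        return RankLMResults(model=self, params=beta, intercept=intercept,
                             dispersion=disp, tau=tau,
                             resid=e - intercept,
                             converged=converged, n_iter=it)


def _aliased_columns(X: np.ndarray, names) -> list:
    names = list(names) if names is not None else [f"x{i}" for i in range(X.shape[1])]
    keep: list[int] = []
    aliased = []
    for j in range(X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
        else:
            aliased.append(names[j])
    return aliased


def drop_in_dispersion(full: RankLMResults, reduced: RankLMResults):
    """F_phi test of the columns present in ``full`` but not ``reduced``.

    Returns (F, df1, df2, p, RD).  tau is taken from the full model.
    """
    q = full.model.nparams - reduced.model.nparams
    if q <= 0:
        raise ValueError("full model must have more columns than reduced model")
    rd = max(reduced.dispersion - full.dispersion, 0.0)
    df2 = full.model.nobs - full.model.nparams - 1
    f = (rd / q) / (full.tau / 2.0)
    p = float(stats.f.sf(f, q, df2))
    return f, q, df2, p, rd


# ---------------------------------------------------------------------------
# Factorial designs
# ---------------------------------------------------------------------------

def build_design(df: pd.DataFrame, terms):
    """Treatment-coded design blocks for main-effect and ``a:b``
    interaction terms.  Returns (X, column names, {term: column slice})."""
    blocks = {}
    names = {}
    for term in terms:
        if ":" in term:
            fa, fb = term.split(":")
            A, na = _dummy_block(df, fa)
            B, nb = _dummy_block(df, fb)
            cols = []
            cnames = []
            for i in range(A.shape[1]):
                for j in range(B.shape[1]):
                    cols.append(A[:, i] * B[:, j])
                    cnames.append(f"{na[i]}:{nb[j]}")
            blocks[term] = np.column_stack(cols)
            names[term] = cnames
        else:
            blocks[term], names[term] = _dummy_block(df, term)
    X = np.column_stack([blocks[t] for t in terms])
    all_names = [n for t in terms for n in names[t]]
    slices = {}
    start = 0
    for t in terms:
        k = blocks[t].shape[1]
        slices[t] = slice(start, start + k)
        start += k
    return X, all_names, slices


def _dummy_block(df: pd.DataFrame, factor: str):
    cat = df[factor].astype("category")
    levels = list(cat.cat.categories)
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has fewer than 2 levels")
    dm = pd.get_dummies(cat, prefix=factor, drop_first=True).to_numpy(float)
    return dm, [f"{factor}[{lv}]" for lv in levels[1:]]


@dataclass
class BalanceReport:
    """Cell counts and balance flag for a factorial design table."""

    balanced: bool
    cell_counts: pd.DataFrame = field(repr=False)
    incomplete_cells: pd.DataFrame = field(repr=False)

    def summary(self) -> str:
        lines = [f"balanced: {self.balanced}",
                 f"cells: {len(self.cell_counts)}",
                 f"incomplete cells: {len(self.incomplete_cells)}"]
        if len(self.incomplete_cells):
            lines.append(self.incomplete_cells.to_string(index=False))
        return "\n".join(lines)


def check_balance(design: pd.DataFrame, factors) -> BalanceReport:
    """Check that every factor-level combination has the same replicate
    count (a requirement of the factorial analyses here)."""
    counts = (design.groupby(list(factors), observed=True)
              .size().rename("n").reset_index())
    full = counts.set_index(list(factors)).reindex(
        pd.MultiIndex.from_product(
            [sorted(design[f].unique()) for f in factors], names=list(factors))
    )["n"].fillna(0).astype(int).reset_index()
    nmax = full["n"].max()
    incomplete = full[full["n"] < nmax]
    return BalanceReport(balanced=len(incomplete) == 0, cell_counts=full,
                         incomplete_cells=incomplete.reset_index(drop=True))


def apply_exclusion_rules(ledger: pd.DataFrame):
    """Apply the site-exclusion rules to a generation ledger.

    ``ledger`` has columns site, wg, gcm, rcp, success; baseline rows carry
    gcm = rcp = "baseline".  A site with any failed or missing future
    wg x gcm x rcp combination is dropped from the future analysis as a
    whole; a site with failures only in the baseline rows is dropped only
    from the baseline analysis.  Returns a dict with ``baseline_sites``,
    ``future_sites`` and the per-site drop reasons.
    """
    required = {"site", "wg", "gcm", "rcp", "success"}
    if not required <= set(ledger.columns):
        raise ValueError(f"ledger must have columns {sorted(required)}")
    is_base = (ledger["gcm"] == "baseline") & (ledger["rcp"] == "baseline")
    wgs = sorted(ledger["wg"].unique())
    fut = ledger[~is_base]
    combos = sorted(set(zip(fut["wg"], fut["gcm"], fut["rcp"])))
    baseline_sites, future_sites = [], []
    reasons = {}
    for site, grp in ledger.groupby("site"):
        gb = grp[(grp["gcm"] == "baseline")]
        ok_base = all(
            ((gb["wg"] == w) & gb["success"]).any() for w in wgs)
        gf = grp[~((grp["gcm"] == "baseline") & (grp["rcp"] == "baseline"))]
        ok_fut = all(
            ((gf["wg"] == w) & (gf["gcm"] == g) & (gf["rcp"] == r)
             & gf["success"]).any() for (w, g, r) in combos)
        if ok_base:
            baseline_sites.append(site)
        else:
            reasons.setdefault(site, []).append("baseline generation incomplete")
        if ok_fut:
            future_sites.append(site)
        else:
            reasons.setdefault(site, []).append("future combination failed or missing")
    return {"baseline_sites": baseline_sites, "future_sites": future_sites,
            "dropped": reasons}


# ---------------------------------------------------------------------------
# ANOVA drivers
# ---------------------------------------------------------------------------

def ranova_table(design: pd.DataFrame, response: str, factors,
                 interactions=None, enforce_balance: bool = True) -> pd.DataFrame:
    """Robust rank ANOVA over a factorial design table.

    ``design`` holds one row per replicate with a numeric ``response``
    column and categorical factor columns.  Main effects are tested by
    dropping each factor from the all-main-effects rank fit; each
    requested ``a:b`` interaction is tested by dropping it from the model
    with all mains and all requested interactions.  Refuses unbalanced
    designs (with the balance report) unless ``enforce_balance=False``.
    """
    factors = list(factors)
    interactions = list(interactions) if interactions else []
    if enforce_balance:
        rep = check_balance(design, factors)
        if not rep.balanced:
            raise ValueError("design is not balanced:\n" + rep.summary())
    y = design[response].to_numpy(float)
    mains = factors
    rows = []
    X_main, nm, _ = build_design(design, mains)
    full_main = RankLM(y, X_main, nm).fit()
    for t in mains:
        keep = [u for u in mains if u != t]
        if keep:
            Xr, nr, _ = build_design(design, keep)
            red = RankLM(y, Xr, nr).fit()
            f, q, df2, p, rd = drop_in_dispersion(full_main, red)
        else:
            q = X_main.shape[1]
            rd = max(_dispersion(y - np.median(y)) - full_main.dispersion, 0.0)
            df2 = full_main.model.nobs - q - 1
            f = (rd / q) / (full_main.tau / 2.0)
            p = float(stats.f.sf(f, q, df2))
        rows.append({"term": t, "stat": f, "df1": q, "df2": df2, "p": p,
                     "rd": rd, "tau": full_main.tau})
    if interactions:
        X_full, nf, _ = build_design(design, mains + interactions)
        full = RankLM(y, X_full, nf).fit()
        for t in interactions:
            keep = mains + [u for u in interactions if u != t]
            Xr, nr, _ = build_design(design, keep)
            red = RankLM(y, Xr, nr).fit()
            f, q, df2, p, rd = drop_in_dispersion(full, red)
            rows.append({"term": t, "stat": f, "df1": q, "df2": df2, "p": p,
                         "rd": rd, "tau": full.tau})
    return pd.DataFrame(rows)


def rank_transform_anova(design: pd.DataFrame, response: str, factors,
                         interactions=None,
                         enforce_balance: bool = True) -> pd.DataFrame:
    """Classical factorial F tests on midrank-transformed responses
    (cross-check method for :func:`ranova_table`; invariant to any
    monotone transform of the response)."""
    factors = list(factors)
    interactions = list(interactions) if interactions else []
    if enforce_balance:
        rep = check_balance(design, factors)
        if not rep.balanced:
            raise ValueError("design is not balanced:\n" + rep.summary())
    y = stats.rankdata(design[response].to_numpy(float))

    def rss(X):
        Xi = np.column_stack([np.ones(len(y)), X])
        beta, *_ = np.linalg.lstsq(Xi, y, rcond=None)
        r = y - Xi @ beta
        return float(r @ r), Xi.shape[1]

    rows = []

    def ftest(term, X_full, X_red):
        rss_f, p_f = rss(X_full)
        rss_r, p_r = rss(X_red) if X_red is not None else (float(np.sum((y - y.mean()) ** 2)), 1)
        q = p_f - p_r
        df2 = len(y) - p_f
        f = ((rss_r - rss_f) / q) / (rss_f / df2)
        rows.append({"term": term, "stat": f, "df1": q, "df2": df2,
                     "p": float(stats.f.sf(f, q, df2))})

    X_main, _, _ = build_design(design, factors)
    for t in factors:
        keep = [u for u in factors if u != t]
        Xr = build_design(design, keep)[0] if keep else None
        ftest(t, X_main, Xr)
    if interactions:
        X_full, _, _ = build_design(design, factors + interactions)
        for t in interactions:
            keep = factors + [u for u in interactions if u != t]
            ftest(t, X_full, build_design(design, keep)[0])
    return pd.DataFrame(rows)


def ranova_by_index(table: pd.DataFrame, response: str, factors,
                    interactions=None, method: str = "rank",
                    enforce_balance: bool = True) -> pd.DataFrame:
    """Run an ANOVA per index code over a long-form table with a ``code``
    column; returns rows ``index_code, term, stat, df1, df2, p``."""
    driver = ranova_table if method == "rank" else rank_transform_anova
    out = []
    for code, grp in table.groupby("code"):
        grp = grp.dropna(subset=[response])
        if grp[response].nunique() < 3:
            continue  # degenerate index (constant response)
        try:
            res = driver(grp.reset_index(drop=True), response, factors,
                         interactions, enforce_balance=enforce_balance)
        except ValueError:
            continue
        res.insert(0, "index_code", code)
        out.append(res)
    return pd.concat(out, ignore_index=True) if out else pd.DataFrame(
        columns=["index_code", "term", "stat", "df1", "df2", "p"])
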