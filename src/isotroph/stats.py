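"""Classical univariate tests for between-species and between-site comparisons.

Covers the fixed-effects two-way ANOVA with sequential (type-I) sums of
squares on an unbalanced species x site design (the interaction is
restricted to the cells the data support), Welch's unequal-variance one-way
F, Bartlett's variance-homogeneity test, Welch's two-sample t, and Pearson
correlation of species means between sites with a leave-one-out influence
report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError

__all__ = [
    "AnovaTable",
    "two_way_anova",
    "TestResult",
    "welch_oneway",
    "bartlett",
    "welch_t",
    "site_correlation",
]


@dataclass(frozen=True)
class AnovaRow:
    term: str
    df: int
    ss: float
    F: float
    p: float


@dataclass(frozen=True)
class AnovaTable:
    rows: tuple[AnovaRow, ...]
    df_resid: int
    ss_resid: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [{"term": r.term, "df": r.df, "SS": r.ss, "F": r.F, "p": r.p} for r in self.rows]
        )
        df.loc[len(df)] = {
            "term": "Residuals", "df": self.df_resid, "SS": self.ss_resid,
            "F": np.nan, "p": np.nan,
        }
        return df

    def __getitem__(self, term: str) -> AnovaRow:
        for r in self.rows:
            if r.term == term:
                return r
        raise KeyError(term)


def _dummies(levels: pd.Series) -> np.ndarray:
    return pd.get_dummies(levels.astype(str), dtype=float).to_numpy()


def _rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def two_way_anova(values, species, site) -> AnovaTable:
    """Sequential-SS two-way fixed-effects ANOVA: species, then site, then
    their interaction, each F-tested against the residual mean square.

    The design may be unbalanced with empty species:site cells (species
    sampled at one site only); the interaction automatically carries only
    the degrees of freedom the observed cells support, which is reported via
    the interaction row's df.
    """
    y = np.asarray(values, dtype=float)
    sp = pd.Series(species).astype(str).reset_index(drop=True)
    si = pd.Series(site).astype(str).reset_index(drop=True)
    if len(y) != len(sp) or len(y) != len(si):
        raise AnalysisError("values, species and site must have equal length")
    if sp.nunique() < 2 or si.nunique() < 2:
        raise AnalysisError("need at least 2 levels per factor")
    n = len(y)
    one = np.ones((n, 1))
    X_sp = np.hstack([one, _dummies(sp)])
    X_add = np.hstack([X_sp, _dummies(si)])
    cells = sp.str.cat(si, sep="\x1f")
    X_full = np.hstack([one, _dummies(cells)])

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    rss_sp, rank_sp = _rss(X_sp, y)
    rss_add, rank_add = _rss(X_add, y)
    rss_full, rank_full = _rss(X_full, y)
    df_resid = n - rank_full
    if df_resid <= 0:
        raise AnalysisError("no residual degrees of freedom")
    ms_resid = rss_full / df_resid

    def row(term: str, ss: float, df: int) -> AnovaRow:
        ss = max(ss, 0.0)
        if df <= 0:
            return AnovaRow(term, df, ss, np.nan, np.nan)
        F = (ss / df) / ms_resid if ms_resid > 0 else 0.0
        p = float(stats.f.sf(F, df, df_resid)) if ms_resid > 0 else 1.0
        return AnovaRow(term, df, ss, float(F), p)

    rows = (
        row("species", ss_tot - rss_sp, rank_sp - 1),
        row("site", rss_sp - rss_add, rank_add - rank_sp),
        row("species:site", rss_add - rss_full, rank_full - rank_add),
    )
    return AnovaTable(rows=rows, df_resid=df_resid, ss_resid=rss_full)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | tuple[float, float]
    p: float
    method: str
    extra: dict | None = None


def _group_arrays(values, groups, min_n: int = 2) -> list[np.ndarray]:
    y = np.asarray(values, dtype=float)
    g = pd.Series(groups).astype(str).reset_index(drop=True)
    arrays = [y[(g == lev).to_numpy()] for lev in g.unique()]
    if len(arrays) < 2:
        raise AnalysisError("need at least 2 groups")
    for a in arrays:
        if len(a) < min_n:
            raise AnalysisError(f"every group needs n >= {min_n}")
    return arrays


def welch_oneway(values, groups) -> TestResult:
    """Welch's unequal-variance one-way F with Satterthwaite-style
    denominator degrees of freedom."""
    arrays = _group_arrays(values, groups)
    k = len(arrays)
    ns = np.array([len(a) for a in arrays], dtype=float)
    means = np.array([a.mean() for a in arrays])
    variances = np.array([a.var(ddof=1) for a in arrays])
    if np.any(variances == 0):
        import warnings

        warnings.warn("a group has zero variance; Welch F may be unstable")
    with np.errstate(divide="ignore"):
        w = ns / variances
    if not np.all(np.isfinite(w)):
        raise AnalysisError("Welch F undefined with a zero-variance group")
    grand = np.sum(w * means) / np.sum(w)
    a = np.sum(w * (means - grand) ** 2) / (k - 1)
    lam = np.sum((1 - w / np.sum(w)) ** 2 / (ns - 1))
    F = a / (1 + 2 * (k - 2) * lam / (k**2 - 1))
    df2 = (k**2 - 1) / (3 * lam)
    p = float(stats.f.sf(F, k - 1, df2))
    return TestResult(float(F), (float(k - 1), float(df2)), p, "welch-oneway-anova")


def bartlett(values, groups) -> TestResult:
    """Bartlett's K-squared for homogeneity of group variances (k-1 df)."""
    arrays = _group_arrays(values, groups)
    for a in arrays:
        if a.var(ddof=1) == 0:
            raise AnalysisError("Bartlett's test undefined with a zero-variance group")
    stat, p = stats.bartlett(*arrays)
    return TestResult(float(stat), float(len(arrays) - 1), float(p), "bartlett")


def welch_t(x, y) -> TestResult:
    """Welch's two-sample t with Welch-Satterthwaite df, two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise AnalysisError("both samples need n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            raise AnalysisError("t undefined: zero variance and equal means")
    se2 = vx / len(x) + vy / len(y)
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / (vx**2 / (len(x) ** 2 * (len(x) - 1)) + vy**2 / (len(y) ** 2 * (len(y) - 1)))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TestResult(float(t), float(df), p, "welch-t")


def site_correlation(
    means_site1, means_site2, *, labels=None, leave_one_out: bool = False
) -> TestResult:
    """Pearson correlation of shared-species means between two sites.

    With ``leave_one_out`` the result's ``extra`` reports, for each species,
    the correlation after removing it, and names the removal that maximizes
    |r| — a quick influence diagnostic for outlier species.
    """
    x = np.asarray(means_site1, dtype=float)
    y = np.asarray(means_site2, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise AnalysisError("need aligned vectors of at least 3 shared species")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AnalysisError("correlation undefined: zero variance")
    r, p = stats.pearsonr(x, y)
    extra = None
    if leave_one_out:
        names = list(labels) if labels is not None else [str(i) for i in range(len(x))]
        loo = {}
        for i in range(len(x)):
            keep = np.arange(len(x)) != i
            if np.ptp(x[keep]) == 0 or np.ptp(y[keep]) == 0:
                continue
            ri, pi = stats.pearsonr(x[keep], y[keep])
            loo[names[i]] = {"r": float(ri), "p": float(pi)}
        influential = max(loo, key=lambda k: abs(loo[k]["r"])) if loo else None
        extra = {"leave_one_out": loo, "most_influential": influential}
    return TestResult(float(r), float(len(x) - 2), float(p), "pearson", extra)
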