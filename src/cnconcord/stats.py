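"""Association statistics between copy number and expression Z-scores.

Spearman's rho is computed as the Pearson correlation of the midrank-
transformed variables (average ranks for ties).  Per-gene linearity is
summarized by an ordinary least-squares fit of the median Z-score at
each observed call level against the level itself, one unweighted point
per level.  Group comparisons use Welch's unequal-variance t with
Welch-Satterthwaite degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import CALL_LEVELS


def spearman_rho(x, y) -> float:
    """Spearman correlation as Pearson-on-midranks.

    Pairs with a missing value in either vector are dropped first.
    Returns NaN when fewer than 3 complete pairs remain or either rank
    vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        return np.nan
    rx = sps.rankdata(x, method="average")
    ry = sps.rankdata(y, method="average")
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r: float
    n_levels: int
    p: float = np.nan
    level_medians: dict | None = None


def median_z_fit(calls_row, z_row) -> LinearFit:
    """OLS of median Z per observed copy-number level against the level.

    One unweighted point per observed level regardless of how many
    samples sit at it; undefined (NaN in all fields except n_levels)
    when fewer than 3 distinct levels carry a defined Z-score.
    """
    c = np.asarray(calls_row, dtype=float)
    z = np.asarray(z_row, dtype=float)
    keep = np.isfinite(c) & np.isfinite(z)
    c, z = c[keep], z[keep]
    levels = []
    medians = []
    for level in CALL_LEVELS:
        at = z[c == level]
        if at.size:
            levels.append(level)
            medians.append(float(np.median(at)))
    n_levels = len(levels)
    if n_levels < 3:
        return LinearFit(np.nan, np.nan, np.nan, n_levels)
    lv = np.asarray(levels, dtype=float)
    md = np.asarray(medians, dtype=float)
    slope, intercept = np.polyfit(lv, md, 1)
    r = _pearson(lv, md)
    # two-sided p of the slope, t-test with n_levels - 2 df
    p = np.nan
    if n_levels > 2 and np.isfinite(r):
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * np.sqrt((n_levels - 2) / (1 - r * r))
            p = float(2 * sps.t.sf(abs(t), n_levels - 2))
    return LinearFit(float(slope), float(intercept), r, n_levels, p,
                     dict(zip(levels, medians)))


@dataclass
class GroupComparison:
    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    var_a: float
    var_b: float
    n_a: int
    n_b: int


def welch_t(a, b) -> GroupComparison:
    """Welch's unequal-variance two-sample t-test (two-sided).

    t = (m_a - m_b) / sqrt(s_a^2/n_a + s_b^2/n_b) with sample (n-1)
    variances; degrees of freedom by Welch-Satterthwaite.  Degenerate
    zero-variance groups: equal means give t = 0, p = 1; unequal means
    give infinite t, p = 0 (flagged by df = inf-safe NaN).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError(f"each group needs >= 2 values, got {na} and {nb}")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    if se2 == 0:
        if ma == mb:
            return GroupComparison(0.0, np.nan, 1.0, ma, mb, va, vb, na, nb)
        t = np.inf if ma > mb else -np.inf
        return GroupComparison(t, np.nan, 0.0, ma, mb, va, vb, na, nb)
    t = (ma - mb) / np.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = float(2 * sps.t.sf(abs(t), df))
    return GroupComparison(float(t), float(df), p, ma, mb, va, vb, na, nb)


def gene_associations(calls: pd.DataFrame, z: pd.DataFrame,
                      valid_genes: pd.Index | None = None) -> pd.DataFrame:
    """Per-gene Spearman rho and median-Z linear-fit summaries.

    Returns a frame indexed by gene with columns rho, fit_r, fit_slope,
    fit_intercept, n_levels; genes outside ``valid_genes`` get NaN rows.
    """
    if not calls.index.equals(z.index) or not calls.columns.equals(z.columns):
        raise ValueError("call and z matrices must share gene/sample indices")
    if valid_genes is None:
        valid = np.ones(len(calls.index), dtype=bool)
    else:
        valid = calls.index.isin(valid_genes)
    c = calls.to_numpy(dtype=float)
    zz = z.to_numpy(dtype=float)
    rows = np.full((len(calls.index), 5), np.nan)
    for i in range(len(calls.index)):
        if not valid[i]:
            continue
        rows[i, 0] = spearman_rho(c[i], zz[i])
        fit = median_z_fit(c[i], zz[i])
        rows[i, 1:] = (fit.r, fit.slope, fit.intercept, fit.n_levels)
    out = pd.DataFrame(
        rows, index=calls.index,
        columns=["rho", "fit_r", "fit_slope", "fit_intercept", "n_levels"])
    return out


def cohort_fit(z: pd.DataFrame, calls: pd.DataFrame,
               valid_genes: pd.Index | None = None) -> LinearFit:
    """Pooled median-Z-per-level regression over all valid genes.

    All defined Z-scores of valid genes at each call level are pooled,
    the per-level median is taken, and the OLS line through the
    (level, median) points summarizes the cohort-wide dosage effect.
    """
    if valid_genes is not None:
        keep = calls.index.isin(valid_genes)
        calls = calls.loc[keep]
        z = z.loc[keep]
    c = calls.to_numpy(dtype=float).ravel()
    zz = z.to_numpy(dtype=float).ravel()
    return median_z_fit(c, zz)


def positive_rho_fraction(assoc: pd.DataFrame) -> float:
    """Fraction of genes with rho > 0 among genes with defined rho."""
    rho = assoc["rho"].to_numpy(dtype=float)
    defined = np.isfinite(rho)
    if defined.sum() == 0:
        return np.nan
    return float((rho[defined] > 0).mean())


def cross_dataset_agreement(assoc_a: pd.DataFrame,
                            assoc_b: pd.DataFrame) -> dict:
    """Quadrant agreement of per-gene rho between two cohorts.

    Joins on shared gene symbols with defined rho in both and reports
    the both-positive and both-negative fractions.
    """
    joined = assoc_a[["rho"]].join(assoc_b[["rho"]], how="inner",
                                   lsuffix="_a", rsuffix="_b").dropna()
    n = len(joined)
    if n == 0:
        return {"n_shared": 0, "both_positive": np.nan, "both_negative": np.nan}
    a = joined["rho_a"].to_numpy()
    b = joined["rho_b"].to_numpy()
    return {
        "n_shared": n,
        "both_positive": float(((a > 0) & (b > 0)).mean()),
        "both_negative": float(((a < 0) & (b < 0)).mean()),
    }
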