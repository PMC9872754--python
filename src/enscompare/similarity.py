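"""Distributional similarity of cross-species expression profiles.

After ortholog-anchored normalization, the question "does the pig region
look like the matching human region?" is asked of whole expression
distributions, not individual genes: empirical CDFs of per-gene mean
expression are compared by the two-sample Kolmogorov-Smirnov test and a
Pearson chi-squared homogeneity test on pooled-quantile bins, and
region-by-region agreement of the ortholog vectors is summarized with
Spearman correlation matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ECDFProfile:
    """An empirical CDF: F(x) = (# values <= x) / n."""

    sorted_values: np.ndarray

    def __call__(self, x) -> np.ndarray | float:
        res = np.searchsorted(self.sorted_values, x, side="right") / len(
            self.sorted_values
        )
        return res

    @property
    def n(self) -> int:
        return len(self.sorted_values)


@dataclass
class SimilarityReport:
    ks_statistic: float
    ks_p: float
    chisq_statistic: float
    chisq_p: float
    n_bins: int
    spearman_rho: float
    spearman_p: float


def ecdf(values) -> ECDFProfile:
    vals = np.asarray(values, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("ecdf needs at least one finite value")
    return ECDFProfile(np.sort(vals))


def ks_compare(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov: D = sup |F_x - F_y| and two-sided p."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("ks_compare needs non-empty samples")
    res = stats.ks_2samp(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def chisq_compare(x, y, n_bins: int = 10) -> tuple[float, float, int]:
    """Pearson chi-squared homogeneity test on pooled-quantile bins.

    Bin edges are quantiles of the pooled sample, so under the null each
    bin collects a similar share of both samples; the statistic is the
    uncorrected chi-squared on the resulting 2 x n_bins count table
    (df = n_bins - 1). Bins are automatically reduced (with a warning)
    until every expected count is at least 1. Returns
    (statistic, p, n_bins_used).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("chisq_compare needs non-empty samples")
    pooled = np.concatenate([x, y])
    k = int(n_bins)
    while k >= 2:
        edges = np.quantile(pooled, np.linspace(0, 1, k + 1))
        edges = np.unique(edges)
        if len(edges) < 3:
            break
        edges[0], edges[-1] = -np.inf, np.inf
        cx, _ = np.histogram(x, bins=edges)
        cy, _ = np.histogram(y, bins=edges)
        table = np.vstack([cx, cy])
        expected = (
            table.sum(axis=1, keepdims=True)
            * table.sum(axis=0, keepdims=True)
            / table.sum()
        )
        if (expected >= 1).all():
            if table.shape[1] != n_bins:
                warnings.warn(
                    f"reduced to {table.shape[1]} bins (requested {n_bins})",
                    stacklevel=2,
                )
            res = stats.chi2_contingency(table, correction=False)
            return float(res[0]), float(res[1]), table.shape[1]
        k -= 1
    raise ValueError("too few observations to form 2 valid quantile bins")


def spearman_pairwise(
    values: pd.DataFrame, grouping: pd.Series | None = None, exact_below: int = 10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rho/p matrix over samples (or over group-mean profiles).

    Each column of ``values`` is a gene vector (shared orthologous gene
    index); when ``grouping`` maps samples to groups (e.g. species-region),
    columns are first averaged within each group. Returns symmetric
    (rho, p) DataFrames with unit diagonal. Constant vectors yield NaN.
    p-values use the t-approximation; for vectors shorter than
    ``exact_below`` genes an exact permutation p is computed instead.
    """
    if grouping is not None:
        values = values.T.groupby(grouping.reindex(values.columns)).mean().T
    cols = list(values.columns)
    n = len(cols)
    if values.shape[0] < 3:
        raise ValueError("need at least 3 shared genes")
    rho = pd.DataFrame(np.eye(n), index=cols, columns=cols)
    pmat = pd.DataFrame(np.zeros((n, n)), index=cols, columns=cols)
    for i in range(n):
        for j in range(i + 1, n):
            xi = values.iloc[:, i].to_numpy(dtype=float)
            xj = values.iloc[:, j].to_numpy(dtype=float)
            if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                r, p = np.nan, np.nan
            elif len(xi) < exact_below:
                res = stats.permutation_test(
                    (xi,),
                    lambda x: stats.spearmanr(x, xj).statistic,
                    permutation_type="pairings",
                    alternative="two-sided",
                    n_resamples=np.inf,
                )
                r = float(res.statistic)
                p = float(res.pvalue)
            else:
                res = stats.spearmanr(xi, xj)
                r, p = float(res.statistic), float(res.pvalue)
            rho.iloc[i, j] = rho.iloc[j, i] = r
            pmat.iloc[i, j] = pmat.iloc[j, i] = p
    return rho, pmat


def compare_profiles(x, y, n_bins: int = 10) -> SimilarityReport:
    """Full similarity report for two per-gene mean expression profiles."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    d, ks_p = ks_compare(x, y)
    chi, chi_p, used = chisq_compare(x, y, n_bins=n_bins)
    if len(x) == len(y) and len(x) >= 3 and np.ptp(x) > 0 and np.ptp(y) > 0:
        sp = stats.spearmanr(x, y)
        rho, sp_p = float(sp.statistic), float(sp.pvalue)
    else:
        rho, sp_p = np.nan, np.nan
    return SimilarityReport(d, ks_p, chi, chi_p, used, rho, sp_p)
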