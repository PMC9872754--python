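"""Expression normalization for cross-species comparison.

Implements the normalization chain used to put two species' bulk RNA-seq
profiles on a common scale: RPKM from raw counts, log2 transformation,
selection of genes whose expression ranks are conserved across samples
(restricted to genes inside every sample's inner quartile range), and the
median-anchored scaling in which every sample is rescaled so that its
median expression over the rank-conserved genes equals the across-sample
average of those medians (the Brawand-style procedure).

A deliberately simple per-gene differential-expression test (Welch t or
Wilcoxon rank-sum with Benjamini-Hochberg correction) is provided as
pipeline plumbing; externally computed DEG tables are accepted as
first-class input wherever a DEGList is consumed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

SPACE = Literal["rpkm", "log2rpkm", "scaled"]


@dataclass
class CountMatrix:
    """Raw gene x sample read counts with the study-design metadata.

    counts: non-negative integer DataFrame (genes x samples).
    gene_length_bp: per-gene length in base pairs (positive).
    total_mapped: per-sample total mapped reads (positive).
    sample_meta: per-sample DataFrame with columns like species, region
        (pC/tC/dC or aC/tC/dC), plexus (MG/ISG), condition (naive/VNS).
    """

    counts: pd.DataFrame
    gene_length_bp: pd.Series
    total_mapped: pd.Series
    sample_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts contain negative entries")
        self.gene_length_bp = self.gene_length_bp.reindex(self.counts.index)
        if self.gene_length_bp.isna().any() or (self.gene_length_bp <= 0).any():
            bad = self.gene_length_bp.index[
                self.gene_length_bp.isna() | (self.gene_length_bp <= 0)
            ][0]
            raise ValueError(f"gene {bad!r}: non-positive or missing length")
        self.total_mapped = self.total_mapped.reindex(self.counts.columns)
        if self.total_mapped.isna().any() or (self.total_mapped <= 0).any():
            bad = self.total_mapped.index[
                self.total_mapped.isna() | (self.total_mapped <= 0)
            ][0]
            raise ValueError(f"sample {bad!r}: non-positive or missing total mapped reads")
        under = self.total_mapped < self.counts.sum(axis=0)
        if under.any():
            warnings.warn(
                f"total_mapped below column sum for samples: "
                f"{list(self.total_mapped.index[under])}",
                stacklevel=2,
            )


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with an explicit value space."""

    values: pd.DataFrame
    space: SPACE
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.space == "rpkm" and (self.values.to_numpy() < 0).any():
            raise ValueError("rpkm space must be non-negative")


@dataclass
class ScalingResult:
    """Record of the median-anchored cross-species scaling."""

    conserved_genes: list[str]
    sample_median: pd.Series
    common_value: float
    factor: pd.Series


def rpkm(cm: CountMatrix) -> ExpressionMatrix:
    """Reads per kilobase of gene per million mapped reads.

    value = reads * 1e3 * 1e6 / (total_mapped * gene_length_bp).
    """
    reads = cm.counts.to_numpy(dtype=float)
    length = cm.gene_length_bp.to_numpy(dtype=float)[:, None]
    total = cm.total_mapped.to_numpy(dtype=float)[None, :]
    vals = reads * 1e3 * 1e6 / (total * length)
    out = pd.DataFrame(vals, index=cm.counts.index, columns=cm.counts.columns)
    return ExpressionMatrix(out, space="rpkm", provenance=["rpkm"])


def log2_transform(em: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(value + pseudocount); accepts rpkm or median-scaled rpkm."""
    if em.space not in ("rpkm", "scaled"):
        raise ValueError(f"log2_transform expects rpkm/scaled space, got {em.space!r}")
    if (em.values.to_numpy() < 0).any():
        raise ValueError("negative values cannot be log-transformed")
    out = np.log2(em.values + pseudocount)
    return ExpressionMatrix(
        out, space="log2rpkm", provenance=em.provenance + [f"log2(+{pseudocount})"]
    )


def select_rank_conserved(em: ExpressionMatrix, n_genes: int) -> list[str]:
    """Genes with the most conserved expression ranks across samples.

    Eligibility: the gene's value lies within [Q1, Q3] of that sample's
    expression distribution in *every* sample. Conservation score: the
    variance across samples of the gene's within-sample rank (average rank
    for ties). The ``n_genes`` smallest scores win; ties break by gene
    identifier order.
    """
    vals = em.values
    if vals.shape[1] < 2:
        raise ValueError("rank conservation needs at least 2 samples")
    q1 = vals.quantile(0.25, axis=0)
    q3 = vals.quantile(0.75, axis=0)
    eligible = ((vals >= q1) & (vals <= q3)).all(axis=1)
    pool = vals.index[eligible]
    if n_genes > len(pool):
        raise ValueError(
            f"requested {n_genes} rank-conserved genes but only "
            f"{len(pool)} genes are inside the inner quartile range of every sample"
        )
    ranks = vals.rank(axis=0, method="average")
    score = ranks.loc[pool].var(axis=1, ddof=1)
    # stable sort after an index sort breaks score ties by gene identifier
    score = score.sort_index().sort_values(kind="mergesort")
    return list(score.index[:n_genes])


def cross_species_scale(
    em: ExpressionMatrix, conserved: Sequence[str]
) -> tuple[ExpressionMatrix, ScalingResult]:
    """Rescale each sample so its conserved-gene median hits a common value.

    The common value is the across-sample average of per-sample medians of
    the conserved genes; sample i's factor is common / median_i and every
    value in sample i is multiplied by it.
    """
    conserved = list(conserved)
    missing = set(conserved) - set(em.values.index)
    if missing:
        raise ValueError(f"conserved genes absent from matrix: {sorted(missing)[:5]}")
    med = em.values.loc[conserved].median(axis=0)
    zero = med <= 0
    if zero.any():
        raise ValueError(
            f"non-positive conserved-gene median in sample {med.index[zero][0]!r}"
        )
    common = float(med.mean())
    factor = common / med
    out = em.values * factor
    res = ScalingResult(
        conserved_genes=conserved,
        sample_median=med,
        common_value=common,
        factor=factor,
    )
    scaled = ExpressionMatrix(
        out,
        space="scaled",
        provenance=em.provenance + [f"median-scaled in {em.space} space"],
    )
    return scaled, res


def _moderated_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-group moderated t: per-gene pooled variances shrunk toward a
    common prior fitted by Smyth's method of moments on log variances.

    The posterior variance (d0*s0^2 + d_g*s_g^2)/(d0 + d_g) replaces the
    per-gene estimate; the t statistic gains d0 extra degrees of freedom.
    With thousands of genes sharing a noise regime this recovers most of
    the power a per-gene Welch test loses to 6-vs-6 variance estimation.
    """
    from scipy.special import digamma, polygamma

    na, nb = a.shape[1], b.shape[1]
    dg = na + nb - 2
    s2 = (a.var(axis=1, ddof=1) * (na - 1) + b.var(axis=1, ddof=1) * (nb - 1)) / dg
    s2 = np.maximum(s2, 1e-12)
    z = np.log(s2)
    e = z - digamma(dg / 2) + np.log(dg / 2)
    ev = max(np.var(e, ddof=1) - polygamma(1, dg / 2), 0.0)
    if ev <= 1e-12:
        d0 = np.inf
        s0_2 = np.exp(np.mean(e))
    else:
        # invert trigamma by Newton iteration (limma's approach)
        y = 0.5 + 1.0 / ev
        for _ in range(50):
            tri = polygamma(1, y)
            delta = tri * (1 - tri / ev) / polygamma(2, y)
            y += delta
            if abs(delta) < 1e-8:
                break
        d0 = 2 * y
        s0_2 = np.exp(np.mean(e) + digamma(y) - np.log(y))
    if np.isinf(d0):
        post = np.full_like(s2, s0_2)
        df = 1e6
    else:
        post = (d0 * s0_2 + dg * s2) / (d0 + dg)
        df = d0 + dg
    t = (a.mean(axis=1) - b.mean(axis=1)) / np.sqrt(post * (1 / na + 1 / nb))
    return 2 * stats.t.sf(np.abs(t), df)


def simple_de(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    method: Literal["moderated", "welch", "wilcoxon"] = "moderated",
) -> pd.DataFrame:
    """Per-gene two-group test with BH correction (pipeline plumbing).

    Expects log-space expression. Returns a DataFrame indexed by gene with
    columns ``direction`` (up/down, A relative to B), ``lfc`` (difference
    of group means), ``p`` and ``q``. The default "moderated" method
    shrinks per-gene variances toward a fitted common prior before the t
    test (the standard remedy for few-replicate designs); "welch" and
    "wilcoxon" run gene-wise without sharing information. Constant genes
    get p=1 with a warning. This is a deliberately simple stand-in for a
    dedicated count-model DE method; externally computed DEG tables can be
    used in its place everywhere downstream.
    """
    if group_a.shape[1] < 2 or group_b.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    common = group_a.index.intersection(group_b.index)
    a = group_a.loc[common].to_numpy(dtype=float)
    b = group_b.loc[common].to_numpy(dtype=float)
    lfc = a.mean(axis=1) - b.mean(axis=1)

    if method == "moderated":
        p = _moderated_t(a, b)
        constant = np.ptp(a, axis=1) + np.ptp(b, axis=1) == 0
        if constant.any():
            warnings.warn(
                f"{int(constant.sum())} constant genes; p set to 1", stacklevel=2
            )
            p = np.where(constant, 1.0, p)
    elif method == "welch":
        with np.errstate(divide="ignore", invalid="ignore"):
            _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
        constant = np.isnan(p)
        if constant.any():
            warnings.warn(
                f"{int(constant.sum())} constant genes under Welch; p set to 1",
                stacklevel=2,
            )
            p = np.where(constant, 1.0, p)
    elif method == "wilcoxon":
        p = np.empty(len(common))
        for i in range(len(common)):
            if np.ptp(np.concatenate([a[i], b[i]])) == 0:
                p[i] = 1.0
            else:
                p[i] = stats.mannwhitneyu(a[i], b[i], alternative="two-sided").pvalue
    else:
        raise ValueError(f"unknown method {method!r}")

    _, q, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {
            "direction": np.where(lfc >= 0, "up", "down"),
            "lfc": lfc,
            "p": p,
            "q": q,
        },
        index=common,
    )


def read_deg_tsv(path) -> pd.DataFrame:
    """Read an externally computed DEG table (gene, direction, lfc, p, q)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df = df.set_index("gene")
    required = {"direction", "lfc", "p", "q"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"DEG table missing columns: {sorted(missing)}")
    return df
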