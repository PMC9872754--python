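"""Single-cell summaries around (not inside) the clustering.

Cluster labels are consumed as given — the upstream normalization,
integration and graph clustering are out of scope. What lives here: the
QC gates (detected-gene band, mitochondrial-fraction cap, minimum cells
per gene), one-vs-rest Wilcoxon marker finding with a log-fold-change
floor, matching cell-type marker lists to bulk DEG lists, directed
ligand-receptor interaction calls between cell subsets with a
VNS-response flag, and the exact-binomial calculator for how many cells
must be captured to see every rare cell type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class CellMatrix:
    """UMI counts (genes x cells) with per-cell metadata and mito flags."""

    counts: pd.DataFrame
    cell_meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    mito_genes: frozenset = frozenset()

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("UMI counts must be non-negative")
        self.mito_genes = frozenset(self.mito_genes) & set(self.counts.index)


@dataclass
class LRPair:
    ligand: str
    receptor: str

    def __post_init__(self) -> None:
        if not self.ligand or not self.receptor:
            raise ValueError("ligand and receptor identifiers must be non-empty")


@dataclass
class InteractionCall:
    source: str
    target: str
    pair: LRPair
    present: bool
    vns_up: bool = False
    ligand_p_naive: float | None = None
    ligand_p_vns: float | None = None
    receptor_p_naive: float | None = None
    receptor_p_vns: float | None = None


def qc_filter(
    cm: CellMatrix,
    min_genes: int = 200,
    max_genes: int = 2500,
    max_mito_pct: float = 5.0,
    min_cells_per_gene: int = 3,
) -> CellMatrix:
    """Standard droplet QC: keep cells with a detected-gene count in
    [min_genes, max_genes] and a mitochondrial UMI share <= max_mito_pct;
    then keep genes detected (count > 0) in at least min_cells_per_gene of
    the surviving cells."""
    counts = cm.counts
    detected = (counts > 0).sum(axis=0)
    total = counts.sum(axis=0)
    mito = counts.loc[sorted(cm.mito_genes)].sum(axis=0) if cm.mito_genes else 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_pct = np.where(total > 0, 100.0 * mito / total, 0.0)
    keep_cells = (
        (detected >= min_genes) & (detected <= max_genes) & (mito_pct <= max_mito_pct)
    )
    if not keep_cells.any():
        raise ValueError("QC removed every cell")
    sub = counts.loc[:, keep_cells]
    keep_genes = (sub > 0).sum(axis=1) >= min_cells_per_gene
    sub = sub.loc[keep_genes]
    meta = (
        cm.cell_meta.loc[sub.columns]
        if len(cm.cell_meta)
        else cm.cell_meta
    )
    return CellMatrix(sub, meta, cm.mito_genes & set(sub.index))


def _log_normalize(counts: pd.DataFrame, scale: float = 1e4) -> pd.DataFrame:
    """Library-size normalize to ``scale`` counts per cell, then ln(1+x)."""
    total = counts.sum(axis=0)
    total = total.replace(0, 1)
    return np.log1p(counts / total * scale)


def find_markers(
    cm: CellMatrix,
    labels: pd.Series,
    min_logfc: float = 0.25,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon marker genes per cluster.

    Expression is library-size normalized and ln(1+x) transformed;
    avg_logfc is the natural-log fold change ln((mean_in + eps) /
    (mean_rest + eps)) of the de-logged normalized expression. Only rows
    with avg_logfc > min_logfc are reported, with BH q-values computed
    over each cluster's full gene family before the threshold is applied.
    Clusters with fewer than 3 cells are skipped with a warning.
    """
    labels = labels.reindex(cm.counts.columns)
    if labels.isna().any():
        raise ValueError("labels must cover every cell")
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    norm = _log_normalize(cm.counts)
    expm = np.expm1(norm)
    eps = 1e-9
    rows = []
    for cl in clusters:
        in_mask = (labels == cl).to_numpy()
        if in_mask.sum() < 3:
            warnings.warn(f"cluster {cl!r} has <3 cells; skipped", stacklevel=2)
            continue
        x_in = norm.loc[:, in_mask].to_numpy()
        x_out = norm.loc[:, ~in_mask].to_numpy()
        mean_in = expm.loc[:, in_mask].mean(axis=1).to_numpy()
        mean_out = expm.loc[:, ~in_mask].mean(axis=1).to_numpy()
        lfc = np.log((mean_in + eps) / (mean_out + eps))
        p = np.ones(len(norm))
        for i in range(len(norm)):
            if np.ptp(np.concatenate([x_in[i], x_out[i]])) > 0:
                p[i] = stats.mannwhitneyu(
                    x_in[i], x_out[i], alternative="two-sided"
                ).pvalue
        _, q, _, _ = multipletests(p, method="fdr_bh")
        sel = lfc > min_logfc
        for g, l, pv, qv in zip(norm.index[sel], lfc[sel], p[sel], q[sel]):
            rows.append({"cluster": cl, "gene": g, "avg_logfc": l, "p": pv, "q": qv})
    return pd.DataFrame(rows, columns=["cluster", "gene", "avg_logfc", "p", "q"])


def celltype_deg_lists(
    markers: pd.DataFrame,
    deg_list: pd.DataFrame,
    p_cut: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Per-cell-type DEG lists: each cluster's marker genes intersected
    with the bulk DEG list at p < p_cut, directions inherited from bulk."""
    degs = deg_list[deg_list["p"] < p_cut]
    out = {}
    for cl, sub in markers.groupby("cluster"):
        shared = [g for g in sub["gene"] if g in degs.index]
        out[cl] = degs.loc[shared]
    return out


def call_interactions(
    cm: CellMatrix,
    labels: pd.Series,
    lr_pairs: Iterable[LRPair],
    min_expr_fraction: float = 0.1,
) -> list[InteractionCall]:
    """Directed ligand-receptor calls between cell subsets.

    Call (A -> B, pair) is present iff the ligand is detected (count > 0)
    in more than ``min_expr_fraction`` of A's cells and the receptor in
    more than that fraction of B's cells. Self-loops are allowed.
    """
    labels = labels.reindex(cm.counts.columns)
    if labels.isna().any():
        raise ValueError("labels must cover every cell")
    clusters = sorted(labels.unique())
    detected = cm.counts > 0
    frac = {
        cl: detected.loc[:, (labels == cl).to_numpy()].mean(axis=1) for cl in clusters
    }
    calls = []
    for pair in lr_pairs:
        if pair.ligand not in cm.counts.index or pair.receptor not in cm.counts.index:
            continue
        for src in clusters:
            if frac[src][pair.ligand] <= min_expr_fraction:
                continue
            for tgt in clusters:
                if frac[tgt][pair.receptor] > min_expr_fraction:
                    calls.append(InteractionCall(src, tgt, pair, present=True))
    return calls


def vns_response(
    calls: list[InteractionCall],
    de_p_naive: Mapping[str, float],
    de_p_vns: Mapping[str, float],
) -> list[InteractionCall]:
    """Flag interactions whose ligand or receptor gains significance under
    vagal nerve stimulation (smaller DE p than without stimulation).

    A gene missing from either table is treated as p = 1 with a warning;
    both genes' p-values are recorded so a stricter both-gene rule stays
    recoverable from the output.
    """
    missing: set[str] = set()

    def get(table: Mapping[str, float], gene: str) -> float:
        if gene not in table:
            missing.add(gene)
            return 1.0
        return table[gene]

    for call in calls:
        if not call.present:
            continue
        call.ligand_p_naive = get(de_p_naive, call.pair.ligand)
        call.ligand_p_vns = get(de_p_vns, call.pair.ligand)
        call.receptor_p_naive = get(de_p_naive, call.pair.receptor)
        call.receptor_p_vns = get(de_p_vns, call.pair.receptor)
        call.vns_up = (
            call.ligand_p_vns < call.ligand_p_naive
            or call.receptor_p_vns < call.receptor_p_naive
        )
    if missing:
        warnings.warn(
            f"{len(missing)} genes missing from a DE table; treated as p=1",
            stacklevel=2,
        )
    return calls


def cells_required(
    n_types: int, fraction: float, min_cells: int, confidence: float
) -> int:
    """Minimum cells to capture every cell type, exact-binomial model.

    Smallest N with [P(X >= min_cells)]^n_types >= confidence for
    X ~ Binomial(N, fraction) — types treated as independent, each present
    at the same frequency. Found by incremental search from min_cells
    using exact binomial tails.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if not 0 < confidence < 1:
        raise ValueError("confidence must lie in (0, 1)")
    if min_cells < 1 or n_types < 1:
        raise ValueError("min_cells and n_types must be >= 1")
    if fraction * n_types > 1:
        warnings.warn(
            "fractions sum above 1; the independent-types model is approximate",
            stacklevel=2,
        )
    n = min_cells
    while True:
        tail = stats.binom.sf(min_cells - 1, n, fraction)
        if tail**n_types >= confidence:
            return n
        n += 1


def read_lr_pairs(path) -> list[LRPair]:
    """Read a ligand-receptor pair table (TSV: ligand, receptor)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return [LRPair(str(r.ligand), str(r.receptor)) for r in df.itertuples(index=False)]
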