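"""WikiPathway-level statistics built on top of the enrichment map.

A WikiPathway is scored by matching its member genes to a DEG list (after
ortholog filtering), locating those DEGs' enriched GO-BP terms in the
map, and combining the per-DEG term significances with the harmonic mean
p-value — a combination rule that stays valid when the individual tests
are dependent, which DEGs from one list are. Companion statistics:
Gene_percent (pathway-specific DEGs over total DEGs), the up/down
enrichment ratio on the -log10(q) scale, the pro-/anti-inflammatory
shared-BP ratio, a gene-gene functional similarity matrix from shared BP
annotations, and Pearson correlation between pathway enrichment vectors.
"""

from __future__ import annotations

import math
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import EnrichmentMap, GeneSetDB, highlight_terms
from .orthologs import OrthologTable, map_gene_space


def match_wp_degs(
    deg_list: pd.DataFrame,
    wp_db: GeneSetDB,
    ortholog_filter: OrthologTable | None = None,
    direction: Literal["a_to_b", "b_to_a"] = "a_to_b",
) -> dict[str, dict[str, set[str]]]:
    """Per-pathway DEG matches, split by regulation direction.

    ``deg_list`` is a DEG table indexed by gene with a ``direction``
    column. When an ortholog filter is given, DEGs are first restricted to
    (and renamed through) the high-quality 1:1 mapping. Returns
    {pathway_id: {"up": genes, "down": genes}}.
    """
    degs = deg_list
    if ortholog_filter is not None:
        degs, _ = map_gene_space(deg_list, ortholog_filter, direction)
    up = set(degs.index[degs["direction"] == "up"])
    down = set(degs.index[degs["direction"] == "down"])
    out = {}
    for s in wp_db:
        out[s.term_id] = {"up": s.genes & up, "down": s.genes & down}
    return out


def combine_hmp(pvalues: Iterable[float]) -> float:
    """Equal-weight harmonic mean of p-values: L / sum(1/p_i).

    Robust to dependence between the combined tests; bounded by
    [min p, max p]. Degenerate p = 0 is rejected.
    """
    ps = np.asarray(list(pvalues), dtype=float)
    if ps.size == 0:
        raise ValueError("combine_hmp needs at least one p-value")
    if (ps <= 0).any() or (ps > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return float(len(ps) / np.sum(1.0 / ps))


def gene_percent(n_matched: int, n_total: int) -> float:
    """Pathway-specific DEGs over total DEGs in the list."""
    if n_total <= 0:
        raise ValueError("total DEG count must be positive")
    if not 0 <= n_matched <= n_total:
        raise ValueError("matched count outside [0, total]")
    return n_matched / n_total


def enrichment_ratio(q_up: float, q_down: float, scale: str = "log10") -> float:
    """Up/down enrichment ratio of one pathway across two DEG directions.

    Default scale: (-log10 q_up) / (-log10 q_down). Returns ``inf`` when
    the denominator direction is unenriched (q_down = 1) and ``nan`` when
    both are (flagged, not numeric errors).
    """
    for q in (q_up, q_down):
        if not 0 < q <= 1:
            raise ValueError("q-values must lie in (0, 1]")
    if scale == "log10":
        num, den = -math.log10(q_up), -math.log10(q_down)
    elif scale == "raw":
        num, den = q_down, q_up  # smaller q = stronger enrichment
    else:
        raise ValueError(f"unknown scale {scale!r}")
    if num == 0 and den == 0:
        return float("nan")
    if den == 0:
        return float("inf")
    if num == 0:
        return 0.0
    return num / den


def pro_anti_ratio(
    pathway_terms: Iterable[str],
    pro_terms: Iterable[str],
    anti_terms: Iterable[str],
    emap: EnrichmentMap | None = None,
    neighborhood: bool = True,
) -> float:
    """Ratio of BP-map nodes a pathway shares with pro- vs
    anti-inflammatory signatures.

    ``pathway_terms``, ``pro_terms`` and ``anti_terms`` are node sets on
    the same enrichment map. "Shared" means a node in the pathway's term
    neighborhood (the terms themselves plus, by default, their map
    neighbors) that also belongs to the pro (resp. anti) signature.
    Returns nan when both counts are zero and inf when only the anti
    count is.
    """
    pw = set(pathway_terms)
    if emap is not None and neighborhood:
        hood = set(pw)
        for n in pw:
            if n in emap.graph:
                hood.update(emap.graph.neighbors(n))
    else:
        hood = pw
    n_pro = len(hood & set(pro_terms))
    n_anti = len(hood & set(anti_terms))
    if n_pro == 0 and n_anti == 0:
        return float("nan")
    if n_anti == 0:
        return float("inf")
    return n_pro / n_anti


def similarity_matrix(gene_to_bps: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Gene x gene functional similarity from shared BP annotations.

    similarity(g1, g2) = |BP(g1) ∩ BP(g2)| / |BP(g1) ∪ BP(g2)| (Jaccard on
    annotation sets — a set-overlap simplification of information-content
    semantic similarity). Unannotated genes are excluded with a warning.
    """
    import warnings

    ann = {g: frozenset(t) for g, t in gene_to_bps.items()}
    empty = [g for g, t in ann.items() if not t]
    if empty:
        warnings.warn(f"excluding {len(empty)} unannotated genes", stacklevel=2)
        for g in empty:
            del ann[g]
    genes = sorted(ann)
    n = len(genes)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = ann[genes[i]], ann[genes[j]]
            mat[i, j] = mat[j, i] = len(a & b) / len(a | b)
    return pd.DataFrame(mat, index=genes, columns=genes)


def pathway_correlation(
    vec_a: Sequence[float], vec_b: Sequence[float]
) -> tuple[float, float]:
    """Pearson r (with t-based p) between two per-BP enrichment vectors."""
    a = np.asarray(vec_a, dtype=float)
    b = np.asarray(vec_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan"), float("nan")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


def score_wikipathway(
    pathway_id: str,
    matched: Mapping[str, set[str]],
    deg_list: pd.DataFrame,
    term_q: Mapping[str, float],
    emap: EnrichmentMap,
) -> dict:
    """Full per-pathway score: matched DEGs, Gene_percent, and the HMP of
    the BH-corrected significances of the map terms highlighted by each
    matched DEG (per direction)."""
    out = {"pathway_id": pathway_id}
    n_total = len(deg_list)
    for direction in ("up", "down"):
        genes = matched.get(direction, set())
        pvals = []
        for g in genes:
            nodes = highlight_terms(emap, {g})
            qs = [term_q[n] for n in nodes if n in term_q and 0 < term_q[n] <= 1]
            if qs:
                pvals.append(min(qs))
        out[f"{direction}_matched"] = sorted(genes)
        out[f"{direction}_gene_percent"] = (
            gene_percent(len(genes), n_total) if n_total else float("nan")
        )
        out[f"{direction}_combined_p"] = combine_hmp(pvals) if pvals else float("nan")
    return out
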