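"""Gene-set enrichment maps and functional-linkage coverage.

Over-representation of DEG lists in Gene Ontology Biological Process terms
is tested with the one-sided hypergeometric (Fisher) test against a custom
background with Benjamini-Hochberg correction. Significant terms are
filtered for specificity (GO level band, minimum overlap, mapped fraction
of the full annotation) and assembled into an *enrichment map*: a network
whose nodes are terms and whose edges connect terms sharing genes with an
overlap coefficient |A∩B| / min(|A|,|B|) at or above a cutoff. An edge is
a *functional linkage*, weighted by the number of shared genes.

The map supports the cross-species statistics this package exists for:
highlighting the terms containing a DEG subset, *linkage coverage* (the
fraction of a reference DEG set's linkages also recovered by a subset —
e.g. by a handful of orthologous DEGs from the other species), the
involvement fraction of highlighted nodes, and projection of a foreign
species' DEG list through the ortholog bijection onto a native map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .orthologs import OrthologTable, map_gene_space


@dataclass
class GeneSet:
    """A term with its member genes and annotation bookkeeping.

    ``associated_gene_count`` is the size of the full annotation (all genes
    ever attached to the term), which may exceed the genes present in the
    analysis background.
    """

    term_id: str
    name: str = ""
    source: str = "GOBP"
    go_level: int | None = None
    genes: frozenset = frozenset()
    associated_gene_count: int | None = None

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        if self.associated_gene_count is None:
            self.associated_gene_count = len(self.genes)


class GeneSetDB:
    """A collection of GeneSets with GMT round-tripping.

    The GMT format is one term per line: term_id, description, then member
    genes, tab-separated. GO level and full-annotation size travel in an
    optional sidecar TSV (term_id, go_level, associated_gene_count,
    category).
    """

    def __init__(self, sets: Iterable[GeneSet]):
        self.sets: dict[str, GeneSet] = {s.term_id: s for s in sets}
        self.category: dict[str, str] = {}

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, term_id: str) -> GeneSet:
        return self.sets[term_id]

    @classmethod
    def from_gmt(cls, gmt_path, sidecar_path=None) -> "GeneSetDB":
        sets = []
        with open(gmt_path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                sets.append(GeneSet(parts[0], parts[1], genes=frozenset(parts[2:])))
        db = cls(sets)
        if sidecar_path is not None:
            side = pd.read_csv(sidecar_path, sep="\t").set_index("term_id")
            for tid, row in side.iterrows():
                if tid in db.sets:
                    gs = db.sets[tid]
                    if "go_level" in row and not pd.isna(row["go_level"]):
                        gs.go_level = int(row["go_level"])
                    if "associated_gene_count" in row and not pd.isna(
                        row["associated_gene_count"]
                    ):
                        gs.associated_gene_count = int(row["associated_gene_count"])
                    if "category" in row and not pd.isna(row["category"]):
                        db.category[tid] = str(row["category"])
        return db

    def to_gmt(self, gmt_path, sidecar_path=None) -> None:
        with open(gmt_path, "w") as fh:
            for s in self.sets.values():
                fh.write("\t".join([s.term_id, s.name, *sorted(s.genes)]) + "\n")
        if sidecar_path is not None:
            rows = [
                {
                    "term_id": s.term_id,
                    "go_level": s.go_level,
                    "associated_gene_count": s.associated_gene_count,
                    "category": self.category.get(s.term_id, ""),
                }
                for s in self.sets.values()
            ]
            pd.DataFrame(rows).to_csv(sidecar_path, sep="\t", index=False)


def enrich_fisher(
    deg_genes: Iterable[str], background: Iterable[str], db: GeneSetDB
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation with BH correction.

    For each term: N = |background|, K = |term ∩ background|, n = |DEGs|,
    k = |DEGs ∩ term|; p = P(X >= k) for X ~ Hypergeom(N, K, n). Terms
    with no background genes are reported with p = 1 (warned). q-values
    are BH over all terms in ``db`` (one family per call).
    """
    deg = frozenset(deg_genes)
    bg = frozenset(background)
    if not deg <= bg:
        raise ValueError("DEG genes must be a subset of the background")
    N, n = len(bg), len(deg)
    rows = []
    empty_terms = 0
    for s in db:
        term_bg = s.genes & bg
        K = len(term_bg)
        k = len(term_bg & deg)
        if K == 0:
            empty_terms += 1
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"term_id": s.term_id, "overlap_count": k, "term_bg_count": K, "p": p}
        )
    if empty_terms:
        warnings.warn(
            f"{empty_terms} terms have no genes in the background (p set to 1)",
            stacklevel=2,
        )
    res = pd.DataFrame(rows).set_index("term_id")
    res["p"] = res["p"].clip(upper=1.0)
    _, q, _, _ = multipletests(res["p"], method="fdr_bh")
    res["q"] = q
    return res


def filter_specific_terms(
    results: pd.DataFrame,
    db: GeneSetDB,
    min_genes: int = 1,
    min_mapped_fraction: float = 0.5,
    level_range: tuple[int, int] = (7, 15),
) -> pd.DataFrame:
    """ClueGO-style term specificity filter.

    Keeps terms whose GO level is within ``level_range`` (inclusive),
    whose DEG overlap is at least ``min_genes``, and whose overlap covers
    strictly more than ``min_mapped_fraction`` of the term's full
    annotation. Terms without a level are excluded with a warning.
    """
    lo, hi = level_range
    keep = []
    n_missing = 0
    for tid, row in results.iterrows():
        if tid not in db.sets:
            continue
        s = db[tid]
        if s.go_level is None:
            n_missing += 1
            continue
        if not (lo <= s.go_level <= hi):
            continue
        if row["overlap_count"] < min_genes:
            continue
        if not s.associated_gene_count:
            continue
        if row["overlap_count"] / s.associated_gene_count <= min_mapped_fraction:
            continue
        keep.append(tid)
    if n_missing:
        warnings.warn(f"{n_missing} terms lack a GO level and were excluded", stacklevel=2)
    return results.loc[keep]


def select_go_level(
    results_by_level: Mapping[int, pd.DataFrame],
    min_bps: int = 3,
    q_cut: float = 0.05,
) -> int | None:
    """Smallest GO level with at least ``min_bps`` terms at q < q_cut.

    Returns None when no level qualifies.
    """
    for level in sorted(results_by_level):
        res = results_by_level[level]
        if len(res) and int((res["q"] < q_cut).sum()) >= min_bps:
            return level
    return None


@dataclass
class EnrichmentMap:
    """Term-overlap network: nodes are enriched terms, edges share genes."""

    graph: nx.Graph
    overlap_cutoff: float

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def member_degs(self, node: str) -> frozenset:
        return self.graph.nodes[node]["member_degs"]

    def to_graphml(self, path) -> None:
        g = self.graph.copy()
        for _, data in g.nodes(data=True):
            data["member_degs"] = ",".join(sorted(data["member_degs"]))
            data["genes"] = ",".join(sorted(data["genes"]))
            if data.get("q") is None:
                data["q"] = float("nan")
        nx.write_graphml(g, path)

    def to_sif(self, sif_path, node_attr_path=None, edge_attr_path=None) -> None:
        """Cytoscape SIF plus node/edge attribute TSVs."""
        with open(sif_path, "w") as fh:
            isolated = set(self.graph.nodes)
            for a, b in self.graph.edges:
                fh.write(f"{a}\toverlap\t{b}\n")
                isolated.discard(a)
                isolated.discard(b)
            for node in sorted(isolated):
                fh.write(f"{node}\n")
        if node_attr_path is not None:
            rows = [
                {
                    "term_id": n,
                    "q": d.get("q"),
                    "direction": d.get("direction", ""),
                    "member_degs": ",".join(sorted(d["member_degs"])),
                }
                for n, d in self.graph.nodes(data=True)
            ]
            pd.DataFrame(rows).to_csv(node_attr_path, sep="\t", index=False)
        if edge_attr_path is not None:
            rows = [
                {
                    "term_a": a,
                    "term_b": b,
                    "shared_gene_count": d["shared_gene_count"],
                    "overlap_coefficient": d["overlap_coefficient"],
                }
                for a, b, d in self.graph.edges(data=True)
            ]
            pd.DataFrame(rows).to_csv(edge_attr_path, sep="\t", index=False)


@dataclass
class CoverageReport:
    """Node/edge/linkage-weight coverage of a map by a DEG subset."""

    highlighted_node_count: int
    total_node_count: int
    covered_edge_count: int
    total_edge_count: int
    covered_linkage_weight: float
    total_linkage_weight: float
    node_fraction: float
    linkage_coverage: float
    mode: str = "weight"
    endpoint_rule: str = "both"


def build_enrichment_map(
    terms: Sequence[GeneSet],
    overlap_cutoff: float = 0.25,
    term_q: Mapping[str, float] | None = None,
    deg_genes: Iterable[str] | None = None,
    direction: Mapping[str, str] | None = None,
) -> EnrichmentMap:
    """Link terms whose gene-set overlap coefficient meets the cutoff.

    Edge (A, B) exists iff |A∩B| / min(|A|,|B|) >= cutoff and the sets
    share at least one gene; the edge carries the shared gene count (the
    linkage weight) and the coefficient. Node attributes: the term's gene
    set, its member DEGs (intersection with ``deg_genes`` when given), q
    and an up/down direction label when supplied.
    """
    deg = frozenset(deg_genes) if deg_genes is not None else None
    g = nx.Graph()
    for s in terms:
        g.add_node(
            s.term_id,
            genes=s.genes,
            member_degs=(s.genes & deg) if deg is not None else s.genes,
            q=(term_q or {}).get(s.term_id),
            direction=(direction or {}).get(s.term_id, ""),
        )
    terms_sorted = sorted(terms, key=lambda s: s.term_id)
    for i, a in enumerate(terms_sorted):
        for b in terms_sorted[i + 1 :]:
            shared = a.genes & b.genes
            if not shared:
                continue
            denom = min(len(a.genes), len(b.genes))
            coef = len(shared) / denom
            if coef >= overlap_cutoff:
                g.add_edge(
                    a.term_id,
                    b.term_id,
                    shared_gene_count=len(shared),
                    overlap_coefficient=coef,
                )
    return EnrichmentMap(g, overlap_cutoff)


def highlight_terms(emap: EnrichmentMap, deg_subset: Iterable[str]) -> set[str]:
    """Nodes whose member DEG set intersects the given genes."""
    sub = frozenset(deg_subset)
    return {
        n for n, d in emap.graph.nodes(data=True) if d["member_degs"] & sub
    }


def linkage_coverage(
    emap: EnrichmentMap,
    subset_degs: Iterable[str],
    reference_degs: Iterable[str],
    mode: Literal["weight", "edge"] = "weight",
    endpoint_rule: Literal["both", "any"] = "both",
) -> CoverageReport:
    """Fraction of the reference DEG set's functional linkages that the
    subset also recovers.

    A linkage (edge) is *covered* by a DEG set when both endpoint terms
    are highlighted by it (``endpoint_rule="any"`` relaxes this to one
    endpoint, for sensitivity analysis). In weight mode the coverage is
    the ratio of summed shared-gene counts over covered edges; in edge
    mode it is the ratio of covered edge counts.
    """

    def covered(highlighted: set[str]) -> tuple[int, float]:
        n_edges, weight = 0, 0.0
        for a, b, d in emap.graph.edges(data=True):
            if endpoint_rule == "both":
                hit = a in highlighted and b in highlighted
            else:
                hit = a in highlighted or b in highlighted
            if hit:
                n_edges += 1
                weight += d["shared_gene_count"]
        return n_edges, weight

    sub_nodes = highlight_terms(emap, subset_degs)
    ref_nodes = highlight_terms(emap, reference_degs)
    sub_edges, sub_weight = covered(sub_nodes)
    ref_edges, ref_weight = covered(ref_nodes)
    if (mode == "weight" and ref_weight == 0) or (mode == "edge" and ref_edges == 0):
        raise ValueError("reference DEG set covers zero linkages; coverage undefined")
    cov = sub_weight / ref_weight if mode == "weight" else sub_edges / ref_edges
    n_total = emap.graph.number_of_nodes()
    return CoverageReport(
        highlighted_node_count=len(sub_nodes),
        total_node_count=n_total,
        covered_edge_count=sub_edges,
        total_edge_count=ref_edges,
        covered_linkage_weight=sub_weight,
        total_linkage_weight=ref_weight,
        node_fraction=len(sub_nodes) / n_total if n_total else 0.0,
        linkage_coverage=cov,
        mode=mode,
        endpoint_rule=endpoint_rule,
    )


def involvement_fraction(
    highlighted_up: int, total_up: int, highlighted_down: int, total_down: int
) -> float:
    """Percent of grouped network nodes directly involving a DEG subset:
    100 * (highlighted_up + highlighted_down) / (total_up + total_down)."""
    if highlighted_up > total_up or highlighted_down > total_down:
        raise ValueError("highlighted counts exceed totals")
    denom = total_up + total_down
    if denom == 0:
        raise ValueError("zero total node count")
    return 100.0 * (highlighted_up + highlighted_down) / denom


def cross_species_match(
    emap_native: EnrichmentMap,
    foreign_degs: Iterable[str],
    ortholog_table: OrthologTable,
    native_reference_degs: Iterable[str],
    direction: Literal["a_to_b", "b_to_a"] = "a_to_b",
    mode: Literal["weight", "edge"] = "weight",
) -> CoverageReport:
    """Project a foreign species' DEG list through the ortholog bijection
    onto a native enrichment map and score its linkage coverage against
    the native full DEG set."""
    mapped, n_dropped = map_gene_space(set(foreign_degs), ortholog_table, direction)
    if not mapped:
        warnings.warn("no foreign DEG maps through the ortholog table", stacklevel=2)
    return linkage_coverage(
        emap_native, mapped, native_reference_degs, mode=mode
    )
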