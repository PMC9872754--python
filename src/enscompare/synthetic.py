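"""Synthetic study generator with recorded ground truth.

Emulates the statistical structure of a two-species colonic-ENS study so
every pipeline stage runs and is validated without downloads: two species
sharing strict 1:1 orthologs (plus decoy non-1:1 and low-quality pairs),
a region x plexus x condition bulk design with planted differential
programs on negative-binomial counts and library-size variation, leveled
GO-BP-like and categorized WikiPathways-like gene-set databases with
controlled pairwise overlaps, and a single-cell UMI fixture with five
planted cell types, marker genes, mitochondrial genes and active
ligand-receptor pairs.

Everything planted is recorded in a :class:`SyntheticTruth` so recovery
experiments can be scored without re-reading generator internals; a given
seed reproduces all outputs exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .celltype import CellMatrix, LRPair
from .enrichment import GeneSet, GeneSetDB
from .normalize import CountMatrix
from .orthologs import OrthologTable

# ---------------------------------------------------------------------------
# ground truth


@dataclass
class SyntheticTruth:
    """Everything the generator planted, for recovery scoring."""

    seed: int
    planted_degs: dict = field(default_factory=dict)  # contrast -> {gene: (dir, log2fc)}
    scaling_factors: dict = field(default_factory=dict)  # sample -> depth factor
    ortholog_pairs: dict = field(default_factory=dict)  # gene_a -> gene_b (true 1:1)
    term_membership: dict = field(default_factory=dict)  # term -> [genes]
    markers: dict = field(default_factory=dict)  # cell type -> {gene: fold}
    lr_active: list = field(default_factory=list)  # [(source, target, ligand, receptor)]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=list)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# bulk


@dataclass
class BulkConfig:
    """Study-design and noise parameters for the bulk generator.

    Defaults mirror the study layout: porcine proximal/transverse/distal
    colon x {myenteric, inner submucosal} ganglia with 6 naive and 3
    stimulated replicates per cell, and human ascending/transverse/
    descending colon myenteric ganglia with 4 replicates; planted log2
    effect 1.5 on negative-binomial counts with dispersion 0.1.
    """

    n_genes: int = 2000
    n_deg_region: int = 80  # genes shifted between proximal and distal colon
    n_deg_plexus: int = 60  # genes shifted between MG and ISG (pig only)
    n_deg_vns: int = 60  # genes responding to vagal stimulation (pig only)
    log2_effect: float = 1.5
    dispersion: float = 0.1
    base_log2_mean: float = 5.0
    base_log2_sd: float = 1.0  # keeps the low tail out of the shot-noise regime
    library_size: float = 2_000_000.0
    library_size_cv: float = 0.25
    pig_regions: Sequence[str] = ("pC", "tC", "dC")
    human_regions: Sequence[str] = ("aC", "tC", "dC")
    n_naive: int = 6
    n_vns: int = 3
    n_human: int = 4
    frac_non_one2one: float = 0.10
    frac_low_score: float = 0.10
    gene_length_min: int = 500
    gene_length_max: int = 5000


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    """Negative binomial via gamma-Poisson mixture (mean, dispersion)."""
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def generate_bulk(
    config: BulkConfig | None = None, seed: int = 0
) -> tuple[dict[str, CountMatrix], OrthologTable, SyntheticTruth]:
    """Simulate the two-species bulk experiment.

    One latent expression program is drawn and shared by both species
    through the ortholog bijection; planted contrasts perturb it per
    group. Returns ({"pig": CountMatrix, "human": CountMatrix},
    unfiltered OrthologTable, SyntheticTruth).
    """
    cfg = config or BulkConfig()
    rng = np.random.default_rng(seed)
    total_deg = cfg.n_deg_region + cfg.n_deg_plexus + cfg.n_deg_vns
    if total_deg > cfg.n_genes:
        raise ValueError(
            f"cannot plant {total_deg} DEGs in {cfg.n_genes} genes"
        )

    pig_genes = [f"PIG{i:05d}" for i in range(cfg.n_genes)]
    hum_genes = [f"HUM{i:05d}" for i in range(cfg.n_genes)]
    truth = SyntheticTruth(seed=seed)
    truth.ortholog_pairs = dict(zip(pig_genes, hum_genes))

    # shared latent program (log2 expression per gene)
    base = rng.normal(cfg.base_log2_mean, cfg.base_log2_sd, cfg.n_genes)
    lengths = rng.integers(cfg.gene_length_min, cfg.gene_length_max + 1, cfg.n_genes)

    # planted contrasts: disjoint gene blocks, half up / half down
    idx = rng.permutation(cfg.n_genes)
    blocks = {
        "region_pC_vs_dC": idx[: cfg.n_deg_region],
        "plexus_ISG_vs_MG": idx[cfg.n_deg_region : cfg.n_deg_region + cfg.n_deg_plexus],
        "vns_VNS_vs_naive": idx[cfg.n_deg_region + cfg.n_deg_plexus : total_deg],
    }
    effect = {}
    for contrast, block in blocks.items():
        signs = np.where(np.arange(len(block)) % 2 == 0, 1.0, -1.0)
        effect[contrast] = dict(zip(block.tolist(), (signs * cfg.log2_effect).tolist()))
        truth.planted_degs[contrast] = {
            pig_genes[g]: ("up" if s > 0 else "down", abs(s * cfg.log2_effect))
            for g, s in zip(block.tolist(), signs.tolist())
        }

    def group_log2(region: str, plexus: str, condition: str, species: str) -> np.ndarray:
        mu = base.copy()
        region_key = "pC" if species == "pig" else "aC"
        for g, eff in effect["region_pC_vs_dC"].items():
            if region == region_key:
                mu[g] += eff
        if species == "pig":
            for g, eff in effect["plexus_ISG_vs_MG"].items():
                if plexus == "ISG":
                    mu[g] += eff
            for g, eff in effect["vns_VNS_vs_naive"].items():
                if condition == "VNS":
                    mu[g] += eff
        return mu

    def simulate_species(species: str) -> CountMatrix:
        genes = pig_genes if species == "pig" else hum_genes
        cols, metas, mats = [], [], []
        if species == "pig":
            design = [
                (r, px, cond, n)
                for r in cfg.pig_regions
                for px in ("MG", "ISG")
                for cond, n in (("naive", cfg.n_naive), ("VNS", cfg.n_vns))
            ]
        else:
            design = [(r, "MG", "naive", cfg.n_human) for r in cfg.human_regions]
        for region, plexus, condition, n_rep in design:
            mu_log2 = group_log2(region, plexus, condition, species)
            rel = 2.0**mu_log2 * lengths  # reads scale with length and expression
            rel = rel / rel.sum()
            for rep in range(n_rep):
                depth_factor = rng.lognormal(0.0, cfg.library_size_cv)
                depth = cfg.library_size * depth_factor
                counts = _nb_counts(rng, rel * depth, cfg.dispersion)
                name = f"{species[0]}-{region}-{plexus}-{condition}-{rep + 1}"
                cols.append(name)
                metas.append(
                    {
                        "sample": name,
                        "species": species,
                        "region": region,
                        "plexus": plexus,
                        "condition": condition,
                    }
                )
                mats.append(counts)
                truth.scaling_factors[name] = depth_factor
        counts_df = pd.DataFrame(
            np.column_stack(mats), index=genes, columns=cols
        )
        meta = pd.DataFrame(metas).set_index("sample")
        return CountMatrix(
            counts_df,
            gene_length_bp=pd.Series(lengths, index=genes),
            total_mapped=counts_df.sum(axis=0),
            sample_meta=meta,
        )

    matrices = {"pig": simulate_species("pig"), "human": simulate_species("human")}

    # ortholog table: true pairs at high quality, plus decoys that the
    # quality filter must remove
    records = []
    n_low = int(cfg.frac_low_score * cfg.n_genes)
    low_idx = set(rng.choice(cfg.n_genes, n_low, replace=False).tolist())
    for i, (ga, gb) in enumerate(zip(pig_genes, hum_genes)):
        if i in low_idx:
            goc, wga = rng.uniform(0, 75, 2).round(2)
            del truth.ortholog_pairs[ga]
        else:
            goc, wga = rng.uniform(76, 100, 2).round(2)
        records.append(
            {
                "gene_a": ga,
                "gene_b": gb,
                "homology_type": "one2one",
                "goc_score": goc,
                "wga_score": wga,
            }
        )
    n_multi = int(cfg.frac_non_one2one * cfg.n_genes)
    for j in range(n_multi):
        src = int(rng.integers(cfg.n_genes))
        records.append(
            {
                "gene_a": pig_genes[src],
                "gene_b": f"HUMX{j:04d}",
                "homology_type": rng.choice(["one2many", "many2many"]),
                "goc_score": float(rng.uniform(76, 100)),
                "wga_score": float(rng.uniform(76, 100)),
            }
        )
    table = OrthologTable(pd.DataFrame(records))
    return matrices, table, truth


# ---------------------------------------------------------------------------
# gene sets


@dataclass
class GeneSetConfig:
    """Shape of the synthetic term databases."""

    n_bp_terms: int = 40
    bp_size_min: int = 10
    bp_size_max: int = 40
    level_min: int = 7
    level_max: int = 15
    overlap_coefficient: float = 0.5  # applied to consecutive term pairs
    frac_linked_pairs: float = 0.5
    n_wp: int = 12
    wp_size_min: int = 15
    wp_size_max: int = 50
    n_categories: int = 9
    pro_anti_size: int = 20
    universe: Sequence[str] | None = None  # defaults to PIG gene ids
    # terms can preferentially include "focus" genes (e.g. planted DEGs)
    # so over-representation has real signal to find
    focus_genes: Sequence[str] | None = None
    frac_focus_terms: float = 0.4
    focus_share: float = 0.5


def generate_genesets(
    config: GeneSetConfig | None = None, seed: int = 0, n_universe: int = 2000
) -> tuple[GeneSetDB, GeneSetDB, dict[str, frozenset], SyntheticTruth]:
    """Build leveled GO-BP-like terms with controlled pairwise overlaps, a
    categorized WikiPathways-like database, and pro/anti-inflammatory
    signatures.

    Consecutive BP term pairs are linked with exactly the configured
    overlap coefficient (for a fraction of pairs), so enrichment-map edges
    at a given cutoff are planted by construction. Returns
    (bp_db, wp_db, {"pro": genes, "anti": genes}, truth).
    """
    cfg = config or GeneSetConfig()
    rng = np.random.default_rng(seed)
    universe = (
        list(cfg.universe)
        if cfg.universe is not None
        else [f"PIG{i:05d}" for i in range(n_universe)]
    )
    truth = SyntheticTruth(seed=seed)

    bp_sets = []
    prev_genes: list[str] | None = None
    for t in range(cfg.n_bp_terms):
        size = int(rng.integers(cfg.bp_size_min, cfg.bp_size_max + 1))
        link = (
            prev_genes is not None
            and cfg.overlap_coefficient > 0
            and rng.random() < cfg.frac_linked_pairs
        )
        focus = (
            list(cfg.focus_genes)
            if cfg.focus_genes is not None and rng.random() < cfg.frac_focus_terms
            else None
        )
        if link:
            # overlap coefficient uses min(|A|,|B|): share exactly
            # ceil(coef * min) genes with the previous term; fresh genes
            # avoid the previous term entirely so the coefficient is exact
            n_shared = int(np.ceil(cfg.overlap_coefficient * min(size, len(prev_genes))))
            n_shared = min(n_shared, len(prev_genes), size)
            shared = list(rng.choice(prev_genes, n_shared, replace=False))
            rest_pool = [g for g in universe if g not in set(prev_genes)]
            fresh = list(rng.choice(rest_pool, size - n_shared, replace=False))
            genes = shared + fresh
        elif focus is not None:
            n_focus = min(int(np.ceil(cfg.focus_share * size)), len(focus))
            part = list(rng.choice(focus, n_focus, replace=False))
            rest_pool = [g for g in universe if g not in set(part)]
            genes = part + list(rng.choice(rest_pool, size - n_focus, replace=False))
        else:
            genes = list(rng.choice(universe, size, replace=False))
        level = int(rng.integers(cfg.level_min, cfg.level_max + 1))
        term_id = f"BP{t:04d}"
        bp_sets.append(
            GeneSet(term_id, f"synthetic process {t}", "GOBP", level, frozenset(genes))
        )
        truth.term_membership[term_id] = sorted(genes)
        prev_genes = genes
    bp_db = GeneSetDB(bp_sets)

    wp_sets = []
    categories = [f"category_{c + 1}" for c in range(cfg.n_categories)]
    for t in range(cfg.n_wp):
        size = int(rng.integers(cfg.wp_size_min, cfg.wp_size_max + 1))
        genes = frozenset(rng.choice(universe, size, replace=False))
        term_id = f"WP{t:04d}"
        wp_sets.append(GeneSet(term_id, f"synthetic pathway {t}", "WikiPathways", None, genes))
        truth.term_membership[term_id] = sorted(genes)
    wp_db = GeneSetDB(wp_sets)
    for t, s in enumerate(wp_db):
        wp_db.category[s.term_id] = categories[t % cfg.n_categories]

    signatures = {
        name: frozenset(rng.choice(universe, cfg.pro_anti_size, replace=False))
        for name in ("pro", "anti")
    }
    return bp_db, wp_db, signatures, truth


# ---------------------------------------------------------------------------
# single cell


@dataclass
class CellConfig:
    """Shape of the single-cell fixture: five colonic-ENS-like types."""

    cell_types: Sequence[str] = (
        "cholinergic",
        "glutamatergic",
        "nitrergic",
        "glia_SLC41A1",
        "glia_SPC24",
    )
    cells_per_type: int = 150
    n_genes: int = 500
    n_mito: int = 10
    n_markers_per_type: int = 8
    marker_fold: float = 4.0
    base_rate: float = 2.0  # mean UMI per gene per cell before type effects
    depth_sd: float = 0.3  # log-normal cell depth spread
    dropout: float = 0.2
    mito_fraction: float = 0.02
    n_high_mito_cells: int = 0  # planted QC violations (mito ~10%)
    high_mito_fraction: float = 0.10
    n_lr_pairs: int = 8
    n_active_lr: int = 3
    gene_names: Sequence[str] | None = None  # use e.g. the bulk gene ids


def generate_cells(
    config: CellConfig | None = None, seed: int = 0
) -> tuple[CellMatrix, pd.Series, list[LRPair], SyntheticTruth]:
    """Simulate the UMI matrix with planted markers and L-R activity.

    Poisson-lognormal counts with dropout; each cell type over-expresses
    its markers by ``marker_fold``; mitochondrial genes (MT- prefix) carry
    ``mito_fraction`` of each cell's signal (a configurable block of cells
    gets ``high_mito_fraction`` to exercise QC); active ligand-receptor
    pairs are expressed in their source/target types, inactive pairs kept
    near zero everywhere.
    """
    cfg = config or CellConfig()
    rng = np.random.default_rng(seed)
    n_types = len(cfg.cell_types)
    mito_genes = [f"MT-{i}" for i in range(cfg.n_mito)]
    n_body = cfg.n_genes - cfg.n_mito
    if cfg.gene_names is not None:
        if len(cfg.gene_names) < n_body:
            raise ValueError("gene_names shorter than the requested gene count")
        body_genes = list(cfg.gene_names)[:n_body]
    else:
        body_genes = [f"SCG{i:05d}" for i in range(n_body)]
    genes = body_genes + mito_genes
    truth = SyntheticTruth(seed=seed)

    # planted markers: disjoint blocks of body genes per type
    markers: dict[str, list[str]] = {}
    cursor = 0
    for ct in cfg.cell_types:
        markers[ct] = body_genes[cursor : cursor + cfg.n_markers_per_type]
        truth.markers[ct] = {g: cfg.marker_fold for g in markers[ct]}
        cursor += cfg.n_markers_per_type

    # ligand-receptor pairs drawn from genes after the marker blocks
    lr_pool = body_genes[cursor : cursor + 2 * cfg.n_lr_pairs]
    lr_pairs = [
        LRPair(lr_pool[2 * i], lr_pool[2 * i + 1]) for i in range(cfg.n_lr_pairs)
    ]
    active: list[tuple[str, str, str, str]] = []
    for i in range(cfg.n_active_lr):
        src = cfg.cell_types[i % n_types]
        tgt = cfg.cell_types[(i + 3) % n_types]
        active.append((src, tgt, lr_pairs[i].ligand, lr_pairs[i].receptor))
    truth.lr_active = active
    active_ligands = {(lig, src) for src, _, lig, _ in active}
    active_receptors = {(rec, tgt) for _, tgt, _, rec in active}

    base = rng.lognormal(np.log(cfg.base_rate), 0.5, len(genes))
    gene_pos = {g: i for i, g in enumerate(genes)}
    cols, labels_list, blocks = [], [], []
    cell_id = 0
    for ct in cfg.cell_types:
        rate = base.copy()
        for g in markers[ct]:
            rate[gene_pos[g]] *= cfg.marker_fold
        # L-R genes are near-silent by default; an active pair's ligand is
        # switched on only in its source type, the receptor in its target
        for pair in lr_pairs:
            rate[gene_pos[pair.ligand]] = 0.005
            rate[gene_pos[pair.receptor]] = 0.005
        for (lig, src) in active_ligands:
            if src == ct:
                rate[gene_pos[lig]] = 2.0
        for (rec, tgt) in active_receptors:
            if tgt == ct:
                rate[gene_pos[rec]] = 2.0
        # mitochondrial genes carry a fixed share of the cell's signal
        body_total = rate[: len(body_genes)].sum()
        mito_rate = (
            cfg.mito_fraction / (1 - cfg.mito_fraction) * body_total / cfg.n_mito
        )
        rate[len(body_genes) :] = mito_rate
        for _ in range(cfg.cells_per_type):
            depth = rng.lognormal(0.0, cfg.depth_sd)
            lam = rate * depth
            counts = rng.poisson(lam)
            keep = rng.random(len(genes)) > cfg.dropout
            counts = counts * keep
            cols.append(f"CELL{cell_id:05d}")
            labels_list.append(ct)
            blocks.append(counts)
            cell_id += 1
    mat = np.column_stack(blocks)

    # planted QC violations: crank mito share to the configured high level
    if cfg.n_high_mito_cells > 0:
        bad = rng.choice(mat.shape[1], cfg.n_high_mito_cells, replace=False)
        for c in bad:
            body_total = mat[: len(body_genes), c].sum()
            target = cfg.high_mito_fraction / (1 - cfg.high_mito_fraction) * body_total
            mat[len(body_genes) :, c] = rng.multinomial(
                max(int(target), cfg.n_mito), np.ones(cfg.n_mito) / cfg.n_mito
            )

    counts = pd.DataFrame(mat, index=genes, columns=cols)
    labels = pd.Series(labels_list, index=cols, name="cell_type")
    meta = pd.DataFrame({"cell_type": labels})
    cm = CellMatrix(counts, meta, frozenset(mito_genes))
    return cm, labels, lr_pairs, truth
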