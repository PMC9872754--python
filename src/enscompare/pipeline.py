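"""End-to-end orchestration of the cross-species comparison.

The pipeline realizes the study dataflow: ortholog filtering -> RPKM +
median-anchored cross-species normalization -> distributional similarity
per matched colon region -> differential expression (or ingestion of
external DEG tables) -> GO-BP enrichment and enrichment-map construction
-> cross-species linkage coverage -> WikiPathway scores -> single-cell
summaries. Every stage writes TSV artifacts with provenance headers
(config hash, seed) into one output directory; no stage mutates another
stage's outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import celltype as ct
from . import enrichment as en
from . import normalize as nm
from . import pathway_scores as ps
from . import similarity as sim
from . import synthetic as syn
from .io import write_tsv
from .orthologs import OrthologTable, filter_high_quality, map_gene_space

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class DataError(ValueError):
    """Missing or malformed stage input."""


@dataclass
class PipelineConfig:
    """All thresholds and mode switches, serializable to/from YAML."""

    seed: int = 0
    outdir: str = "enscompare_out"
    # ortholog quality
    min_goc: float = 75.0
    min_wga: float = 75.0
    # normalization
    log_pseudocount: float = 1.0
    n_conserved: int | None = None  # default: half the eligible pool
    scale_space: str = "rpkm"  # medians computed before the log transform
    # testing
    q_cut: float = 0.05
    de_method: str = "moderated"
    min_conserved: int = 50  # below this pool, anchor medians on all genes
    # enrichment map
    overlap_cutoff: float = 0.25
    go_level_range: tuple[int, int] = (7, 15)
    min_bps: int = 3
    min_genes_per_term: int = 1
    # fraction of a term's full annotation the DEG overlap must exceed; the
    # synthetic databases are fully in-background, so the pipeline default
    # disables the rule (the operation's own default is 0.5)
    min_mapped_fraction: float = 0.0
    linkage_mode: str = "weight"
    endpoint_rule: str = "both"
    # single cell
    qc_min_genes: int = 200
    qc_max_genes: int = 2500
    qc_max_mito_pct: float = 5.0
    qc_min_cells_per_gene: int = 3
    marker_min_logfc: float = 0.25
    lr_min_expr_fraction: float = 0.1
    celltype_p_cut: float = 0.05
    # synthetic generators (used when no external inputs are supplied)
    bulk: syn.BulkConfig = field(default_factory=syn.BulkConfig)
    genesets: syn.GeneSetConfig = field(default_factory=syn.GeneSetConfig)
    cells: syn.CellConfig = field(default_factory=syn.CellConfig)

    def __post_init__(self) -> None:
        if not (0 <= self.min_goc <= 100 and 0 <= self.min_wga <= 100):
            raise ConfigError("GOC/WGA thresholds must lie in [0, 100]")
        if not 0 < self.q_cut < 1:
            raise ConfigError("q_cut must lie in (0, 1)")
        if not 0 < self.overlap_cutoff <= 1:
            raise ConfigError("overlap_cutoff must lie in (0, 1]")
        if self.linkage_mode not in ("weight", "edge"):
            raise ConfigError("linkage_mode must be 'weight' or 'edge'")
        if self.endpoint_rule not in ("both", "any"):
            raise ConfigError("endpoint_rule must be 'both' or 'any'")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Load a config; YAML sequences come back as tuples so a dumped
        default config compares equal after the round trip."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub in (("bulk", syn.BulkConfig), ("genesets", syn.GeneSetConfig), ("cells", syn.CellConfig)):
            if key in raw and isinstance(raw[key], dict):
                sub_raw = {
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in raw[key].items()
                }
                raw[key] = sub(**sub_raw)
        if "go_level_range" in raw:
            raw["go_level_range"] = tuple(raw["go_level_range"])
        return cls(**raw)

    def hash(self) -> str:
        """Digest of the analysis-relevant configuration (the output
        location does not affect results and is excluded)."""
        blob = dataclasses.asdict(self)
        blob.pop("outdir", None)
        return hashlib.sha256(
            json.dumps(blob, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _provenance(config: PipelineConfig, stage: str) -> dict:
    return {"stage": stage, "config_hash": config.hash(), "seed": config.seed}


def run_compare(config: PipelineConfig | None = None) -> dict:
    """Execute the full synthetic-driven comparison; return the in-memory
    report bundle (also written as TSV/JSON under ``config.outdir``)."""
    cfg = config or PipelineConfig()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config_hash": cfg.hash()}

    # --- simulate -----------------------------------------------------------
    try:
        matrices, ortho_raw, truth = syn.generate_bulk(cfg.bulk, seed=cfg.seed)
        gs_cfg = cfg.genesets
        if gs_cfg.focus_genes is None and truth.planted_degs:
            planted = sorted(next(iter(truth.planted_degs.values())))
            gs_cfg = dataclasses.replace(gs_cfg, focus_genes=planted)
        bp_db, wp_db, signatures, gs_truth = syn.generate_genesets(
            gs_cfg, seed=cfg.seed + 1, n_universe=cfg.bulk.n_genes
        )
        cell_cfg = dataclasses.replace(
            cfg.cells, gene_names=list(matrices["pig"].counts.index)
        )
        cells, labels, lr_pairs, cell_truth = syn.generate_cells(
            cell_cfg, seed=cfg.seed + 2
        )
    except Exception as exc:  # noqa: BLE001
        raise DataError(f"stage simulate failed: {exc}") from exc
    truth.to_json(out / "truth.json")

    # --- orthologs ----------------------------------------------------------
    ortho = filter_high_quality(ortho_raw, cfg.min_goc, cfg.min_wga)
    ortho.to_tsv(out / "orthologs.filtered.tsv")
    bundle["n_orthologs"] = len(ortho)
    logger.info("orthologs: %d high-quality 1:1 pairs", len(ortho))

    # --- normalize (joint cross-species matrix in the pig gene space) ------
    pig_rpkm = nm.rpkm(matrices["pig"])
    hum_rpkm = nm.rpkm(matrices["human"])
    hum_in_pig, _ = map_gene_space(hum_rpkm.values, ortho, "b_to_a")
    shared = pig_rpkm.values.index.intersection(hum_in_pig.index)
    joint = nm.ExpressionMatrix(
        pd.concat([pig_rpkm.values.loc[shared], hum_in_pig.loc[shared]], axis=1),
        space="rpkm",
        provenance=["rpkm", "orthologous join (pig gene space)"],
    )
    q1 = joint.values.quantile(0.25)
    q3 = joint.values.quantile(0.75)
    pool = int(((joint.values >= q1) & (joint.values <= q3)).all(axis=1).sum())
    n_cons = cfg.n_conserved if cfg.n_conserved is not None else pool
    if cfg.n_conserved is not None and n_cons > pool:
        raise DataError(
            f"stage normalize: {n_cons} conserved genes requested, pool is {pool}"
        )
    if pool >= max(cfg.min_conserved, n_cons if cfg.n_conserved else 0) and n_cons > 0:
        conserved = nm.select_rank_conserved(joint, n_cons)
    else:
        # at many-sample desk scale the strict every-sample IQR rule can
        # empty the pool; anchor the medians on all shared genes instead
        logger.warning(
            "rank-conserved pool too small (%d); using all %d shared genes "
            "as the median anchor",
            pool,
            len(shared),
        )
        conserved = list(shared)
    scaled, scaling = nm.cross_species_scale(joint, conserved)
    logexpr = nm.log2_transform(scaled, cfg.log_pseudocount)
    write_tsv(
        pd.DataFrame(
            {"sample_median": scaling.sample_median, "factor": scaling.factor}
        ),
        out / "scaling.tsv",
        _provenance(cfg, "normalize"),
    )
    bundle["n_conserved"] = len(conserved)
    bundle["common_value"] = scaling.common_value

    meta = pd.concat(
        [matrices["pig"].sample_meta, matrices["human"].sample_meta]
    ).loc[logexpr.values.columns]

    # --- similarity per matched region (MG, naive) --------------------------
    region_pairs = list(zip(cfg.bulk.pig_regions, cfg.bulk.human_regions))
    sim_rows = []
    for pig_region, hum_region in region_pairs:
        pig_cols = meta.index[
            (meta.species == "pig")
            & (meta.region == pig_region)
            & (meta.plexus == "MG")
            & (meta.condition == "naive")
        ]
        hum_cols = meta.index[(meta.species == "human") & (meta.region == hum_region)]
        x = logexpr.values[pig_cols].mean(axis=1)
        y = logexpr.values[hum_cols].mean(axis=1)
        rep = sim.compare_profiles(x, y)
        sim_rows.append(
            {
                "pig_region": pig_region,
                "human_region": hum_region,
                "ks_D": rep.ks_statistic,
                "ks_p": rep.ks_p,
                "chisq": rep.chisq_statistic,
                "chisq_p": rep.chisq_p,
                "spearman_rho": rep.spearman_rho,
                "spearman_p": rep.spearman_p,
            }
        )
    sim_df = pd.DataFrame(sim_rows)
    write_tsv(sim_df, out / "similarity.tsv", _provenance(cfg, "similarity"), index=False)
    bundle["similarity"] = sim_df

    # --- differential expression -------------------------------------------
    def cols(species, region, plexus, condition):
        sel = meta.index[
            (meta.species == species)
            & (meta.region == region)
            & (meta.plexus == plexus)
            & (meta.condition == condition)
        ]
        return logexpr.values[sel]

    pig_r0, pig_r2 = cfg.bulk.pig_regions[0], cfg.bulk.pig_regions[-1]
    hum_r0, hum_r2 = cfg.bulk.human_regions[0], cfg.bulk.human_regions[-1]
    contrasts = {
        "pig_region": (cols("pig", pig_r0, "MG", "naive"), cols("pig", pig_r2, "MG", "naive")),
        "human_region": (cols("human", hum_r0, "MG", "naive"), cols("human", hum_r2, "MG", "naive")),
        "pig_region_vns": (cols("pig", pig_r0, "MG", "VNS"), cols("pig", pig_r2, "MG", "VNS")),
    }
    degs = {}
    for name, (a, b) in contrasts.items():
        if a.shape[1] < 2 or b.shape[1] < 2:
            raise DataError(f"stage de: contrast {name} lacks replicates")
        table = nm.simple_de(a, b, method=cfg.de_method)
        degs[name] = table
        write_tsv(
            table.rename_axis("gene"), out / f"deg.{name}.tsv", _provenance(cfg, "de")
        )
    bundle["degs"] = degs
    pig_deg = degs["pig_region"][degs["pig_region"].q < cfg.q_cut]
    hum_deg = degs["human_region"][degs["human_region"].q < cfg.q_cut]
    bundle["n_deg_pig"] = len(pig_deg)
    bundle["n_deg_human"] = len(hum_deg)

    # --- enrichment and the native (pig) map --------------------------------
    background = set(joint.values.index)
    enr = en.enrich_fisher(set(pig_deg.index), background, bp_db)
    write_tsv(enr, out / "enrichment.bp.tsv", _provenance(cfg, "enrich"))
    enr_specific = en.filter_specific_terms(
        enr,
        bp_db,
        min_genes=cfg.min_genes_per_term,
        min_mapped_fraction=cfg.min_mapped_fraction,
        level_range=cfg.go_level_range,
    )
    sig_terms = [
        bp_db[tid] for tid in enr_specific.index[enr_specific["q"] < cfg.q_cut]
    ]
    if not sig_terms:  # fall back to top-ranked terms so the map stage runs
        top = enr_specific.sort_values("p").head(10)
        sig_terms = [bp_db[tid] for tid in top.index]
    emap = en.build_enrichment_map(
        sig_terms,
        overlap_cutoff=cfg.overlap_cutoff,
        term_q=enr["q"].to_dict(),
        deg_genes=set(pig_deg.index),
    )
    emap.to_sif(out / "map.sif", out / "map.nodes.tsv", out / "map.edges.tsv")
    bundle["map_nodes"] = emap.graph.number_of_nodes()
    bundle["map_edges"] = emap.graph.number_of_edges()

    # --- cross-species coverage ---------------------------------------------
    # the joint matrix lives in the pig gene space; re-express the human
    # DEG list in its native namespace so the ortholog projection is
    # exercised the way externally supplied human DEG lists would be
    hum_deg_foreign, _ = map_gene_space(set(hum_deg.index), ortho, "a_to_b")
    try:
        cov = en.cross_species_match(
            emap,
            hum_deg_foreign,
            ortho,
            set(pig_deg.index),
            direction="b_to_a",
            mode=cfg.linkage_mode,
        )
        cov_row = dataclasses.asdict(cov)
    except ValueError:
        cov_row = {"linkage_coverage": float("nan"), "mode": cfg.linkage_mode}
    write_tsv(
        pd.DataFrame([cov_row]), out / "coverage.tsv", _provenance(cfg, "coverage"),
        index=False,
    )
    bundle["coverage"] = cov_row

    # --- WikiPathway scores --------------------------------------------------
    matched = ps.match_wp_degs(pig_deg, wp_db)
    score_rows = []
    up_genes = set(pig_deg.index[pig_deg.direction == "up"])
    down_genes = set(pig_deg.index[pig_deg.direction == "down"])
    enr_up = en.enrich_fisher(up_genes, background, wp_db) if up_genes else None
    enr_down = en.enrich_fisher(down_genes, background, wp_db) if down_genes else None
    pro_nodes = en.highlight_terms(emap, signatures["pro"])
    anti_nodes = en.highlight_terms(emap, signatures["anti"])
    for s in wp_db:
        row = ps.score_wikipathway(
            s.term_id, matched[s.term_id], pig_deg, enr["q"].to_dict(), emap
        )
        row["category"] = wp_db.category.get(s.term_id, "")
        if enr_up is not None and enr_down is not None:
            qu = float(np.clip(enr_up.loc[s.term_id, "q"], 1e-300, 1.0))
            qd = float(np.clip(enr_down.loc[s.term_id, "q"], 1e-300, 1.0))
            row["enrichment_ratio_up_down"] = ps.enrichment_ratio(qu, qd)
        pw_nodes = en.highlight_terms(emap, s.genes)
        row["pro_anti_ratio"] = ps.pro_anti_ratio(pw_nodes, pro_nodes, anti_nodes, emap)
        row["up_matched"] = ",".join(row["up_matched"])
        row["down_matched"] = ",".join(row["down_matched"])
        score_rows.append(row)
    wp_scores = pd.DataFrame(score_rows)
    write_tsv(wp_scores, out / "wikipathway_scores.tsv", _provenance(cfg, "scores"), index=False)
    bundle["wp_scores"] = wp_scores

    # --- single-cell summaries ----------------------------------------------
    cells_qc = ct.qc_filter(
        cells,
        cfg.qc_min_genes,
        cfg.qc_max_genes,
        cfg.qc_max_mito_pct,
        cfg.qc_min_cells_per_gene,
    )
    labels_qc = labels.loc[cells_qc.counts.columns]
    markers = ct.find_markers(cells_qc, labels_qc, cfg.marker_min_logfc)
    write_tsv(markers, out / "markers.tsv", _provenance(cfg, "cells"), index=False)
    ctype_degs = ct.celltype_deg_lists(markers, degs["pig_region"], cfg.celltype_p_cut)
    calls = ct.call_interactions(cells_qc, labels_qc, lr_pairs, cfg.lr_min_expr_fraction)
    calls = ct.vns_response(
        calls,
        degs["pig_region"]["p"].to_dict(),
        degs["pig_region_vns"]["p"].to_dict(),
    )
    call_df = pd.DataFrame(
        [
            {
                "source": c.source,
                "target": c.target,
                "ligand": c.pair.ligand,
                "receptor": c.pair.receptor,
                "present": c.present,
                "vns_up": c.vns_up,
            }
            for c in calls
        ]
    )
    write_tsv(call_df, out / "interactions.tsv", _provenance(cfg, "cells"), index=False)
    bundle["markers"] = markers
    bundle["celltype_degs"] = {k: len(v) for k, v in ctype_degs.items()}
    bundle["interactions"] = call_df
    bundle["cell_truth"] = cell_truth

    # --- cells-required reference numbers ------------------------------------
    bundle["cells_required_10types_2pct"] = ct.cells_required(10, 0.02, 6, 0.95)
    bundle["cells_required_5types_10pct"] = ct.cells_required(5, 0.10, 6, 0.95)
    with open(out / "summary.json", "w") as fh:
        json.dump(
            {
                k: v
                for k, v in bundle.items()
                if isinstance(v, (int, float, str, dict))
                and k not in ("degs", "celltype_degs", "cell_truth")
            },
            fh,
            indent=1,
            default=str,
        )
    return bundle
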