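"""High-quality 1:1 ortholog selection and cross-species gene-space projection.

Cross-species comparison of expression requires a trusted gene mapping.
Starting from a BioMart-style ortholog export (gene pair, homology type,
gene-order-conservation score, whole-genome-alignment score), this module
keeps only strict one-to-one pairs whose GOC and WGA scores both exceed a
quality threshold, enforces a bijection between the two gene namespaces,
and projects gene-keyed objects (DEG lists, expression rows) from one
species' gene space into the other's.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

ORTHOLOG_COLUMNS = ["gene_a", "gene_b", "homology_type", "goc_score", "wga_score"]

HOMOLOGY_TYPES = {"one2one", "one2many", "many2many"}


class OrthologError(ValueError):
    """Malformed ortholog record or misuse of an unfiltered table."""


@dataclass
class OrthologTable:
    """A scored cross-species gene mapping.

    Parameters
    ----------
    records
        DataFrame with columns ``gene_a, gene_b, homology_type, goc_score,
        wga_score``. Scores are in [0, 100].
    filtered
        True once the table has passed :func:`filter_high_quality`; only a
        filtered table guarantees the 1:1 bijection the projections rely on.
    """

    records: pd.DataFrame
    filtered: bool = False
    n_dropped_ambiguous: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        missing = [c for c in ORTHOLOG_COLUMNS if c not in self.records.columns]
        if missing:
            raise OrthologError(f"ortholog table missing columns: {missing}")
        self.records = self.records[ORTHOLOG_COLUMNS].reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        df = self.records
        for idx, row in enumerate(df.itertuples(index=False)):
            if pd.isna(row.goc_score) or pd.isna(row.wga_score):
                raise OrthologError(f"record {idx}: missing GOC/WGA score")
            if not (0 <= row.goc_score <= 100 and 0 <= row.wga_score <= 100):
                raise OrthologError(f"record {idx}: score outside [0, 100]")
            if not row.gene_a or not row.gene_b or pd.isna(row.gene_a) or pd.isna(row.gene_b):
                raise OrthologError(f"record {idx}: empty gene identifier")
        if self.filtered:
            if df["gene_a"].duplicated().any() or df["gene_b"].duplicated().any():
                raise OrthologError("filtered table violates 1:1 bijection")

    def __len__(self) -> int:
        return len(self.records)

    def mapping(self, direction: Literal["a_to_b", "b_to_a"] = "a_to_b") -> dict[str, str]:
        """Return the gene-to-gene dictionary in the requested direction."""
        if not self.filtered:
            raise OrthologError("mapping requires a filtered (bijective) table")
        if direction == "a_to_b":
            return dict(zip(self.records["gene_a"], self.records["gene_b"]))
        if direction == "b_to_a":
            return dict(zip(self.records["gene_b"], self.records["gene_a"]))
        raise ValueError(f"unknown direction {direction!r}")

    @classmethod
    def from_tsv(cls, path) -> "OrthologTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(df)

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def filter_high_quality(
    table: OrthologTable, min_goc: float = 75.0, min_wga: float = 75.0
) -> OrthologTable:
    """Keep strict 1:1 orthologs with both quality scores above threshold.

    Steps, in order: drop exact duplicate pairs; keep ``one2one`` records
    with ``goc_score > min_goc`` and ``wga_score > min_wga`` (strictly
    greater, per the "above 75" convention); then drop any record whose
    gene on either side still appears in more than one record, so the
    result is a strict bijection. Ambiguous drops are counted and logged.
    """
    if not (0 <= min_goc <= 100 and 0 <= min_wga <= 100):
        raise ValueError("thresholds must lie in [0, 100]")
    df = table.records.drop_duplicates(subset=["gene_a", "gene_b"])
    df = df[
        (df["homology_type"] == "one2one")
        & (df["goc_score"] > min_goc)
        & (df["wga_score"] > min_wga)
    ]
    # strictness over salvage: a gene seen twice disqualifies every record
    # it appears in
    amb_a = df["gene_a"].duplicated(keep=False)
    amb_b = df["gene_b"].duplicated(keep=False)
    n_ambiguous = int((amb_a | amb_b).sum())
    if n_ambiguous:
        logger.warning("dropped %d records with ambiguous 1:1 assignment", n_ambiguous)
    df = df[~(amb_a | amb_b)].reset_index(drop=True)
    return OrthologTable(df, filtered=True, n_dropped_ambiguous=n_ambiguous)


def map_gene_space(
    obj,
    table: OrthologTable,
    direction: Literal["a_to_b", "b_to_a"] = "a_to_b",
):
    """Project a gene-keyed object into the other species' gene space.

    ``obj`` may be a set/list of genes, a dict keyed by gene, a Series
    indexed by gene, or a DataFrame indexed by gene. Genes absent from the
    filtered mapping are dropped; values ride along unchanged. Returns
    ``(mapped_obj, n_dropped)``.
    """
    mapping = table.mapping(direction)

    if isinstance(obj, pd.DataFrame):
        keep = [g for g in obj.index if g in mapping]
        out = obj.loc[keep].rename(index=mapping)
        return out, len(obj.index) - len(keep)
    if isinstance(obj, pd.Series):
        keep = [g for g in obj.index if g in mapping]
        out = obj.loc[keep].rename(index=mapping)
        return out, len(obj.index) - len(keep)
    if isinstance(obj, Mapping):
        out = {mapping[g]: v for g, v in obj.items() if g in mapping}
        return out, len(obj) - len(out)
    if isinstance(obj, (set, frozenset)):
        out = {mapping[g] for g in obj if g in mapping}
        return out, len(obj) - len(out)
    if isinstance(obj, Iterable):
        genes = list(obj)
        out = [mapping[g] for g in genes if g in mapping]
        return out, len(genes) - len(out)
    raise TypeError(f"cannot map object of type {type(obj).__name__}")
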