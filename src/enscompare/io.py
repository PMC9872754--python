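"""Plain-text readers and writers for the pipeline's file formats.

Counts and metadata travel as TSV, gene sets as GMT with a sidecar TSV
(see :mod:`enscompare.enrichment`), single-cell UMI matrices as a
10x-style MatrixMarket triplet (matrix.mtx + features.tsv + barcodes.tsv),
and every emitted table can carry provenance header comments (# key: value)
that readers skip.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .celltype import CellMatrix
from .normalize import CountMatrix


def write_tsv(df: pd.DataFrame, path, provenance: dict | None = None, index=True) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (provenance or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_count_matrix(cm: CountMatrix, prefix) -> None:
    """Write counts, gene lengths and sample metadata as <prefix>.*.tsv."""
    prefix = Path(prefix)
    write_tsv(cm.counts, f"{prefix}.counts.tsv")
    write_tsv(cm.gene_length_bp.rename("length_bp").to_frame(), f"{prefix}.lengths.tsv")
    write_tsv(cm.total_mapped.rename("total_mapped").to_frame(), f"{prefix}.totals.tsv")
    write_tsv(cm.sample_meta, f"{prefix}.meta.tsv")


def read_count_matrix(prefix) -> CountMatrix:
    prefix = Path(prefix)
    counts = read_tsv(f"{prefix}.counts.tsv")
    lengths = read_tsv(f"{prefix}.lengths.tsv")["length_bp"]
    totals = read_tsv(f"{prefix}.totals.tsv")["total_mapped"]
    meta = read_tsv(f"{prefix}.meta.tsv")
    return CountMatrix(counts, lengths, totals, meta)


def write_cell_matrix(cm: CellMatrix, outdir) -> None:
    """10x-style triplet: matrix.mtx, features.tsv (with mito flag),
    barcodes.tsv, plus cells.meta.tsv when metadata is present."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.csc_matrix(cm.counts.to_numpy())
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), sparse)
    feats = pd.DataFrame(
        {
            "gene": cm.counts.index,
            "mito": [int(g in cm.mito_genes) for g in cm.counts.index],
        }
    )
    feats.to_csv(outdir / "features.tsv", sep="\t", index=False, header=False)
    pd.Series(cm.counts.columns).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )
    if len(cm.cell_meta):
        write_tsv(cm.cell_meta, outdir / "cells.meta.tsv")


def read_cell_matrix(outdir) -> CellMatrix:
    outdir = Path(outdir)
    mat = scipy.io.mmread(str(outdir / "matrix.mtx")).toarray().astype(np.int64)
    feats = pd.read_csv(
        outdir / "features.tsv", sep="\t", header=None, names=["gene", "mito"]
    )
    barcodes = pd.read_csv(outdir / "barcodes.tsv", sep="\t", header=None)[0]
    counts = pd.DataFrame(mat, index=feats["gene"].tolist(), columns=barcodes.tolist())
    mito = frozenset(feats.loc[feats["mito"] == 1, "gene"])
    meta_path = outdir / "cells.meta.tsv"
    meta = read_tsv(meta_path) if meta_path.exists() else pd.DataFrame()
    return CellMatrix(counts, meta, mito)
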