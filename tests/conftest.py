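import numpy as np
import pandas as pd
import pytest

from enscompare import (
    BulkConfig,
    CellConfig,
    GeneSet,
    OrthologTable,
    generate_bulk,
    generate_cells,
)


@pytest.fixture(scope="session")
def small_bulk():
    """One compact two-species bulk study with recorded truth."""
    cfg = BulkConfig(n_genes=600, n_deg_region=40, n_deg_plexus=20, n_deg_vns=20)
    matrices, table, truth = generate_bulk(cfg, seed=11)
    return matrices, table, truth


@pytest.fixture(scope="session")
def small_cells():
    cfg = CellConfig(cells_per_type=60, n_genes=400, n_markers_per_type=5)
    return generate_cells(cfg, seed=7)


@pytest.fixture()
def toy_ortholog_table():
    """Five records exercising every filtering rule: one survivor."""
    rows = [
        ("a1", "b1", "one2one", 80, 80),
        ("a2", "b2", "one2one", 75, 80),  # GOC at threshold: excluded
        ("a3", "b3", "one2one", 80, 74),  # WGA below threshold
        ("a4", "b4", "one2many", 90, 90),  # not strictly 1:1
        ("a1", "b1", "one2one", 80, 80),  # exact duplicate
    ]
    df = pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "homology_type", "goc_score", "wga_score"]
    )
    return OrthologTable(df)


@pytest.fixture()
def toy_terms():
    """Three terms: n1-n2 share 2 genes, n2-n3 share 3, n1-n3 disjoint."""
    return [
        GeneSet("n1", genes={"g1", "g2", "x1", "x2"}),
        GeneSet("n2", genes={"g1", "g2", "y1", "y2", "y3", "y4", "y5", "y6"}),
        GeneSet("n3", genes={"y4", "y5", "y6", "z1"}),
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
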