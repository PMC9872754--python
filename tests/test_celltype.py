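"""Single-cell QC, markers, ligand-receptor calls and the cell-number model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from enscompare.celltype import (
    CellMatrix,
    LRPair,
    call_interactions,
    cells_required,
    celltype_deg_lists,
    find_markers,
    qc_filter,
    vns_response,
)


def brute_force_cells_required(n_types, fraction, min_cells, confidence):
    """Independent oracle: incremental search with explicitly summed
    binomial tail probabilities."""
    n = min_cells
    while True:
        tail = sum(
            stats.binom.pmf(k, n, fraction) for k in range(min_cells, n + 1)
        )
        if tail**n_types >= confidence:
            return n
        n += 1


class TestQcFilter:
    def make_cells(self, detected_per_cell, mito_pct_per_cell, n_genes=3000):
        """Cells with controlled detected-gene counts and mito shares."""
        mito = ["MT-0"]
        body = [f"g{i}" for i in range(n_genes - 1)]
        cols = {}
        for i, (det, mpct) in enumerate(zip(detected_per_cell, mito_pct_per_cell)):
            col = np.zeros(n_genes)
            col[: det - 1] = 10  # det-1 body genes plus the mito gene
            body_total = col.sum()
            col[-1] = mpct / (100 - mpct) * body_total
            cols[f"c{i}"] = col
        counts = pd.DataFrame(cols, index=body + mito).round().astype(int)
        return CellMatrix(counts, mito_genes=frozenset(mito))

    def test_three_rules_applied_by_hand(self):
        # detected counts 150, 200, 2500, 2600, 300(6% mito), 300(5% mito)
        cm = self.make_cells(
            [150, 200, 2500, 2600, 300, 300], [1, 1, 1, 1, 6, 5]
        )
        out = qc_filter(cm, min_cells_per_gene=1)
        assert list(out.counts.columns) == ["c1", "c2", "c5"]

    def test_low_complexity_cell_removed(self):
        cm = self.make_cells([100, 300, 300, 300], [1, 1, 1, 1])
        out = qc_filter(cm, min_cells_per_gene=1)
        assert "c0" not in out.counts.columns

    def test_gene_filter_runs_after_cell_filter(self):
        # a gene expressed in 3 cells of which 1 fails QC ends below the
        # min-cells threshold and is removed
        counts = pd.DataFrame(
            {
                "bad": [1] + [1] * 250 + [0] * 250,
                "ok1": [1] + [1] * 500,
                "ok2": [1] + [1] * 500,
                "ok3": [0] + [1] * 500,
            },
            index=["special"] + [f"g{i}" for i in range(500)],
        )
        cm = CellMatrix(counts)
        out = qc_filter(cm, min_genes=400, max_genes=2500, min_cells_per_gene=3)
        assert "bad" not in out.counts.columns
        assert "special" not in out.counts.index

    def test_all_cells_removed_is_an_error(self):
        cm = self.make_cells([50, 60], [1, 1])
        with pytest.raises(ValueError, match="every cell"):
            qc_filter(cm)

    def test_order_stability(self, small_cells):
        cm, labels, _, _ = small_cells
        out1 = qc_filter(cm)
        perm = np.random.default_rng(3).permutation(cm.counts.shape[1])
        shuffled = CellMatrix(
            cm.counts.iloc[:, perm], cm.cell_meta.iloc[perm], cm.mito_genes
        )
        out2 = qc_filter(shuffled)
        assert set(out1.counts.columns) == set(out2.counts.columns)
        assert set(out1.counts.index) == set(out2.counts.index)


class TestFindMarkers:
    def test_planted_markers_recovered(self, small_cells):
        cm, labels, _, truth = small_cells
        cm = qc_filter(cm)
        markers = find_markers(cm, labels.loc[cm.counts.columns])
        for ct_name, planted in truth.markers.items():
            found = set(markers.loc[markers.cluster == ct_name, "gene"])
            present = set(planted) & set(cm.counts.index)
            hits = found & present
            assert len(hits) / len(present) >= 0.8
            sig = markers[
                (markers.cluster == ct_name) & markers.gene.isin(hits)
            ]
            assert (sig["q"] < 0.05).all()

    def test_exclusive_gene_is_a_marker(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(
            rng.poisson(2, (20, 30)), index=[f"g{i}" for i in range(20)]
        )
        counts.columns = [f"c{i}" for i in range(30)]
        counts.iloc[0, :15] = 20
        counts.iloc[0, 15:] = 0
        labels = pd.Series(["A"] * 15 + ["B"] * 15, index=counts.columns)
        markers = find_markers(CellMatrix(counts), labels)
        a_markers = set(markers.loc[markers.cluster == "A", "gene"])
        assert "g0" in a_markers

    def test_label_permutation_yields_no_confident_markers(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(
            rng.poisson(3, (100, 60)), index=[f"g{i}" for i in range(100)]
        )
        counts.columns = [f"c{i}" for i in range(60)]
        labels = pd.Series(rng.permutation(["A"] * 30 + ["B"] * 30), index=counts.columns)
        markers = find_markers(CellMatrix(counts), labels)
        assert (markers["q"] < 0.05).sum() == 0

    def test_reported_rows_respect_logfc_floor(self, small_cells):
        cm, labels, _, _ = small_cells
        markers = find_markers(cm, labels, min_logfc=0.25)
        assert (markers["avg_logfc"] > 0.25).all()


class TestCelltypeDegLists:
    def make_markers(self, genes):
        return pd.DataFrame(
            {"cluster": "A", "gene": genes, "avg_logfc": 1.0, "p": 0.001, "q": 0.01}
        )

    def make_degs(self, genes, ps):
        return pd.DataFrame(
            {"direction": "up", "lfc": 1.0, "p": ps, "q": ps}, index=genes
        )

    def test_no_overlap_gives_empty_list(self):
        out = celltype_deg_lists(
            self.make_markers(["m1"]), self.make_degs(["d1"], [0.01])
        )
        assert len(out["A"]) == 0

    def test_intersection_at_p_threshold(self):
        markers = self.make_markers(["g1", "g2", "g3", "g4", "g5"])
        degs = self.make_degs(
            ["g1", "g2", "g3", "x1"], [0.01, 0.04, 0.2, 0.001]
        )
        out = celltype_deg_lists(markers, degs, p_cut=0.05)
        assert set(out["A"].index) == {"g1", "g2"}
        assert (out["A"]["direction"] == "up").all()


class TestCallInteractions:
    def make_fixture(self):
        genes = ["lig", "rec", "dead_lig", "dead_rec", "filler"]
        cells = [f"c{i}" for i in range(40)]
        counts = pd.DataFrame(0, index=genes, columns=cells)
        labels = pd.Series(["A"] * 20 + ["B"] * 20, index=cells)
        counts.loc["filler"] = 1
        counts.loc["lig", cells[:10]] = 5  # 50% of A
        counts.loc["rec", cells[20:28]] = 5  # 40% of B
        return CellMatrix(counts), labels

    def test_planted_directed_call(self):
        cm, labels = self.make_fixture()
        pairs = [LRPair("lig", "rec"), LRPair("dead_lig", "dead_rec")]
        calls = call_interactions(cm, labels, pairs)
        found = {(c.source, c.target, c.pair.ligand) for c in calls}
        assert ("A", "B", "lig") in found
        assert all(c.pair.ligand != "dead_lig" for c in calls)

    def test_absent_ligand_no_call(self):
        cm, labels = self.make_fixture()
        calls = call_interactions(cm, labels, [LRPair("dead_lig", "rec")])
        assert calls == []

    def test_self_loops_allowed(self):
        cm, labels = self.make_fixture()
        cm.counts.loc["rec", cm.counts.columns[:10]] = 5  # rec also in A
        calls = call_interactions(cm, labels, [LRPair("lig", "rec")])
        assert ("A", "A") in {(c.source, c.target) for c in calls}

    def test_deterministic_and_flags_bounded(self, small_cells):
        cm, labels, pairs, truth = small_cells
        c1 = call_interactions(cm, labels, pairs)
        c2 = call_interactions(cm, labels, pairs)
        assert [(c.source, c.target) for c in c1] == [(c.source, c.target) for c in c2]
        flagged = vns_response(c1, {}, {})
        assert sum(c.vns_up for c in flagged) <= len(flagged)


class TestVnsResponse:
    def make_call(self):
        return [LRPair("lig", "rec")], [
            c
            for c in call_interactions(
                *TestCallInteractions().make_fixture(), [LRPair("lig", "rec")]
            )
        ]

    def test_identical_tables_no_flags(self):
        _, calls = self.make_call()
        out = vns_response(calls, {"lig": 0.5, "rec": 0.5}, {"lig": 0.5, "rec": 0.5})
        assert not any(c.vns_up for c in out)

    def test_ligand_gains_significance_sets_flag(self):
        _, calls = self.make_call()
        out = vns_response(calls, {"lig": 0.2, "rec": 0.5}, {"lig": 0.001, "rec": 0.5})
        assert all(c.vns_up for c in out)

    def test_missing_gene_treated_as_p_one(self):
        _, calls = self.make_call()
        with pytest.warns(UserWarning, match="missing"):
            out = vns_response(calls, {}, {"lig": 0.4, "rec": 1.0})
        assert all(c.vns_up for c in out)  # 0.4 < 1 (imputed naive p)
        assert all(c.ligand_p_naive == 1.0 for c in out)


class TestCellsRequired:
    def test_printed_minima_match_brute_force_oracle(self):
        for args in [(10, 0.02, 6, 0.95), (5, 0.10, 6, 0.95)]:
            assert cells_required(*args) == brute_force_cells_required(*args)
        assert cells_required(10, 0.02, 6, 0.95) == 702
        assert cells_required(5, 0.10, 6, 0.95) == 127

    def test_certainty_needs_exactly_min_cells(self):
        assert cells_required(1, 1.0, 1, 0.95) == 1

    def test_monotone_in_fraction_and_confidence(self):
        assert cells_required(5, 0.05, 6, 0.95) >= cells_required(5, 0.10, 6, 0.95)
        assert cells_required(5, 0.10, 6, 0.99) >= cells_required(5, 0.10, 6, 0.95)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            cells_required(5, 0.0, 6, 0.95)
        with pytest.raises(ValueError):
            cells_required(5, 0.1, 6, 1.5)

    def test_overcommitted_fractions_warn_only(self):
        with pytest.warns(UserWarning, match="sum above 1"):
            n = cells_required(20, 0.1, 2, 0.5)
        assert n >= 2
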