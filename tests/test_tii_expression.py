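import numpy as np
import pandas as pd
import pytest
from scipy import io as spio
from scipy import sparse

import chtii
from chtii.tii_expression import CellMatrix


def _toy_matrix():
    # 4 cells (3 immune, 1 epithelial) x 2 genes
    counts = sparse.csc_matrix(
        np.array(
            [
                [3, 0],  # T-cell: expresses g1
                [1, 2],  # myeloid: expresses both
                [0, 1],  # B-cell: expresses g2
                [2, 0],  # epithelial: expresses g1
            ]
        )
    )
    return CellMatrix(
        cells=["c1", "c2", "c3", "c4"],
        genes=["g1", "g2"],
        counts=counts,
        cell_type=["T-cell", "myeloid", "B-cell", "epithelial"],
        is_immune={"T-cell": True, "myeloid": True, "B-cell": True, "epithelial": False},
    )


class TestReadCellMatrix:
    def _write(self, tmp_path, with_label_for_all=True):
        mtx = sparse.coo_matrix(np.array([[1, 0], [0, 2], [3, 0]]))
        spio.mmwrite(str(tmp_path / "matrix.mtx"), mtx)
        (tmp_path / "barcodes.tsv").write_text("b1\nb2\nb3\n")
        (tmp_path / "genes.tsv").write_text("g1\ng2\n")
        labels = ["b1\tT-cell", "b2\tmyeloid"] + (["b3\tepithelial"] if with_label_for_all else [])
        (tmp_path / "celltypes.tsv").write_text("barcode\tcell_type\n" + "\n".join(labels) + "\n")

    def test_three_cell_toy_fixture(self, tmp_path):
        self._write(tmp_path)
        m = chtii.read_cell_matrix(
            tmp_path / "matrix.mtx",
            tmp_path / "barcodes.tsv",
            tmp_path / "genes.tsv",
            tmp_path / "celltypes.tsv",
        )
        assert m.n_cells == 3 and m.genes == ["g1", "g2"]
        assert m.cell_type == ["T-cell", "myeloid", "epithelial"]

    def test_missing_label_names_offending_barcode(self, tmp_path):
        self._write(tmp_path, with_label_for_all=False)
        with pytest.raises(ValueError, match="b3"):
            chtii.read_cell_matrix(
                tmp_path / "matrix.mtx",
                tmp_path / "barcodes.tsv",
                tmp_path / "genes.tsv",
                tmp_path / "celltypes.tsv",
            )

    def test_synthetic_bundle_cell_count_matches_manifest(self, bundle_dir):
        import json

        manifest = json.loads((bundle_dir / "manifest.json").read_text())
        expected = next(m["rows"] for m in manifest if m["path"] == "scrna/barcodes.tsv")
        m = chtii.read_cell_matrix(
            bundle_dir / "scrna" / "matrix.mtx",
            bundle_dir / "scrna" / "barcodes.tsv",
            bundle_dir / "scrna" / "genes.tsv",
            bundle_dir / "scrna" / "celltypes.tsv",
        )
        assert m.n_cells == expected


class TestSummarizeGeneExpression:
    def test_toy_counts(self):
        out = chtii.summarize_gene_expression(_toy_matrix(), "g1")
        # g1 expressed in 3 cells, 2 of them immune
        assert out["n_cells_expressing"] == 3
        assert out["n_immune_cells_expressing"] == 2
        assert out["immune_fraction"] == pytest.approx(2 / 3, abs=1e-9)

    def test_breakdown_sums_to_one_over_immune_labels(self):
        out = chtii.summarize_gene_expression(_toy_matrix(), "g2")
        assert sum(out["celltype_breakdown"].values()) == pytest.approx(1.0)
        assert set(out["celltype_breakdown"]) == {"myeloid", "B-cell"}

    def test_candidate_scale_ratio_reports_23_percent(self):
        # 12,075 expressing cells of which 2,810 are immune: the ratio the
        # candidate table prints as "23%"
        n_cells = 13000
        rows = np.arange(12075)
        counts = sparse.csc_matrix(
            (np.ones(12075, dtype=int), (rows, np.zeros(12075, dtype=int))),
            shape=(n_cells, 1),
        )
        types = ["T-cell"] * 2810 + ["epithelial"] * (n_cells - 2810)
        m = CellMatrix(
            cells=[f"c{i}" for i in range(n_cells)],
            genes=["g"],
            counts=counts,
            cell_type=types,
            is_immune={"T-cell": True, "epithelial": False},
        )
        out = chtii.summarize_gene_expression(m, "g")
        assert out["n_immune_cells_expressing"] == 2810
        assert out["n_cells_expressing"] == 12075
        assert round(out["immune_fraction"], 4) == 0.2327
        assert chtii.report_percent(2810, 12075, 0) == 23

    def test_unexpressed_gene_has_absent_fraction(self):
        m = _toy_matrix()
        empty = CellMatrix(
            cells=m.cells,
            genes=["g0"],
            counts=sparse.csc_matrix((4, 1), dtype=int),
            cell_type=m.cell_type,
            is_immune=m.is_immune,
        )
        out = chtii.summarize_gene_expression(empty, "g0")
        assert out["n_cells_expressing"] == 0 and out["immune_fraction"] is None

    def test_unknown_gene_is_a_lookup_error(self):
        with pytest.raises(KeyError):
            chtii.summarize_gene_expression(_toy_matrix(), "nope")

    def test_invariant_under_cell_permutation(self):
        m = _toy_matrix()
        perm = [2, 0, 3, 1]
        permuted = CellMatrix(
            cells=[m.cells[i] for i in perm],
            genes=m.genes,
            counts=sparse.csc_matrix(m.counts.toarray()[perm]),
            cell_type=[m.cell_type[i] for i in perm],
            is_immune=m.is_immune,
        )
        a = chtii.summarize_gene_expression(m, "g1")
        b = chtii.summarize_gene_expression(permuted, "g1")
        assert a["immune_fraction"] == b["immune_fraction"]
        assert a["celltype_breakdown"] == b["celltype_breakdown"]

    def test_adding_non_expressing_cell_changes_nothing(self):
        m = _toy_matrix()
        grown = CellMatrix(
            cells=m.cells + ["c5"],
            genes=m.genes,
            counts=sparse.csc_matrix(np.vstack([m.counts.toarray(), [0, 0]])),
            cell_type=m.cell_type + ["T-cell"],
            is_immune=m.is_immune,
        )
        for gene in m.genes:
            a = chtii.summarize_gene_expression(m, gene)
            b = chtii.summarize_gene_expression(grown, gene)
            assert (a["n_cells_expressing"], a["n_immune_cells_expressing"]) == (
                b["n_cells_expressing"],
                b["n_immune_cells_expressing"],
            )


class TestFilterExpressedInImmune:
    def test_silent_in_immune_gene_removed(self, default_cohort):
        gt = default_cohort.ground_truth
        matrix = default_cohort.cell_matrix()
        maf = default_cohort.annotated_maf()
        variant_gene = maf.drop_duplicates("variant_id").set_index("variant_id")["Hugo_Symbol"]
        candidates = pd.DataFrame(
            [
                {"variant_id": vid, "gene": variant_gene[vid]}
                for vid, label in gt.labels.items()
                if label in ("planted_ch", "passenger:expression")
            ]
        )
        silenced_genes = {
            variant_gene[vid]
            for vid, label in gt.labels.items()
            if label == "passenger:expression"
        }
        summaries = {
            g: chtii.summarize_gene_expression(matrix, g) for g in candidates["gene"].unique()
        }
        kept = chtii.filter_expressed_in_immune(summaries, candidates)
        assert silenced_genes.isdisjoint(kept["gene"])
        assert len(kept) == len(candidates) - 1

    def test_empty_candidates(self):
        kept = chtii.filter_expressed_in_immune({}, pd.DataFrame({"gene": []}))
        assert len(kept) == 0


class TestCelltypeComposition:
    def test_single_gene_all_t_cells(self):
        s = {
            "n_immune_cells_expressing": 10,
            "celltype_breakdown": {"T-cell": 1.0},
        }
        assert chtii.celltype_composition([s]) == {"T-cell": 1.0}

    def test_pooled_split_hand_computed(self):
        a = {"n_immune_cells_expressing": 100, "celltype_breakdown": {"T-cell": 1.0}}
        b = {
            "n_immune_cells_expressing": 100,
            "celltype_breakdown": {"T-cell": 0.2, "myeloid": 0.8},
        }
        out = chtii.celltype_composition([a, b])
        assert out["T-cell"] == pytest.approx(0.6)
        assert out["myeloid"] == pytest.approx(0.4)

    def test_synthetic_composition_recovered(self, default_cohort):
        gt = default_cohort.ground_truth
        matrix = default_cohort.cell_matrix()
        planted_genes = {
            row["Hugo_Symbol"]
            for _, row in default_cohort.annotated_maf().iterrows()
            if gt.labels.get(row["variant_id"]) == "planted_ch"
        }
        summaries = [chtii.summarize_gene_expression(matrix, g) for g in planted_genes]
        pooled = chtii.celltype_composition(summaries)
        for label, expected in gt.immune_composition.items():
            assert pooled.get(label, 0.0) == pytest.approx(expected, abs=0.05)

    def test_all_zero_pool_is_a_domain_error(self):
        with pytest.raises(ValueError):
            chtii.celltype_composition(
                [{"n_immune_cells_expressing": 0, "celltype_breakdown": {}}]
            )
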