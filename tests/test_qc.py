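"""QC cascade: boundary behaviour, composition, planted-roster recovery."""

import numpy as np
import pandas as pd
import pytest

from sccurate import QCConfig, run_qc
from sccurate.io import GeneAnnotation
from sccurate.qc import (
    filter_cells_coding,
    filter_cells_min_genes,
    filter_cells_mito,
    filter_cells_outlier,
    filter_rare_cell_types,
    filter_samples_min_cells,
    restrict_core_genes,
)
from conftest import make_matrix


def _annotation(symbols, biotype="protein_coding", mito=(), chromosome="chr1"):
    return GeneAnnotation(
        pd.DataFrame(
            {
                "chromosome": chromosome,
                "biotype": [biotype] * len(symbols) if isinstance(biotype, str) else biotype,
                "is_mitochondrial": [g in set(mito) for g in symbols],
                "exonic_length_bp": 1000,
                "is_chrX_unique": False,
            },
            index=pd.Index(symbols, name="symbol"),
        )
    )


def _cell_with_detected(n_detected, n_genes):
    row = np.zeros(n_genes, dtype=int)
    row[:n_detected] = 1
    return row


class TestMinGenes:
    @pytest.mark.parametrize("detected,kept", [(199, False), (200, True)])
    def test_threshold_boundary(self, detected, kept):
        m = make_matrix(np.vstack([_cell_with_detected(d, 250) for d in (detected, 250)]))
        out, removed = filter_cells_min_genes(m, 200)
        assert ("c0" not in removed) == kept

    def test_empty_matrix(self):
        m = make_matrix(np.zeros((0, 5), dtype=int), samples=[])
        out, removed = filter_cells_min_genes(m, 200)
        assert out.n_cells == 0 and removed == []


class TestMinCellsPerSample:
    @pytest.mark.parametrize("n_cells,kept", [(2, False), (3, True)])
    def test_threshold_boundary(self, n_cells, kept):
        m = make_matrix(np.ones((n_cells + 3, 2), dtype=int),
                        samples=["probe"] * n_cells + ["big"] * 3)
        out, removed_samples = filter_samples_min_cells(m, 3)
        assert ("probe" in removed_samples) == (not kept)

    def test_single_sample_below_threshold_warns_and_empties(self):
        m = make_matrix(np.ones((2, 2), dtype=int))
        with pytest.warns(UserWarning, match="every sample"):
            out, removed = filter_samples_min_cells(m, 3)
        assert out.n_cells == 0 and removed == ["s0"]


class TestCodingFilter:
    def test_other_biotype_genes_do_not_count(self):
        genes = [f"cod{i}" for i in range(6)] + [f"oth{i}" for i in range(50)]
        ann = _annotation(genes, biotype=["protein_coding"] * 6 + ["other"] * 50)
        m = make_matrix(np.ones((1, 56), dtype=int), genes=genes)
        out, removed = filter_cells_coding(m, ann, 7)
        assert removed == ["c0"]

    def test_mirna_pools_with_protein_coding(self):
        genes = [f"mir{i}" for i in range(7)]
        ann = _annotation(genes, biotype=["miRNA"] * 7)
        m = make_matrix(np.ones((1, 7), dtype=int), genes=genes)
        out, removed = filter_cells_coding(m, ann, 7)
        assert removed == []

    def test_annotation_without_coding_genes_removes_all_with_warning(self):
        genes = ["a", "b"]
        ann = _annotation(genes, biotype=["other", "other"])
        m = make_matrix(np.ones((3, 2), dtype=int), genes=genes)
        with pytest.warns(UserWarning, match="protein_coding"):
            out, removed = filter_cells_coding(m, ann, 7)
        assert out.n_cells == 0


class TestMitoFilter:
    @pytest.mark.parametrize("mito_counts,kept", [(16, False), (15, True)])
    def test_exceeding_is_strict(self, mito_counts, kept):
        genes = ["MT-1", "nuc"]
        ann = _annotation(genes, mito=["MT-1"])
        m = make_matrix(np.array([[mito_counts, 100 - mito_counts]]), genes=genes)
        out, removed = filter_cells_mito(m, ann, 0.15)
        assert (removed == []) == kept

    def test_no_mito_genes_removes_nothing(self):
        ann = _annotation(["a", "b"])
        m = make_matrix(np.ones((4, 2), dtype=int))
        renamed = make_matrix(np.ones((4, 2), dtype=int), genes=["a", "b"])
        out, removed = filter_cells_mito(renamed, ann, 0.15)
        assert removed == []

    def test_zero_total_cell_removed(self):
        ann = _annotation(["a", "b"])
        m = make_matrix(np.array([[0, 0], [1, 1]]), genes=["a", "b"])
        out, removed = filter_cells_mito(m, ann, 0.15)
        assert removed == ["c0"]


class TestOutlierFilter:
    def test_exceedance_matches_direct_computation(self):
        # 10 cells with 100 detected genes, one with 500
        detected = [100] * 10 + [500]
        m = make_matrix(np.vstack([_cell_with_detected(d, 600) for d in detected]))
        vals = np.array(detected, dtype=float)
        cut = vals.mean() + 3 * vals.std()
        out, removed = filter_cells_outlier(m, 3.0)
        assert (removed == ["c10"]) == (500 > cut)

    def test_identical_cells_sd_zero_none_removed(self):
        m = make_matrix(np.ones((5, 10), dtype=int))
        out, removed = filter_cells_outlier(m)
        assert removed == []

    def test_single_cell_sample_skipped(self):
        m = make_matrix(np.vstack([_cell_with_detected(d, 600) for d in (500, 100, 100, 100)]),
                        samples=["solo", "s", "s", "s"])
        out, removed = filter_cells_outlier(m)
        assert "c0" not in removed


class TestCoreGenesAndRareTypes:
    def test_core_restriction_preserves_matrix_order(self):
        m = make_matrix(np.ones((2, 5), dtype=int), genes=list("abcde"))
        out, removed = restrict_core_genes(m, ["e", "c", "a"])
        assert list(out.gene_symbols) == ["a", "c", "e"]
        assert removed == ["b", "d"]

    def test_superset_core_list_is_identity(self):
        m = make_matrix(np.ones((2, 3), dtype=int), genes=list("abc"))
        out, removed = restrict_core_genes(m, list("abcdef"))
        assert list(out.gene_symbols) == ["a", "b", "c"] and removed == []

    def test_disjoint_core_list_errors(self):
        m = make_matrix(np.ones((2, 3), dtype=int), genes=list("abc"))
        with pytest.raises(ValueError, match="core gene"):
            restrict_core_genes(m, ["x", "y"])

    @pytest.mark.parametrize("n_cells,kept", [(19, False), (20, True)])
    def test_rare_type_boundary(self, n_cells, kept):
        total = n_cells + 25
        m = make_matrix(np.ones((total, 2), dtype=int))
        labels = ["rare"] * n_cells + ["common"] * 25
        out, removed = filter_rare_cell_types(m, np.array(labels, dtype=object), 20)
        assert (len(removed) == 0) == kept

    def test_unlabeled_cells_untouched(self):
        m = make_matrix(np.ones((3, 2), dtype=int))
        labels = np.array(["t"] * 2 + [None], dtype=object)
        with pytest.warns(UserWarning, match="no type label"):
            out, removed = filter_rare_cell_types(m, labels, 2)
        assert "c2" not in removed


class TestRunQC:
    def test_planted_rosters_recovered_exactly(self, default_corpus, clean_corpus):
        _, _, _, truth = default_corpus
        _, report = clean_corpus
        for stage in ["min_genes", "min_cells_per_sample", "coding", "mito", "outlier"]:
            assert set(report.removed_cells[stage]) == truth.qc_violations[stage], stage

    def test_attrition_chain_consistent(self, clean_corpus):
        clean, report = clean_corpus
        report.validate()
        frame = report.to_frame()
        assert frame["removed"].sum() == report.cells_in - clean.n_cells

    def test_idempotence(self, default_corpus, clean_corpus):
        _, annotation, _, _ = default_corpus
        clean, _ = clean_corpus
        clean2, report2 = run_qc(clean, annotation, QCConfig())
        assert clean2.n_cells == clean.n_cells
        assert set(clean2.cell_ids) == set(clean.cell_ids)
        assert all(r == 0 for _, _, r in report2.stages)

    def test_all_clean_corpus_is_identity(self):
        genes = [f"g{i}" for i in range(30)]
        ann = _annotation(genes)
        m = make_matrix(np.ones((8, 30), dtype=int),
                        samples=["s0"] * 4 + ["s1"] * 4, genes=genes)
        cfg = QCConfig(min_genes_per_cell=10, min_coding_genes_per_cell=5)
        out, report = run_qc(m, ann, cfg)
        assert out.n_cells == 8
        assert all(r == 0 for _, _, r in report.stages)

    def test_cell_level_filters_commute_without_sample_deletion(self, default_corpus):
        """min-genes, coding and mito removals are pairwise commutative
        when no sample drops below the census floor."""
        cells, annotation, _, _ = default_corpus
        a1, _ = filter_cells_min_genes(cells, 200)
        ab, _ = filter_cells_coding(a1, annotation, 7)
        b1, _ = filter_cells_coding(cells, annotation, 7)
        ba, _ = filter_cells_min_genes(b1, 200)
        assert set(ab.cell_ids) == set(ba.cell_ids)
        a2, _ = filter_cells_mito(a1, annotation, 0.15)
        b2, _ = filter_cells_mito(cells, annotation, 0.15)
        b2, _ = filter_cells_min_genes(b2, 200)
        assert set(a2.cell_ids) == set(b2.cell_ids)
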