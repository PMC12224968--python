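"""Staged quality-control cascade over cells, samples and genes.

Stage order is fixed: minimum detected genes per cell → minimum cells per
sample → minimum protein-coding/miRNA genes per cell → mitochondrial
fraction → per-sample detected-gene outliers → core-gene restriction →
(optional) rare annotated cell types. All threshold comparisons are strict
in the direction of the rule's wording: "fewer than" / "less than" remove
below the threshold (retention is ≥), "exceeding" removes above it
(retention is ≤).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io import CellMatrix, GeneAnnotation, QCReport

__all__ = [
    "QCConfig",
    "filter_cells_min_genes",
    "filter_samples_min_cells",
    "filter_cells_coding",
    "filter_cells_mito",
    "filter_cells_outlier",
    "restrict_core_genes",
    "filter_rare_cell_types",
    "run_qc",
]


@dataclass
class QCConfig:
    """Thresholds of the QC cascade.

    Defaults follow the curation pipeline's published constants: cells
    need at least 200 detected genes and at least 7 protein-coding or
    miRNA genes; samples need at least 3 cells; cells with a
    mitochondrial-count fraction exceeding 15% or a detected-gene count
    more than 3 sample-level standard deviations above the sample mean
    are removed. The core-gene restriction and rare-cell-type stage are
    optional.
    """

    min_genes_per_cell: int = 200
    min_cells_per_sample: int = 3
    min_coding_genes_per_cell: int = 7
    max_mito_fraction: float = 0.15
    outlier_sd_multiplier: float = 3.0
    core_gene_list: Sequence[str] | None = None
    min_cells_per_annotated_type: int = 20

    def __post_init__(self) -> None:
        if min(self.min_genes_per_cell, self.min_cells_per_sample,
               self.min_coding_genes_per_cell, self.min_cells_per_annotated_type) <= 0:
            raise ValueError("count thresholds must be positive")
        if not 0 < self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction must lie in (0, 1]")
        if self.outlier_sd_multiplier <= 0:
            raise ValueError("outlier_sd_multiplier must be positive")


def _split(matrix: CellMatrix, remove_mask: np.ndarray) -> tuple[CellMatrix, list[str]]:
    removed = [str(c) for c in matrix.cell_ids[remove_mask]]
    return matrix.subset_cells(~remove_mask), removed


def filter_cells_min_genes(matrix: CellMatrix, min_genes: int = 200) -> tuple[CellMatrix, list[str]]:
    """Remove cells with fewer than ``min_genes`` detected genes."""
    detected = matrix.detected_genes_per_cell()
    return _split(matrix, detected < min_genes)


def filter_samples_min_cells(matrix: CellMatrix, min_cells: int = 3) -> tuple[CellMatrix, list[str]]:
    """Remove whole samples with fewer than ``min_cells`` surviving cells.

    Returns the filtered matrix and the list of removed *sample* ids. Run
    after cell-level removals so the per-sample census reflects survivors.
    """
    samples, counts = np.unique(matrix.sample_of_cell, return_counts=True)
    bad = set(samples[counts < min_cells])
    if len(bad) == len(samples) and len(samples) > 0:
        warnings.warn("every sample fell below the minimum cell count; matrix is empty")
    mask = np.array([s in bad for s in matrix.sample_of_cell])
    kept, _ = _split(matrix, mask)
    return kept, sorted(bad)


def filter_cells_coding(
    matrix: CellMatrix, annotation: GeneAnnotation, min_coding: int = 7
) -> tuple[CellMatrix, list[str]]:
    """Remove cells expressing fewer than ``min_coding`` protein-coding or
    miRNA genes. Genes missing from the annotation count as biotype
    ``other``."""
    coding = set(annotation.coding_like_symbols())
    col_mask = np.array([g in coding for g in matrix.gene_symbols])
    if not col_mask.any():
        warnings.warn("no matrix gene is annotated protein_coding/miRNA; all cells removed")
        return _split(matrix, np.ones(matrix.n_cells, dtype=bool))
    sub = matrix.counts[:, col_mask]
    n_coding = np.asarray((sub > 0).sum(axis=1)).ravel()
    return _split(matrix, n_coding < min_coding)


def filter_cells_mito(
    matrix: CellMatrix, annotation: GeneAnnotation, max_fraction: float = 0.15
) -> tuple[CellMatrix, list[str]]:
    """Remove cells whose mitochondrial count fraction exceeds
    ``max_fraction`` (strictly); cells with zero total counts are removed
    too."""
    mito = set(annotation.mito_symbols())
    col_mask = np.array([g in mito for g in matrix.gene_symbols])
    total = matrix.total_counts_per_cell().astype(float)
    mito_counts = (
        np.asarray(matrix.counts[:, col_mask].sum(axis=1)).ravel()
        if col_mask.any()
        else np.zeros(matrix.n_cells)
    )
    zero_total = total == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(zero_total, np.inf, mito_counts / np.where(zero_total, 1, total))
    return _split(matrix, (frac > max_fraction) | zero_total)


def filter_cells_outlier(
    matrix: CellMatrix, sd_multiplier: float = 3.0
) -> tuple[CellMatrix, list[str]]:
    """Remove cells whose detected-gene count exceeds mean + k·SD within
    their own sample (upper tail only; population SD over the sample's
    cells). Samples with fewer than 2 cells skip the stage."""
    detected = matrix.detected_genes_per_cell().astype(float)
    remove = np.zeros(matrix.n_cells, dtype=bool)
    for s in matrix.samples:
        idx = np.flatnonzero(matrix.sample_of_cell == s)
        if len(idx) < 2:
            continue
        vals = detected[idx]
        cut = vals.mean() + sd_multiplier * vals.std()
        remove[idx] = vals > cut
    return _split(matrix, remove)


def restrict_core_genes(
    matrix: CellMatrix, core_list: Sequence[str]
) -> tuple[CellMatrix, list[str]]:
    """Keep only genes present in the core gene list (matrix order
    preserved); error on an empty intersection."""
    core = set(core_list)
    keep = np.array([g in core for g in matrix.gene_symbols])
    if not keep.any():
        raise ValueError("core gene list shares no genes with the matrix")
    removed = [str(g) for g in matrix.gene_symbols[~keep]]
    return matrix.subset_genes(keep), removed


def filter_rare_cell_types(
    matrix: CellMatrix, type_labels: Mapping[str, str] | np.ndarray, min_cells: int = 20
) -> tuple[CellMatrix, list[str]]:
    """Remove cells of annotated types represented by fewer than
    ``min_cells`` cells. Unlabeled cells are untouched (with a warning)."""
    if isinstance(type_labels, Mapping):
        labels = np.array([type_labels.get(str(c)) for c in matrix.cell_ids], dtype=object)
    else:
        labels = np.asarray(type_labels, dtype=object)
        if len(labels) != matrix.n_cells:
            raise ValueError("type_labels length mismatch")
    unlabeled = np.array([l is None or l == "" for l in labels])
    if unlabeled.any():
        warnings.warn(f"{int(unlabeled.sum())} cells have no type label; left untouched")
    types, counts = np.unique(labels[~unlabeled].astype(str), return_counts=True)
    rare = set(types[counts < min_cells])
    remove = np.array(
        [not u and str(l) in rare for u, l in zip(unlabeled, labels)]
    )
    return _split(matrix, remove)


def run_qc(
    matrix: CellMatrix,
    annotation: GeneAnnotation,
    config: QCConfig | None = None,
    type_labels: Mapping[str, str] | None = None,
) -> tuple[CellMatrix, QCReport]:
    """Run the full staged cascade and account for every removal.

    Returns the cleaned matrix and a :class:`QCReport` whose per-stage
    attrition chain sums exactly to ``cells_in - cells_out``. The
    rare-cell-type stage runs only when ``type_labels`` is given; the
    core-gene restriction only when ``config.core_gene_list`` is set.
    """
    config = config or QCConfig()
    report = QCReport()

    m = matrix
    before = m.n_cells
    m, removed = filter_cells_min_genes(m, config.min_genes_per_cell)
    report.add_stage("min_genes", before, removed)

    before = m.n_cells
    m, removed_samples = filter_samples_min_cells(m, config.min_cells_per_sample)
    sample_cells = before - m.n_cells
    report.stages.append(("min_cells_per_sample", before, sample_cells))
    report.samples_removed = removed_samples
    # record the individual cells too, so rosters stay cell-addressable
    gone = set(matrix.cell_ids) - set(m.cell_ids) - {
        c for ids in report.removed_cells.values() for c in ids
    }
    report.removed_cells["min_cells_per_sample"] = sorted(gone)

    before = m.n_cells
    m, removed = filter_cells_coding(m, annotation, config.min_coding_genes_per_cell)
    report.add_stage("coding", before, removed)

    before = m.n_cells
    m, removed = filter_cells_mito(m, annotation, config.max_mito_fraction)
    report.add_stage("mito", before, removed)

    before = m.n_cells
    m, removed = filter_cells_outlier(m, config.outlier_sd_multiplier)
    report.add_stage("outlier", before, removed)

    if config.core_gene_list is not None:
        before = m.n_cells
        m, removed_genes = restrict_core_genes(m, config.core_gene_list)
        report.stages.append(("core_genes", before, 0))
        report.genes_removed = removed_genes

    if type_labels is not None:
        before = m.n_cells
        m, removed = filter_rare_cell_types(m, type_labels, config.min_cells_per_annotated_type)
        report.add_stage("rare_types", before, removed)

    report.validate()
    return m, report
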