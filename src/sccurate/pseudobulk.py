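"""Pseudo-bulk aggregation, FPKM conversion, per-gene CV, pseudo-cell pooling.

Pseudo-bulk sums raw counts over a grouping of cells (sample, organ or
cluster). FPKM then normalizes by exonic gene length (kb) and group
sequencing depth (millions): FPKM = 1e9 · c / (L · C). The coefficient of
variation of a gene's FPKM across groups (sample SD / mean) is the
instability half of the stable-gene statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CellMatrix, GeneAnnotation, UNKNOWN_ORGAN

__all__ = [
    "PseudoBulkMatrix",
    "aggregate",
    "counts_to_fpkm",
    "gene_cv",
    "pool_pseudocells",
]


@dataclass
class PseudoBulkMatrix:
    """Dense groups × genes matrix in either raw-count or FPKM units."""

    values: np.ndarray
    group_ids: np.ndarray
    gene_symbols: np.ndarray
    unit: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.group_ids = np.asarray(self.group_ids, dtype=object)
        self.gene_symbols = np.asarray(self.gene_symbols, dtype=object)
        if self.values.shape != (len(self.group_ids), len(self.gene_symbols)):
            raise ValueError("values shape does not match group/gene labels")
        if self.unit not in ("counts", "FPKM"):
            raise ValueError(f"unit must be 'counts' or 'FPKM', got {self.unit!r}")
        if not np.isfinite(self.values).all() or (self.values < 0).any():
            raise ValueError("pseudo-bulk values must be finite and non-negative")
        if len(set(self.group_ids)) != len(self.group_ids):
            raise ValueError("duplicate group ids")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.group_ids, columns=self.gene_symbols)


_GROUP_FIELDS = {"sample": "sample_of_cell", "organ": "organ_of_cell"}


def aggregate(
    matrix: CellMatrix,
    group_by: str = "sample",
    labels: Sequence[str] | None = None,
) -> PseudoBulkMatrix:
    """Sum counts over cell groups.

    ``group_by`` is ``"sample"``, ``"organ"`` or ``"cluster"``; the latter
    requires explicit per-cell ``labels``. Total mass is conserved exactly.
    """
    if group_by == "cluster":
        if labels is None:
            raise ValueError("group_by='cluster' requires explicit labels")
        lab = np.asarray(labels, dtype=object)
    elif group_by in _GROUP_FIELDS:
        lab = getattr(matrix, _GROUP_FIELDS[group_by])
    else:
        raise ValueError(f"unknown group_by {group_by!r}")
    if len(lab) != matrix.n_cells:
        raise ValueError("label length mismatch")
    groups = pd.unique(lab)
    codes = pd.Categorical(lab, categories=groups).codes
    indicator = sp.csr_matrix(
        (np.ones(matrix.n_cells), (codes, np.arange(matrix.n_cells))),
        shape=(len(groups), matrix.n_cells),
    )
    sums = np.asarray((indicator @ matrix.counts).todense())
    return PseudoBulkMatrix(sums, groups, matrix.gene_symbols, unit="counts")


def counts_to_fpkm(pb: PseudoBulkMatrix, annotation: GeneAnnotation) -> PseudoBulkMatrix:
    """FPKM(g, j) = counts(g, j) · 1e9 / (length_j · total_counts_g).

    Zero-depth groups produce an all-zero row with a warning.
    """
    if pb.unit != "counts":
        raise ValueError("counts_to_fpkm expects a counts-unit matrix")
    lengths = annotation.lengths_for(pb.gene_symbols)
    totals = pb.values.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"groups with zero total counts get all-zero FPKM rows: "
            f"{list(pb.group_ids[zero])}"
        )
    denom = np.where(zero, 1.0, totals)
    fpkm = pb.values * 1e9 / (lengths[None, :] * denom[:, None])
    fpkm[zero] = 0.0
    return PseudoBulkMatrix(fpkm, pb.group_ids, pb.gene_symbols, unit="FPKM")


def gene_cv(pb: PseudoBulkMatrix) -> pd.Series:
    """Per-gene coefficient of variation across groups.

    CV = sample SD (ddof=1) / mean over groups; genes with mean 0 get the
    +inf sentinel (least stable). Requires at least 2 groups.
    """
    if len(pb.group_ids) < 2:
        raise ValueError("CV requires at least 2 pseudo-bulk groups")
    mean = pb.values.mean(axis=0)
    sd = pb.values.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), np.inf)
    return pd.Series(cv, index=pb.gene_symbols, name="cv")


def pool_pseudocells(
    matrix: CellMatrix,
    cluster_labels: Sequence[str],
    pool_size: int = 100,
    seed: int = 0,
) -> CellMatrix:
    """Pool cells within clusters into pseudo-cells of ``pool_size`` cells.

    Cells of each cluster are randomly partitioned (seeded) into
    consecutive pools; a remainder pool is kept iff it holds at least
    ``pool_size / 2`` cells. Each pseudo-cell carries its cluster id as
    sample label and the cluster's majority organ.
    """
    labels = np.asarray(cluster_labels, dtype=object)
    if len(labels) != matrix.n_cells:
        raise ValueError("cluster_labels length mismatch")
    rng = np.random.default_rng(seed)
    rows, ids, samples, organs = [], [], [], []
    for cl in pd.unique(labels):
        idx = np.flatnonzero(labels == cl)
        organ_counts = pd.Series(matrix.organ_of_cell[idx]).value_counts()
        majority_organ = organ_counts.index[0] if len(organ_counts) else UNKNOWN_ORGAN
        perm = rng.permutation(idx)
        k = 0
        for start in range(0, len(perm), pool_size):
            chunk = perm[start : start + pool_size]
            if len(chunk) < pool_size and len(chunk) < pool_size / 2:
                continue
            rows.append(np.asarray(matrix.counts[chunk].sum(axis=0)).ravel())
            ids.append(f"{cl}_pc{k}")
            samples.append(str(cl))
            organs.append(majority_organ)
            k += 1
    if not rows:
        counts = sp.csr_matrix((0, matrix.n_genes), dtype=np.int64)
    else:
        counts = sp.csr_matrix(np.vstack(rows))
    return CellMatrix(
        counts=counts,
        cell_ids=np.array(ids, dtype=object),
        gene_symbols=matrix.gene_symbols,
        sample_of_cell=np.array(samples, dtype=object),
        organ_of_cell=np.array(organs, dtype=object),
        species=matrix.species,
    )
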