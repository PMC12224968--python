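"""AI-ready corpus preparation: median normalization and rank encoding.

Rank-based transcriptome foundation models consume, per cell, the genes
ordered by expression normalized against each gene's corpus-wide typical
level. The typical level is the median of a gene's *non-zero* counts
(zeros would collapse most medians to 0 and break the division); the
per-cell sequence orders genes by count/median descending.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import CellMatrix

__all__ = [
    "RankedCellRecord",
    "compute_gene_medians",
    "rank_encode",
    "export_corpus",
    "RankEncoder",
]


@dataclass(frozen=True)
class RankedCellRecord:
    """One cell's rank-encoded transcriptome: genes in descending
    median-normalized expression, ties broken by ascending symbol."""

    cell_id: str
    genes: tuple[str, ...]
    values: tuple[float, ...]


def compute_gene_medians(matrix: CellMatrix) -> pd.Series:
    """Median of each gene's strictly positive counts over the corpus.

    Genes never expressed are absent from the table; an all-zero corpus
    errors.
    """
    if matrix.counts.nnz == 0:
        raise ValueError("corpus has no non-zero counts")
    csc = matrix.counts.tocsc()
    medians = {}
    for j, g in enumerate(matrix.gene_symbols):
        col = csc.data[csc.indptr[j] : csc.indptr[j + 1]]
        if len(col):
            medians[g] = float(np.median(col))
    return pd.Series(medians, name="nonzero_median")


def rank_encode(
    cell_counts: Mapping[str, float] | pd.Series,
    medians: pd.Series,
    cell_id: str = "",
    max_genes: int | None = None,
) -> RankedCellRecord:
    """Rank-encode one cell against the corpus median table.

    Zero-count genes are excluded; expressed genes are normalized by
    their median and sorted descending, ties by symbol ascending.
    ``max_genes`` optionally truncates the sequence.
    """
    series = pd.Series(cell_counts)
    expressed = series[series > 0]
    norm = [
        (g, float(c) / float(medians[g]))
        for g, c in expressed.items()
        if g in medians.index
    ]
    norm.sort(key=lambda item: (-item[1], item[0]))
    if max_genes is not None:
        norm = norm[:max_genes]
    return RankedCellRecord(
        cell_id=str(cell_id),
        genes=tuple(g for g, _ in norm),
        values=tuple(v for _, v in norm),
    )


def _encode_all(matrix: CellMatrix, medians: pd.Series, max_genes: int | None):
    for i in range(matrix.n_cells):
        row = matrix.counts.getrow(i)
        counts = pd.Series(row.data, index=matrix.gene_symbols[row.indices])
        yield rank_encode(counts, medians, cell_id=str(matrix.cell_ids[i]), max_genes=max_genes)


def export_corpus(
    matrix: CellMatrix,
    medians: pd.Series,
    format: str,
    path: str | Path,
    max_genes: int | None = None,
) -> list[Path]:
    """Export the corpus for foundation-model consumption.

    ``format="ranked_jsonl"`` writes ``cells.jsonl`` (one record per cell:
    cell_id, genes, values) and ``vocab.tsv`` (symbol → integer id,
    frequency-ordered then symbol-ordered) under ``path``;
    ``format="matrix_h5ad"`` writes the counts with the median table as
    gene metadata. Output is byte-deterministic given the input.
    """
    path = Path(path)
    if format == "ranked_jsonl":
        path.mkdir(parents=True, exist_ok=True)
        jsonl = path / "cells.jsonl"
        freq = np.asarray((matrix.counts > 0).sum(axis=0)).ravel()
        expressed = [
            (str(g), int(f)) for g, f in zip(matrix.gene_symbols, freq) if f > 0
        ]
        expressed.sort(key=lambda item: (-item[1], item[0]))
        with open(jsonl, "w") as fh:
            for rec in _encode_all(matrix, medians, max_genes):
                fh.write(
                    json.dumps(
                        {
                            "cell_id": rec.cell_id,
                            "genes": list(rec.genes),
                            "values": list(rec.values),
                        },
                        sort_keys=True,
                    )
                    + "\n"
                )
        vocab = path / "vocab.tsv"
        with open(vocab, "w") as fh:
            fh.write("symbol\tid\tn_cells_expressed\n")
            for idx, (g, f) in enumerate(expressed):
                fh.write(f"{g}\t{idx}\t{f}\n")
        return [jsonl, vocab]
    if format == "matrix_h5ad":
        path = path if path.suffix == ".h5ad" else path / "corpus.h5ad"
        path.parent.mkdir(parents=True, exist_ok=True)
        adata = matrix.to_anndata()
        adata.var["nonzero_median"] = medians.reindex(adata.var_names).to_numpy()
        adata.write_h5ad(str(path))
        return [path]
    raise ValueError(f"unknown export format {format!r}")


class RankEncoder(BaseEstimator, TransformerMixin):
    """Transformer from raw counts to rank-encoded cell records.

    ``fit`` learns the per-gene non-zero median table (``medians_``);
    ``transform`` returns one :class:`RankedCellRecord` per cell.

    Parameters
    ----------
    max_genes
        Optional truncation of each cell's sequence (default: none).
    """

    def __init__(self, max_genes: int | None = None):
        self.max_genes = max_genes

    def fit(self, X: CellMatrix, y=None) -> "RankEncoder":
        self.medians_ = compute_gene_medians(X)
        return self

    def transform(self, X: CellMatrix) -> list[RankedCellRecord]:
        if not hasattr(self, "medians_"):
            raise ValueError("RankEncoder is not fitted")
        return list(_encode_all(X, self.medians_, self.max_genes))
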