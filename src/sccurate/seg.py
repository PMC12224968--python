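"""Stable-expression-gene (SEG) identification.

A gene's stability is scored by two statistics: the single-cell zero-rate
(fraction of cells with a zero count) and the coefficient of variation of
its pseudo-bulk FPKM across groups. Each statistic is ranked ascending,
the two ranks are summed, and the summed score is ranked again; the top N
genes — N sized by a bulk-derived housekeeping-gene (HKG) reference list —
are the SEGs.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import CellMatrix, GeneAnnotation
from .pseudobulk import PseudoBulkMatrix, aggregate, counts_to_fpkm, gene_cv

__all__ = [
    "gene_zero_rate",
    "rank_stability",
    "select_segs",
    "hkg_overlap",
    "StableGeneRanker",
]


def gene_zero_rate(matrix: CellMatrix) -> pd.Series:
    """Fraction of cells with a zero count, per gene."""
    if matrix.n_cells == 0:
        raise ValueError("zero-rate undefined on an empty matrix")
    nonzero_cells = np.asarray((matrix.counts > 0).sum(axis=0)).ravel()
    return pd.Series(
        1.0 - nonzero_cells / matrix.n_cells, index=matrix.gene_symbols, name="zero_rate"
    )


def _rank_ascending(values: pd.Series) -> pd.Series:
    """Dense 1..G ranking, ascending in value, ties broken by symbol."""
    order = sorted(values.index, key=lambda g: (values[g], str(g)))
    return pd.Series(np.arange(1, len(order) + 1), index=order).reindex(values.index)


def rank_stability(zero_rates: pd.Series, cvs: pd.Series) -> pd.DataFrame:
    """Combine zero-rate and CV rankings into a total stability order.

    Both statistics are ranked ascending (+inf CV last); the combined
    score is the sum of the two ranks, itself ranked ascending. All ties
    break lexicographically by symbol, so the ordering is a deterministic,
    permutation-invariant total order.

    Returns a DataFrame indexed by symbol with columns zero_rate, cv,
    zero_rank, cv_rank, combined_rank.
    """
    if set(zero_rates.index) != set(cvs.index):
        raise ValueError("zero_rates and cvs must cover the same gene universe")
    cvs = cvs.reindex(zero_rates.index)
    zero_rank = _rank_ascending(zero_rates)
    cv_rank = _rank_ascending(cvs)
    score = zero_rank + cv_rank
    combined_rank = _rank_ascending(score.astype(float))
    out = pd.DataFrame(
        {
            "zero_rate": zero_rates,
            "cv": cvs,
            "zero_rank": zero_rank,
            "cv_rank": cv_rank,
            "combined_rank": combined_rank,
        }
    )
    return out.sort_values("combined_rank")


def select_segs(stability: pd.DataFrame, hkg_list: Sequence[str]) -> list[str]:
    """Top combined-rank genes, as many as the HKG reference holds.

    HKG symbols absent from the gene universe are dropped (with a
    warning) before sizing N.
    """
    if not list(hkg_list):
        raise ValueError("empty HKG reference list")
    present = [g for g in dict.fromkeys(hkg_list) if g in stability.index]
    absent = len(dict.fromkeys(hkg_list)) - len(present)
    if absent:
        warnings.warn(f"{absent} HKG symbols absent from the matrix; N sized on the rest")
    if not present:
        raise ValueError("no HKG symbol overlaps the gene universe")
    n = len(present)
    return list(stability.sort_values("combined_rank").index[:n])


def hkg_overlap(seg_list: Sequence[str], hkg_list: Sequence[str]) -> float:
    """|SEG ∩ HKG| / |HKG| — the overlap fraction reported against the
    housekeeping reference."""
    if not list(seg_list) or not list(hkg_list):
        raise ValueError("overlap needs two non-empty lists")
    hkg = list(dict.fromkeys(hkg_list))
    return len(set(seg_list) & set(hkg)) / len(hkg)


class StableGeneRanker(BaseEstimator):
    """Estimator wrapping the SEG statistic.

    ``fit`` computes per-gene zero-rates on the cell matrix and CVs on a
    per-group pseudo-bulk FPKM matrix, then the combined stability
    ranking. Fitted attributes: ``stability_`` (the ranked table),
    ``segs_`` (if an HKG list was given), ``overlap_``.

    Parameters
    ----------
    group_by
        Pseudo-bulk grouping for the CV statistic (default "sample").
    hkg_list
        Optional housekeeping reference sizing the SEG set.
    """

    def __init__(self, group_by: str = "sample", hkg_list: Sequence[str] | None = None):
        self.group_by = group_by
        self.hkg_list = hkg_list

    def fit(self, X: CellMatrix, annotation: GeneAnnotation) -> "StableGeneRanker":
        zero = gene_zero_rate(X)
        pb = counts_to_fpkm(aggregate(X, group_by=self.group_by), annotation)
        cv = gene_cv(pb)
        self.stability_ = rank_stability(zero, cv)
        if self.hkg_list is not None:
            self.segs_ = select_segs(self.stability_, self.hkg_list)
            self.overlap_ = hkg_overlap(self.segs_, self.hkg_list)
        return self
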