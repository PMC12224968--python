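"""Organ-specific-gene (OSG) calling from per-organ zero-rates.

A gene counts as *expressed* in an organ when its zero-rate there is at
most 90% of cells; an OSG is a gene expressed in at least one and at most
two organs, and it is assigned to every organ in which it is expressed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import CellMatrix
from .seg import gene_zero_rate

__all__ = ["OrganZeroRateTable", "organ_zero_rates", "call_osgs", "OrganSpecificGeneCaller"]


@dataclass
class OrganZeroRateTable:
    """Genes × organs zero-rate matrix plus the per-organ cell census."""

    zero_rates: pd.DataFrame  # genes × organs, values in [0, 1]
    cells_per_organ: pd.Series

    def __post_init__(self) -> None:
        vals = self.zero_rates.to_numpy()
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError("zero rates must lie in [0, 1]")


def organ_zero_rates(matrix: CellMatrix, min_cells_per_organ: int = 50) -> OrganZeroRateTable:
    """Per-organ per-gene zero-rates.

    Organs represented by fewer than ``min_cells_per_organ`` cells are
    excluded with a warning (their zero-rates would be too noisy to call
    specificity on); if no organ meets the floor, an error is raised.
    """
    organs, counts = np.unique(matrix.organ_of_cell, return_counts=True)
    keep = [o for o, c in zip(organs, counts) if c >= min_cells_per_organ]
    skipped = [o for o, c in zip(organs, counts) if c < min_cells_per_organ]
    if skipped:
        warnings.warn(f"organs below the {min_cells_per_organ}-cell floor skipped: {skipped}")
    if not keep:
        raise ValueError("no organ meets the minimum cell floor")
    cols = {}
    census = {}
    for o in keep:
        sub = matrix.subset_cells(matrix.organ_of_cell == o)
        cols[o] = gene_zero_rate(sub)
        census[o] = sub.n_cells
    table = pd.DataFrame(cols)
    return OrganZeroRateTable(table, pd.Series(census, name="cells"))


def call_osgs(
    table: OrganZeroRateTable,
    expressed_max_zero_rate: float = 0.90,
    max_organs: int = 2,
) -> pd.DataFrame:
    """Call organ-specific genes from the zero-rate table.

    A gene is expressed in an organ iff its zero-rate there is
    ≤ ``expressed_max_zero_rate``; genes expressed in 1..``max_organs``
    organs are OSGs of each such organ. Returns a DataFrame with one row
    per (gene, organ) assignment: symbol, organ, zero_rate,
    n_organs_expressed.
    """
    zr = table.zero_rates
    expressed = zr <= expressed_max_zero_rate
    n_expr = expressed.sum(axis=1)
    is_osg = (n_expr >= 1) & (n_expr <= max_organs)
    rows = []
    for gene in zr.index[is_osg]:
        for organ in zr.columns[expressed.loc[gene]]:
            rows.append(
                {
                    "symbol": gene,
                    "organ": organ,
                    "zero_rate": zr.at[gene, organ],
                    "n_organs_expressed": int(n_expr[gene]),
                }
            )
    return pd.DataFrame(rows, columns=["symbol", "organ", "zero_rate", "n_organs_expressed"])


class OrganSpecificGeneCaller(BaseEstimator):
    """Estimator wrapping OSG calling.

    ``fit`` computes the per-organ zero-rate table and the OSG calls.
    Fitted attributes: ``table_`` (:class:`OrganZeroRateTable`),
    ``calls_`` (assignment DataFrame), ``osg_map_`` (organ → gene list).
    """

    def __init__(
        self,
        expressed_max_zero_rate: float = 0.90,
        max_organs: int = 2,
        min_cells_per_organ: int = 50,
    ):
        self.expressed_max_zero_rate = expressed_max_zero_rate
        self.max_organs = max_organs
        self.min_cells_per_organ = min_cells_per_organ

    def fit(self, X: CellMatrix) -> "OrganSpecificGeneCaller":
        self.table_ = organ_zero_rates(X, self.min_cells_per_organ)
        self.calls_ = call_osgs(self.table_, self.expressed_max_zero_rate, self.max_organs)
        self.osg_map_ = {
            organ: sorted(grp["symbol"]) for organ, grp in self.calls_.groupby("organ")
        }
        return self
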