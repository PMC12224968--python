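"""Core data containers and readers/writers.

The pipeline's universal currency is :class:`CellMatrix`: a sparse
cells × genes raw-count matrix with per-cell sample and organ labels.
Readers cover the 10x Matrix Market triplet dialect and AnnData h5ad;
per-gene annotation and per-sample metadata arrive as TSV tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CellMatrix",
    "GeneAnnotation",
    "QCReport",
    "FormatError",
    "read_mtx",
    "read_h5ad",
    "write_h5ad",
    "read_gene_annotation",
    "read_gene_list",
    "read_sample_metadata",
]

UNKNOWN_ORGAN = "unknown"

BIOTYPES = ("protein_coding", "miRNA", "other")

SPECIES = ("human", "mouse", "other")

SEX_LABELS = ("male", "female", "mixed", "unknown")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _as_str_array(values: Iterable) -> np.ndarray:
    return np.asarray(list(values), dtype=object)


@dataclass
class CellMatrix:
    """Sparse cells × genes raw counts with per-cell labels.

    Parameters
    ----------
    counts
        Non-negative integer matrix, one row per cell, stored CSR.
    cell_ids, gene_symbols
        Unique identifiers for the two axes.
    sample_of_cell
        Sample label per cell (required).
    organ_of_cell
        Organ label per cell; ``"unknown"`` where not annotated.
    species
        Corpus-level species tag.
    """

    counts: sp.csr_matrix
    cell_ids: np.ndarray
    gene_symbols: np.ndarray
    sample_of_cell: np.ndarray
    organ_of_cell: np.ndarray | None = None
    species: str = "other"

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.nnz:
            data = self.counts.data
            if np.isnan(data).any():
                raise ValueError("counts contain NaN")
            if (data < 0).any():
                raise ValueError("counts must be non-negative")
            if not np.allclose(data, np.round(data)):
                bad = data[~np.isclose(data, np.round(data))][:5]
                raise ValueError(f"counts must be integers; found {bad}")
        self.counts.data = np.round(self.counts.data).astype(np.int64)
        self.counts.eliminate_zeros()
        self.cell_ids = _as_str_array(self.cell_ids)
        self.gene_symbols = _as_str_array(self.gene_symbols)
        self.sample_of_cell = _as_str_array(self.sample_of_cell)
        if self.organ_of_cell is None:
            self.organ_of_cell = np.full(self.n_cells, UNKNOWN_ORGAN, dtype=object)
        else:
            self.organ_of_cell = _as_str_array(self.organ_of_cell)
        n, g = self.counts.shape
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} matrix rows")
        if len(self.gene_symbols) != g:
            raise ValueError(f"{len(self.gene_symbols)} gene symbols for {g} matrix columns")
        if len(self.sample_of_cell) != n or len(self.organ_of_cell) != n:
            raise ValueError("per-cell label length mismatch")
        for name, ids in (("cell_ids", self.cell_ids), ("gene_symbols", self.gene_symbols)):
            if len(set(ids)) != len(ids):
                seen: set = set()
                dup = next(x for x in ids if x in seen or seen.add(x))
                raise ValueError(f"duplicate entry in {name}: {dup!r}")

    # -- basic geometry ------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def samples(self) -> np.ndarray:
        return pd.unique(self.sample_of_cell)

    def detected_genes_per_cell(self) -> np.ndarray:
        """Number of genes with count > 0 in each cell."""
        return np.diff(self.counts.indptr)

    def total_counts_per_cell(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def gene_index(self, symbols: Sequence[str]) -> np.ndarray:
        """Column indices of ``symbols``; raises on unknown symbols."""
        lookup = {s: i for i, s in enumerate(self.gene_symbols)}
        missing = [s for s in symbols if s not in lookup]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        return np.array([lookup[s] for s in symbols], dtype=int)

    # -- subsetting ----------------------------------------------------

    def subset_cells(self, keep: np.ndarray) -> "CellMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CellMatrix(
            counts=self.counts[keep],
            cell_ids=self.cell_ids[keep],
            gene_symbols=self.gene_symbols,
            sample_of_cell=self.sample_of_cell[keep],
            organ_of_cell=self.organ_of_cell[keep],
            species=self.species,
        )

    def subset_genes(self, keep: np.ndarray) -> "CellMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CellMatrix(
            counts=self.counts[:, keep],
            cell_ids=self.cell_ids,
            gene_symbols=self.gene_symbols[keep],
            sample_of_cell=self.sample_of_cell,
            organ_of_cell=self.organ_of_cell,
            species=self.species,
        )

    # -- AnnData bridge ------------------------------------------------

    def to_anndata(self) -> ad.AnnData:
        obs = pd.DataFrame(
            {
                "sample": pd.Categorical(self.sample_of_cell),
                "organ": pd.Categorical(self.organ_of_cell),
            },
            index=pd.Index(self.cell_ids.astype(str), name="cell_id"),
        )
        var = pd.DataFrame(index=pd.Index(self.gene_symbols.astype(str), name="symbol"))
        adata = ad.AnnData(X=self.counts.copy(), obs=obs, var=var)
        adata.uns["species"] = self.species
        return adata

    @classmethod
    def from_anndata(cls, adata: ad.AnnData, layer: str | None = None) -> "CellMatrix":
        if layer is None:
            X = adata.X
        else:
            if layer not in adata.layers:
                raise FormatError(
                    f"count layer {layer!r} not found; available layers: {list(adata.layers)}"
                )
            X = adata.layers[layer]
        if X is None:
            raise FormatError(
                f"no count matrix in AnnData; available layers: {list(adata.layers)}"
            )
        X = sp.csr_matrix(X)
        sample = (
            adata.obs["sample"].astype(str).to_numpy()
            if "sample" in adata.obs
            else adata.obs_names.to_numpy(dtype=object)
        )
        organ = (
            adata.obs["organ"].astype(str).to_numpy()
            if "organ" in adata.obs
            else None
        )
        return cls(
            counts=X,
            cell_ids=adata.obs_names.to_numpy(dtype=object),
            gene_symbols=adata.var_names.to_numpy(dtype=object),
            sample_of_cell=sample,
            organ_of_cell=organ,
            species=str(adata.uns.get("species", "other")),
        )


@dataclass
class GeneAnnotation:
    """Per-gene annotation: chromosome, biotype, mito flag, exonic length.

    Backed by a DataFrame indexed by gene symbol with columns
    ``chromosome``, ``biotype``, ``is_mitochondrial``, ``exonic_length_bp``,
    ``is_chrX_unique``. ``is_chrX_unique`` marks chrX genes with no chrY
    homolog (the numerator of the X-Ratio statistic).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {
            "chromosome",
            "biotype",
            "is_mitochondrial",
            "exonic_length_bp",
            "is_chrX_unique",
        }
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"annotation missing columns: {sorted(missing)}")
        if self.table.index.duplicated().any():
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ValueError(f"duplicate gene symbol in annotation: {dup!r}")
        bad_bio = set(self.table["biotype"]) - set(BIOTYPES)
        if bad_bio:
            raise FormatError(
                f"unknown biotype(s) {sorted(bad_bio)}; allowed: {list(BIOTYPES)}"
            )
        if (self.table["exonic_length_bp"] < 1).any():
            raise ValueError("exonic_length_bp must be >= 1")
        bad_uniq = self.table["is_chrX_unique"] & (self.table["chromosome"] != "chrX")
        if bad_uniq.any():
            raise ValueError(
                "is_chrX_unique set for non-chrX gene(s): "
                f"{list(self.table.index[bad_uniq][:5])}"
            )

    @property
    def symbols(self) -> np.ndarray:
        return self.table.index.to_numpy(dtype=object)

    def __len__(self) -> int:
        return len(self.table)

    def coding_like_symbols(self) -> np.ndarray:
        """Symbols whose biotype is protein_coding or miRNA (pooled in QC)."""
        mask = self.table["biotype"].isin(["protein_coding", "miRNA"])
        return self.table.index[mask].to_numpy(dtype=object)

    def mito_symbols(self) -> np.ndarray:
        return self.table.index[self.table["is_mitochondrial"]].to_numpy(dtype=object)

    def chromosome_symbols(self, chromosome: str) -> np.ndarray:
        return self.table.index[self.table["chromosome"] == chromosome].to_numpy(dtype=object)

    def chrx_unique_symbols(self) -> np.ndarray:
        return self.table.index[self.table["is_chrX_unique"]].to_numpy(dtype=object)

    def lengths_for(self, symbols: Sequence[str]) -> np.ndarray:
        missing = [s for s in symbols if s not in self.table.index]
        if missing:
            raise KeyError(f"no exonic length for genes: {missing[:10]}")
        return self.table.loc[list(symbols), "exonic_length_bp"].to_numpy(dtype=float)


@dataclass
class QCReport:
    """Attrition accounting for the staged QC cascade.

    ``stages`` is an ordered list of (filter_name, cells_before,
    cells_removed); the chain invariant ``before[k+1] == before[k] -
    removed[k]`` is validated on demand.
    """

    stages: list[tuple[str, int, int]] = field(default_factory=list)
    samples_removed: list[str] = field(default_factory=list)
    genes_removed: list[str] = field(default_factory=list)
    removed_cells: dict[str, list[str]] = field(default_factory=dict)

    def add_stage(self, name: str, before: int, removed_ids: Sequence[str]) -> None:
        self.stages.append((name, int(before), len(removed_ids)))
        self.removed_cells[name] = [str(c) for c in removed_ids]

    def validate(self) -> None:
        for (n0, b0, r0), (n1, b1, _r1) in zip(self.stages, self.stages[1:]):
            if b1 != b0 - r0:
                raise ValueError(
                    f"attrition chain broken between {n0!r} and {n1!r}: "
                    f"{b0} - {r0} != {b1}"
                )
        if any(b < 0 or r < 0 for _, b, r in self.stages):
            raise ValueError("negative attrition count")

    @property
    def cells_in(self) -> int:
        return self.stages[0][1] if self.stages else 0

    @property
    def cells_out(self) -> int:
        if not self.stages:
            return 0
        name, before, removed = self.stages[-1]
        return before - removed

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"stage": name, "before": before, "removed": removed, "after": before - removed}
            for name, before, removed in self.stages
        ]
        return pd.DataFrame(rows, columns=["stage", "before", "removed", "after"])


# ----------------------------------------------------------------------
# Readers / writers
# ----------------------------------------------------------------------


def _sample_from_barcodes(
    barcodes: Sequence[str], sample_map: Mapping[str, str] | None
) -> np.ndarray:
    """Resolve a sample label per barcode.

    An explicit barcode → sample map wins; otherwise the suffix after the
    last ``-`` in the barcode is taken as the sample id, and barcodes with
    no suffix fall into a single implicit sample.
    """
    out = np.empty(len(barcodes), dtype=object)
    for i, bc in enumerate(barcodes):
        if sample_map is not None and bc in sample_map:
            out[i] = str(sample_map[bc])
        elif "-" in bc:
            out[i] = bc.rsplit("-", 1)[1]
        else:
            out[i] = "sample0"
    return out


def read_mtx(
    matrix_path: str | Path,
    barcodes_path: str | Path,
    features_path: str | Path,
    sample_table: pd.DataFrame | None = None,
    sample_map: Mapping[str, str] | None = None,
    species: str = "other",
) -> CellMatrix:
    """Read a 10x-style Matrix Market triplet into a :class:`CellMatrix`.

    Orientation (genes × cells vs cells × genes) is auto-detected from the
    barcode and feature file lengths. Cells are joined to sample metadata
    through ``sample_map`` (barcode → sample id) or, failing that, the
    ``-<sample_id>`` barcode suffix dialect.
    """
    mat = sp.csr_matrix(scipy.io.mmread(str(matrix_path)))
    barcodes = [ln.split("\t")[0] for ln in _read_lines(barcodes_path)]
    feat_rows = [ln.split("\t") for ln in _read_lines(features_path)]
    features = [row[0] for row in feat_rows]
    if len(set(features)) != len(features):
        raise FormatError("duplicate gene symbol in features file")
    if len(set(barcodes)) != len(barcodes):
        raise FormatError("duplicate barcode in barcodes file")

    nb, nf = len(barcodes), len(features)
    if mat.shape == (nb, nf):
        pass  # cells × genes already
    elif mat.shape == (nf, nb):
        mat = sp.csr_matrix(mat.T)
    else:
        raise FormatError(
            f"matrix shape {mat.shape} matches neither {nb} barcodes × {nf} features "
            "nor its transpose"
        )

    sample_of_cell = _sample_from_barcodes(barcodes, sample_map)
    organ = None
    if sample_table is not None:
        meta = sample_table.set_index("sample_id") if "sample_id" in sample_table else sample_table
        organ = np.array(
            [
                str(meta.at[s, "organ"]) if s in meta.index and "organ" in meta else UNKNOWN_ORGAN
                for s in sample_of_cell
            ],
            dtype=object,
        )
    return CellMatrix(
        counts=mat,
        cell_ids=np.array(barcodes, dtype=object),
        gene_symbols=np.array(features, dtype=object),
        sample_of_cell=sample_of_cell,
        organ_of_cell=organ,
        species=species,
    )


def _read_lines(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [ln.rstrip("\n") for ln in fh if ln.strip()]


def read_h5ad(path: str | Path, layer: str | None = None) -> CellMatrix:
    """Read raw counts from an h5ad file.

    ``layer=None`` reads the main matrix; otherwise the named layer.
    Float-typed counts are accepted when losslessly integral.
    """
    adata = ad.read_h5ad(str(path))
    return CellMatrix.from_anndata(adata, layer=layer)


def write_h5ad(matrix: CellMatrix, path: str | Path) -> None:
    matrix.to_anndata().write_h5ad(str(path))


def read_gene_annotation(tsv_path: str | Path) -> GeneAnnotation:
    """Read the per-gene annotation TSV (header required).

    Columns: symbol, chromosome, biotype, is_mitochondrial,
    exonic_length_bp, is_chrX_unique.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype={"symbol": str, "chromosome": str})
    required = {"symbol", "chromosome", "biotype", "exonic_length_bp"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"annotation TSV missing columns: {sorted(missing)}")
    for col, default in (("is_mitochondrial", False), ("is_chrX_unique", False)):
        if col not in df:
            df[col] = default
        else:
            df[col] = df[col].map(_parse_bool)
    df = df.set_index("symbol")
    return GeneAnnotation(df)


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "1", "t", "yes"):
        return True
    if s in ("false", "0", "f", "no"):
        return False
    raise FormatError(f"cannot parse boolean value {v!r}")


def read_gene_list(path: str | Path) -> list[str]:
    """One symbol per line; de-duplicated preserving first occurrence."""
    seen: set[str] = set()
    out: list[str] = []
    for ln in _read_lines(path):
        sym = ln.strip()
        if sym and sym not in seen:
            seen.add(sym)
            out.append(sym)
    return out


def read_sample_metadata(tsv_path: str | Path) -> pd.DataFrame:
    """Read per-sample metadata (sample_id, species, organ, declared_sex)."""
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise FormatError("sample metadata TSV must have a sample_id column")
    if df["sample_id"].duplicated().any():
        raise FormatError("duplicate sample_id in metadata")
    for col, default in (("species", "other"), ("organ", UNKNOWN_ORGAN), ("declared_sex", "unknown")):
        if col not in df:
            df[col] = default
    bad_sex = set(df["declared_sex"]) - set(SEX_LABELS)
    if bad_sex:
        raise FormatError(f"unknown declared_sex value(s) {sorted(bad_sex)}; allowed {SEX_LABELS}")
    return df
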