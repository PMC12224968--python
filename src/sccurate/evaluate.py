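"""Clustering-based gene-set evaluation and classification metrics.

Gene sets (all expressed genes vs a housekeeping reference vs the SEG
set) are compared by how well k-means clusters cells using only those
genes, scored with the Calinski-Harabasz index and the silhouette score
over repeated seeded subsamples. Accuracy/recall/precision summarize
binary agreement with planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import calinski_harabasz_score, silhouette_score

from .io import CellMatrix

__all__ = [
    "kmeans",
    "calinski_harabasz",
    "silhouette",
    "evaluate_gene_sets",
    "classification_metrics",
    "ClassificationMetrics",
]


def kmeans(points, k: int, seed: int = 0, n_init: int = 10, max_iter: int = 300) -> np.ndarray:
    """Lloyd's k-means with k-means++ seeding, best of ``n_init`` starts."""
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if k > len(X):
        raise ValueError(f"k={k} exceeds the {len(X)} available points")
    km = KMeans(n_clusters=k, n_init=n_init, max_iter=max_iter, random_state=seed)
    return km.fit_predict(X)


def _check_points_labels(points, labels):
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    lab = np.asarray(labels)
    if len(lab) != len(X):
        raise ValueError("labels length mismatch")
    if len(np.unique(lab)) < 2:
        raise ValueError("need at least 2 clusters")
    return X, lab


def _within_scatter(X: np.ndarray, lab: np.ndarray) -> float:
    w = 0.0
    for c in np.unique(lab):
        pts = X[lab == c]
        w += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return w


def calinski_harabasz(points, labels) -> float:
    """Calinski-Harabasz index [B/(k-1)] / [W/(n-k)]; +inf when every
    cluster has zero within-cluster scatter."""
    X, lab = _check_points_labels(points, labels)
    if _within_scatter(X, lab) == 0.0:
        return float("inf")
    return float(calinski_harabasz_score(X, lab))


def silhouette(points, labels) -> float:
    """Mean silhouette (b-a)/max(a,b) over points; singleton-cluster
    points score 0."""
    X, lab = _check_points_labels(points, labels)
    return float(silhouette_score(X, lab))


def evaluate_gene_sets(
    matrix: CellMatrix,
    gene_sets: Mapping[str, Sequence[str]],
    k: int,
    n_repeats: int = 20,
    subsample_size: int = 500,
    seed: int = 0,
    n_init: int = 10,
    n_pcs: int | None = 20,
) -> pd.DataFrame:
    """Score gene sets by clustering quality over seeded subsamples.

    Per repeat, a random subsample of cells is drawn once (shared by all
    sets); per gene set, the subsample is restricted to the set's genes,
    depth-normalized (cell totals over *all* genes scaled to the median
    total), log1p-transformed and embedded into the top
    ``min(n_pcs, n_features)`` principal components, then clustered with
    k-means and scored with both indices in the embedding. The common
    embedding dimensionality keeps the indices comparable across gene
    sets of very different sizes (scores computed directly in spaces of
    wildly different dimension are dominated by dimension, not by signal).
    Returns a tidy DataFrame: gene_set, repeat, ch_index, silhouette.
    """
    if subsample_size > matrix.n_cells:
        raise ValueError(
            f"subsample_size {subsample_size} exceeds {matrix.n_cells} cells"
        )
    for name, genes in gene_sets.items():
        if not set(genes) & set(matrix.gene_symbols):
            raise ValueError(f"gene set {name!r} shares no genes with the matrix")
    rng = np.random.default_rng(seed)
    totals = matrix.total_counts_per_cell().astype(float)
    target = np.median(totals[totals > 0])
    rows = []
    for rep in range(n_repeats):
        idx = rng.choice(matrix.n_cells, size=subsample_size, replace=False)
        rep_seed = int(rng.integers(0, 2**31 - 1))
        for name, genes in gene_sets.items():
            present = [g for g in genes if g in set(matrix.gene_symbols)]
            cols = matrix.gene_index(present)
            sub = matrix.counts[idx][:, cols].toarray().astype(float)
            scale = np.where(totals[idx] > 0, target / np.where(totals[idx] > 0, totals[idx], 1), 0.0)
            X = np.log1p(sub * scale[:, None])
            if n_pcs is not None:
                d = min(n_pcs, X.shape[1], X.shape[0] - 1)
                X = PCA(n_components=d, svd_solver="full").fit_transform(X)
            labels = kmeans(X, k=k, seed=rep_seed, n_init=n_init)
            if len(np.unique(labels)) < 2:
                ch = sil = float("nan")
            else:
                ch = calinski_harabasz(X, labels)
                sil = silhouette(X, labels)
            rows.append(
                {"gene_set": name, "repeat": rep, "ch_index": ch, "silhouette": sil}
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ClassificationMetrics:
    """Confusion counts plus accuracy/recall/precision.

    A metric whose denominator is zero is reported as ``None`` (absent),
    never as NaN.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    recall: float | None
    precision: float | None


def classification_metrics(tp: int, tn: int, fp: int, fn: int) -> ClassificationMetrics:
    """Accuracy (TP+TN)/(TP+TN+FP+FN), recall TP/(TP+FN), precision
    TP/(TP+FP) from confusion counts."""
    counts = (tp, tn, fp, fn)
    if any(c < 0 for c in counts):
        raise ValueError("confusion counts must be non-negative")
    total = sum(counts)
    if total == 0:
        raise ValueError("confusion counts are all zero")
    accuracy = (tp + tn) / total
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    return ClassificationMetrics(tp, tn, fp, fn, accuracy, recall, precision)
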