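"""Synthetic multi-sample, multi-organ count corpora with planted truth.

The generator emulates the statistical structure the curation pipeline
exploits — zero-inflated negative-binomial counts, cell-type cluster
structure, sex-dependent chrY output, stable genes with near-zero dropout
and low cross-sample variation, organ-restricted genes — and plants a
roster of quality-control violations so that every pipeline stage can be
checked against exact ground truth.

Counts are drawn with a *bounded-spread detection* scheme: each cell
detects a uniformly sampled, fixed-size set of background genes (size
uniform in a ±5% band around ``n_background · (1 - dropout_rate)``), and
each detected gene gets a shifted negative-binomial count (1 + Poisson
mixed over a Gamma rate) whose mean carries a per-(cell type, gene)
multiplicative factor — the cluster signal lives in count magnitudes,
spread across the whole background rather than a narrow marker panel. Marginally, the mean per-gene zero-rate equals
the configured dropout rate, preserving the zero-inflation regime; the
bounded spread guarantees that no clean cell can ever breach the
mean + 3·SD detected-gene outlier cut, so the planted violation roster is
recovered exactly and the QC cascade is idempotent by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CellMatrix, GeneAnnotation

__all__ = ["SimConfig", "SyntheticTruth", "generate_corpus", "truth_confusion"]


@dataclass
class SimConfig:
    """Study conditions for the synthetic corpus.

    Defaults give the desk-scale default corpus: 20 regular samples of
    100 cells over 4 organs (plus one deliberately under-sized sample),
    1,000 genes of which 20 are planted stable genes and 10 per organ are
    planted organ-specific, 4 cell types, and a small roster of planted
    QC violations of every kind.
    """

    n_samples: int = 20
    organs: tuple[str, ...] = ("brain", "liver", "lung", "kidney")
    cells_per_sample: int = 100
    n_genes: int = 1000
    n_stable_genes: int = 20
    n_osg_per_organ: int = 10
    n_cell_types: int = 4
    sex_assignment: str | Mapping[str, str] = "alternate"
    nb_mean: float = 2.5
    nb_dispersion: float = 2.0
    dropout_rate: float = 0.65
    type_effect_sigma: float = 1.3
    # mitochondrial-fraction mixture: clean component + planted high tail
    mito_fraction_mean: float = 0.05
    mito_fraction_sd: float = 0.02
    mito_fraction_high: tuple[float, float] = (0.20, 0.35)
    n_high_mito_cells: int = 5
    n_outlier_cells: int = 5
    n_low_complexity_cells: int = 5
    n_coding_violation_cells: int = 3
    n_small_samples: int = 1
    small_sample_cells: int = 2
    seed: int = 0

    # fixed structural constants
    n_mito_genes: int = 5
    n_chry_genes: int = 10  # besides SRY
    n_chrx_genes: int = 30
    n_chrx_unique: int = 20

    def __post_init__(self) -> None:
        if not self.organs:
            raise ValueError("organs must be non-empty")
        if self.n_samples < len(self.organs):
            raise ValueError("need at least one sample per organ")
        n_special = (
            self.n_stable_genes
            + self.n_mito_genes
            + 1
            + self.n_chry_genes
            + self.n_chrx_genes
            + self.n_osg_per_organ * len(self.organs)
        )
        if self.n_genes - n_special < 60:
            raise ValueError(
                f"n_genes={self.n_genes} too small to host the planted gene sets "
                f"({n_special} special genes) plus a background of at least 60"
            )
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.n_coding_violation_cells > 0 and self.n_background // 3 < 40:
            raise ValueError("background too small to plant coding-biotype violations")

    @property
    def n_background(self) -> int:
        return self.n_genes - (
            self.n_stable_genes
            + self.n_mito_genes
            + 1
            + self.n_chry_genes
            + self.n_chrx_genes
            + self.n_osg_per_organ * len(self.organs)
        )


@dataclass
class SyntheticTruth:
    """Planted ground truth of a generated corpus."""

    sex_of_sample: dict[str, str]
    stable_gene_symbols: list[str]
    osg_map: dict[str, list[str]]
    cluster_of_cell: dict[str, str]
    qc_violations: dict[str, set[str]]
    hkg_reference: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        planted_osgs = {g for genes in self.osg_map.values() for g in genes}
        if planted_osgs & set(self.stable_gene_symbols):
            raise ValueError("stable genes and OSGs must be disjoint")


def _shifted_nb(rng: np.random.Generator, extra_mean: np.ndarray, shape: float) -> np.ndarray:
    """1 + Gamma-Poisson counts with the given extra mean per entry."""
    lam = rng.gamma(shape, np.maximum(extra_mean, 1e-9) / shape)
    return 1 + rng.poisson(lam)


def generate_corpus(
    config: SimConfig | None = None,
) -> tuple[CellMatrix, GeneAnnotation, pd.DataFrame, SyntheticTruth]:
    """Generate a corpus with planted ground truth.

    Returns (cells, annotation, sample_metadata, truth). The same seed
    reproduces the corpus bit-for-bit.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    organs = list(cfg.organs)
    species = "human"
    sry_symbol = "SRY"

    # ---------------- gene universe ----------------------------------
    stable = [f"STB{i:03d}" for i in range(cfg.n_stable_genes)]
    mito = [f"MT-{i + 1}" for i in range(cfg.n_mito_genes)]
    chry = [sry_symbol] + [f"GY{i:02d}" for i in range(cfg.n_chry_genes)]
    chrx = [f"GX{i:02d}" for i in range(cfg.n_chrx_genes)]
    osg: dict[str, list[str]] = {
        o: [f"OSG_{o}_{i:02d}" for i in range(cfg.n_osg_per_organ)] for o in organs
    }
    osg_flat = [g for o in organs for g in osg[o]]
    n_bg = cfg.n_background
    background = [f"G{i:04d}" for i in range(n_bg)]
    symbols = stable + mito + chry + chrx + osg_flat + background
    col = {g: j for j, g in enumerate(symbols)}

    # background split: an "other"-biotype pool plus coding genes
    n_other = max(8, n_bg // 3)
    other_pool = background[:n_other]
    coding_bg = background[n_other:]

    # annotation table
    chromo = (
        ["chr1"] * len(stable)
        + ["chrM"] * len(mito)
        + ["chrY"] * len(chry)
        + ["chrX"] * len(chrx)
        + ["chr2"] * len(osg_flat)
        + ["chr3"] * n_bg
    )
    n_mirna = min(50, len(coding_bg) // 10)
    biotype = {g: "protein_coding" for g in symbols}
    for g in other_pool:
        biotype[g] = "other"
    for g in coding_bg[-n_mirna:] if n_mirna else []:
        biotype[g] = "miRNA"
    annotation = GeneAnnotation(
        pd.DataFrame(
            {
                "chromosome": chromo,
                "biotype": [biotype[g] for g in symbols],
                "is_mitochondrial": [g in set(mito) for g in symbols],
                "exonic_length_bp": rng.integers(500, 5001, size=len(symbols)),
                "is_chrX_unique": [g in set(chrx[: cfg.n_chrx_unique]) for g in symbols],
            },
            index=pd.Index(symbols, name="symbol"),
        )
    )

    # ---------------- samples, sexes, organs --------------------------
    sample_ids = [f"S{i:02d}" for i in range(cfg.n_samples)]
    small_ids = [f"TINY{i}" for i in range(cfg.n_small_samples)]
    organ_of_sample = {s: organs[i % len(organs)] for i, s in enumerate(sample_ids)}
    organ_of_sample.update({s: organs[0] for s in small_ids})
    if isinstance(cfg.sex_assignment, Mapping):
        sex_of_sample = {s: cfg.sex_assignment[s] for s in sample_ids + small_ids}
    elif cfg.sex_assignment == "alternate":
        # alternate by organ round so every organ sees both sexes
        sex_of_sample = {
            s: ("male" if (i // len(organs)) % 2 == 0 else "female")
            for i, s in enumerate(sample_ids)
        }
        sex_of_sample.update({s: "female" for s in small_ids})
    elif cfg.sex_assignment in ("all_female", "all_male"):
        lab = cfg.sex_assignment.split("_")[1]
        sex_of_sample = {s: lab for s in sample_ids + small_ids}
    else:
        raise ValueError(f"unknown sex_assignment {cfg.sex_assignment!r}")

    # per-sample cell-type proportions (cluster structure varies by sample)
    type_props = {
        s: rng.dirichlet(np.full(cfg.n_cell_types, 5.0)) for s in sample_ids + small_ids
    }

    # ---------------- violator placement ------------------------------
    def _spread(n: int, start_sample: int) -> list[tuple[str, int]]:
        """(sample, within-sample slot) pairs, one violator per sample."""
        out = []
        for i in range(n):
            s = sample_ids[(start_sample + i) % len(sample_ids)]
            out.append((s, i // len(sample_ids)))
        return out

    placements = {
        "min_genes": _spread(cfg.n_low_complexity_cells, 0),
        "coding": _spread(cfg.n_coding_violation_cells, 5),
        "mito": _spread(cfg.n_high_mito_cells, 8),
        "outlier": _spread(cfg.n_outlier_cells, 13),
    }
    # slot index -> role, per sample
    role_of = {}
    for role, slots in placements.items():
        for s, slot_round in slots:
            taken = [k for k in role_of if k[0] == s]
            role_of[(s, len(taken))] = role

    # ---------------- draw cells --------------------------------------
    # Cluster signal is spread over the whole background: every background
    # gene carries a per-type multiplicative mean factor (lognormal with
    # unit mean), while detection weights stay uniform so per-gene
    # zero-rates are type- and organ-independent by construction.
    base_extra = cfg.nb_mean - 1.0
    bg_offset = len(symbols) - n_bg
    sigma = cfg.type_effect_sigma
    type_factor = rng.lognormal(
        mean=-sigma**2 / 2, sigma=sigma, size=(cfg.n_cell_types, n_bg)
    )
    # planted housekeeping-like background genes: type-uniform means (no
    # cluster signal) but ordinary dropout — what a bulk assay nominates
    # as stable yet single-cell zero-rates penalize
    n_half = cfg.n_stable_genes // 2
    hkg_bg = coding_bg[: min(n_half, len(coding_bg))]
    hkg_bg_local = np.array([col[g] - bg_offset for g in hkg_bg], dtype=int)
    type_factor[:, hkg_bg_local] = 1.0
    extra_mean_by_type = [base_extra * type_factor[t] for t in range(cfg.n_cell_types)]

    stable_idx = np.array([col[g] for g in stable])
    mito_idx = np.array([col[g] for g in mito])
    sry_idx = col[sry_symbol]
    chry_other_idx = np.array([col[g] for g in chry[1:]])
    chrx_idx = np.array([col[g] for g in chrx])
    osg_idx = {o: np.array([col[g] for g in osg[o]]) for o in organs}
    other_idx = np.array([col[g] for g in other_pool])
    coding_bg_idx = np.array([col[g] for g in coding_bg])

    lo = int(round(n_bg * (1 - cfg.dropout_rate) * 0.95))
    hi = int(round(n_bg * (1 - cfg.dropout_rate) * 1.05))
    lo = max(lo, 1)
    n_chrx_det = max(1, int(round(0.7 * cfg.n_chrx_genes)))
    n_chry_det = max(1, int(round(0.7 * cfg.n_chry_genes)))
    n_osg_det = max(1, int(round(0.6 * cfg.n_osg_per_organ)))
    shape = cfg.nb_dispersion

    rows_i: list[np.ndarray] = []
    rows_j: list[np.ndarray] = []
    rows_v: list[np.ndarray] = []
    cell_ids: list[str] = []
    cell_sample: list[str] = []
    cell_organ: list[str] = []
    cluster_of_cell: dict[str, str] = {}
    violations: dict[str, set[str]] = {
        "min_genes": set(),
        "min_cells_per_sample": set(),
        "coding": set(),
        "mito": set(),
        "outlier": set(),
    }

    def _mito_counts(nonmito_total: int, frac: float) -> np.ndarray:
        total = max(len(mito), int(round(frac / (1 - frac) * nonmito_total)))
        extra_counts = rng.multinomial(total - len(mito), np.full(len(mito), 1 / len(mito)))
        return 1 + extra_counts

    def _emit(cell_id: str, sample: str, organ: str, ctype: int, role: str | None) -> None:
        cols: list[np.ndarray] = []
        vals: list[np.ndarray] = []
        male = sex_of_sample[sample] == "male"

        if role == "coding":
            n_det_other = min(len(other_idx), max(cfg.n_genes // 4, 210))
            pick = rng.choice(other_idx, size=n_det_other, replace=False)
            cols.append(pick)
            vals.append(_shifted_nb(rng, np.full(n_det_other, base_extra), shape))
            pick_cod = rng.choice(coding_bg_idx, size=5, replace=False)
            cols.append(pick_cod)
            vals.append(_shifted_nb(rng, np.full(5, base_extra), shape))
        else:
            if role == "min_genes":
                n_det = min(lo, 100)
            elif role == "outlier":
                n_det = n_bg
            else:
                n_det = int(rng.integers(lo, hi + 1))
            if n_det == n_bg:
                picked = np.arange(n_bg)
            else:
                picked = rng.choice(n_bg, size=n_det, replace=False)
            extra = extra_mean_by_type[ctype][picked]
            cols.append(picked + bg_offset)
            vals.append(_shifted_nb(rng, extra, shape))

            cols.append(stable_idx)
            vals.append(1 + rng.poisson(19.0, size=len(stable_idx)))

            det_x = rng.choice(chrx_idx, size=n_chrx_det, replace=False)
            cols.append(det_x)
            vals.append(_shifted_nb(rng, np.full(n_chrx_det, 2.0), shape))

            if male:
                det_y = np.concatenate(
                    [
                        [sry_idx],
                        rng.choice(chry_other_idx, size=min(n_chry_det, len(chry_other_idx)), replace=False),
                    ]
                ).astype(int)
                cols.append(det_y)
                vals.append(_shifted_nb(rng, np.full(len(det_y), 2.0), shape))

            if role != "outlier":
                det_o = rng.choice(osg_idx[organ], size=n_osg_det, replace=False)
                cols.append(det_o)
                vals.append(_shifted_nb(rng, np.full(n_osg_det, 4.0), shape))

            nonmito_total = int(sum(v.sum() for v in vals))
            if role == "mito":
                frac = float(rng.uniform(*cfg.mito_fraction_high))
            else:
                frac = float(
                    np.clip(
                        rng.normal(cfg.mito_fraction_mean, cfg.mito_fraction_sd),
                        0.005,
                        0.12,
                    )
                )
            cols.append(mito_idx)
            vals.append(_mito_counts(nonmito_total, frac))

        j = np.concatenate(cols)
        v = np.concatenate(vals).astype(np.int64)
        rows_i.append(np.full(len(j), len(cell_ids)))
        rows_j.append(j)
        rows_v.append(v)
        cell_ids.append(cell_id)
        cell_sample.append(sample)
        cell_organ.append(organ)
        cluster_of_cell[cell_id] = f"T{ctype}"
        if role is not None:
            violations[role].add(cell_id)

    for s in sample_ids:
        organ = organ_of_sample[s]
        types = rng.choice(cfg.n_cell_types, size=cfg.cells_per_sample, p=type_props[s])
        slot = 0
        for c in range(cfg.cells_per_sample):
            role = role_of.get((s, slot)) if c < 10 else None
            if role is not None and c < 10:
                slot += 1
            _emit(f"{s}_c{c:03d}", s, organ, int(types[c]), role)
    for s in small_ids:
        organ = organ_of_sample[s]
        types = rng.choice(cfg.n_cell_types, size=cfg.small_sample_cells, p=type_props[s])
        for c in range(cfg.small_sample_cells):
            cell_id = f"{s}_c{c:03d}"
            _emit(cell_id, s, organ, int(types[c]), None)
            violations["min_cells_per_sample"].add(cell_id)

    counts = sp.coo_matrix(
        (
            np.concatenate(rows_v),
            (np.concatenate(rows_i), np.concatenate(rows_j)),
        ),
        shape=(len(cell_ids), len(symbols)),
    ).tocsr()

    cells = CellMatrix(
        counts=counts,
        cell_ids=np.array(cell_ids, dtype=object),
        gene_symbols=np.array(symbols, dtype=object),
        sample_of_cell=np.array(cell_sample, dtype=object),
        organ_of_cell=np.array(cell_organ, dtype=object),
        species=species,
    )

    all_samples = sample_ids + small_ids
    declared = []
    for i, s in enumerate(all_samples):
        declared.append(sex_of_sample[s] if i % 3 == 0 else "unknown")
    metadata = pd.DataFrame(
        {
            "sample_id": all_samples,
            "species": species,
            "organ": [organ_of_sample[s] for s in all_samples],
            "declared_sex": declared,
        }
    )

    # synthetic housekeeping reference: half planted stable genes, half
    # planted type-uniform background genes; mirrors the partial SEG/HKG
    # overlap seen against bulk-derived references
    hkg_reference = stable[:n_half] + sorted(hkg_bg)

    truth = SyntheticTruth(
        sex_of_sample=dict(sex_of_sample),
        stable_gene_symbols=list(stable),
        osg_map={o: list(v) for o, v in osg.items()},
        cluster_of_cell=cluster_of_cell,
        qc_violations=violations,
        hkg_reference=hkg_reference,
    )
    return cells, annotation, metadata, truth


def truth_confusion(
    predicted_labels: Mapping[str, str],
    truth_labels: Mapping[str, str],
    positive_label: str,
) -> tuple[int, int, int, int]:
    """Tally (TP, TN, FP, FN) of a prediction against planted truth.

    The two label universes (key sets) must match; ``positive_label``
    defines the positive class of the binary tally.
    """
    if set(predicted_labels) != set(truth_labels):
        raise ValueError("predicted and truth label universes differ")
    tp = tn = fp = fn = 0
    for k, truth_v in truth_labels.items():
        pred_pos = predicted_labels[k] == positive_label
        true_pos = truth_v == positive_label
        if pred_pos and true_pos:
            tp += 1
        elif pred_pos and not true_pos:
            fp += 1
        elif not pred_pos and true_pos:
            fn += 1
        else:
            tn += 1
    return tp, tn, fp, fn
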