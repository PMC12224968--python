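"""Expression-based sex inference from sex-chromosome ratios.

Two per-sample statistics on pseudo-bulk FPKM drive the call:

* Y-Ratio = FPKM(SRY) / Σ FPKM(chrY genes) — in males SRY contributes a
  characteristic share of chrY output; in females chrY output is absent.
* X-Ratio = Σ FPKM(chrX genes with no chrY homolog) / Σ FPKM(chrX genes) —
  the X–Y-homolog-free share of chrX output.

A rule-based classifier with species-calibrated thresholds maps the pair
to one of {male, female, mixed, unknown}; both ratios default to 0 when
their denominator is 0, so corpora without any chrY signal classify
female rather than erroring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .io import GeneAnnotation
from .pseudobulk import PseudoBulkMatrix

__all__ = [
    "SexThresholds",
    "HUMAN_THRESHOLDS",
    "MOUSE_THRESHOLDS",
    "SexClassifier",
    "compute_sex_ratios",
    "classify_sex",
    "correct_sample_sex",
]


@dataclass(frozen=True)
class SexThresholds:
    """Decision thresholds of the rule-based sex classifier.

    ``species`` selects the rule set; the remaining fields are the
    calibrated constants. For human: ``male_y`` is the Y-Ratio above which
    a sample is male regardless of X-Ratio, ``male_x``/``band_y`` bound the
    secondary male branch, ``female_x_min`` the minimum X-Ratio for a
    female call. For mouse: ``male_y``/``male_x`` play the same roles,
    ``female_x`` is the minimum X-Ratio of the in-band female branch and
    ``low_y`` the Y-Ratio floor under which any X signal means female.
    """

    species: str
    male_y: float
    male_x: float
    band_y: float = 0.0          # human only: lower Y-Ratio bound of the male x-branch
    female_x_min: float = 0.0    # human only: minimum X-Ratio for female
    female_x: float = 0.0        # mouse only: in-band female X-Ratio floor
    low_y: float = 0.0           # mouse only: Y-Ratio floor

    def __post_init__(self) -> None:
        if self.species == "human" and not self.male_y > self.band_y:
            raise ValueError("human thresholds require male_y > band_y")
        if self.species == "mouse" and not self.male_y > self.low_y:
            raise ValueError("mouse thresholds require male_y > low_y")


HUMAN_THRESHOLDS = SexThresholds(
    species="human", male_y=0.001188, male_x=0.000070, band_y=0.000106, female_x_min=0.000001
)
MOUSE_THRESHOLDS = SexThresholds(
    species="mouse", male_y=0.000065, male_x=0.000008, female_x=0.000555, low_y=0.000004
)

_PRESETS = {"human": HUMAN_THRESHOLDS, "mouse": MOUSE_THRESHOLDS}


def _classify_one(x: float, y: float, t: SexThresholds) -> str:
    """Apply the four-way rule set to one (X-Ratio, Y-Ratio) pair.

    Branch precedence: male first, then (human) mixed before female /
    (mouse) female before mixed, then unknown. "Between" bounds are open
    intervals; inclusive endpoints belong to the ≥/≤ branches that cite
    them.
    """
    if np.isnan(x) or np.isnan(y):
        warnings.warn("NaN ratio encountered; labeling unknown")
        return "unknown"
    if t.species == "human":
        if y >= t.male_y or (x <= t.male_x and y > t.band_y):
            return "male"
        if x > t.male_x and t.band_y < y < t.male_y:
            return "mixed"
        if x >= t.female_x_min and y <= t.band_y:
            return "female"
        return "unknown"
    if t.species == "mouse":
        if y >= t.male_y or (x <= t.male_x and t.low_y < y < t.male_y):
            return "male"
        if (x >= t.female_x and t.low_y < y < t.male_y) or (x > 0 and y <= t.low_y):
            return "female"
        if t.male_x < x < t.female_x and t.low_y < y < t.male_y:
            return "mixed"
        return "unknown"
    raise ValueError(f"no rule set for species {t.species!r}")


class SexClassifier(BaseEstimator, ClassifierMixin):
    """Rule-based sex classifier over (X-Ratio, Y-Ratio) pairs.

    Works un-fitted with the species' published threshold preset;
    ``fit(X, y)`` re-calibrates the primary thresholds by grid search
    maximizing accuracy on labeled samples (the refinement loop applied
    to sex-specific organs with trusted labels).

    Parameters
    ----------
    species
        "human" or "mouse" (selects rule set and preset thresholds).
    thresholds
        Optional explicit :class:`SexThresholds` overriding the preset.
    """

    def __init__(self, species: str = "human", thresholds: SexThresholds | None = None):
        self.species = species
        self.thresholds = thresholds

    def _resolved_thresholds(self) -> SexThresholds:
        if getattr(self, "thresholds_", None) is not None:
            return self.thresholds_
        if self.thresholds is not None:
            return self.thresholds
        if self.species not in _PRESETS:
            raise ValueError(f"no threshold preset for species {self.species!r}")
        return _PRESETS[self.species]

    def fit(self, X, y) -> "SexClassifier":
        """Grid-search ``male_y`` and (human) ``band_y`` / (mouse) ``low_y``
        over observed ratio quantiles, maximizing accuracy against ``y``."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_samples, 2): columns x_ratio, y_ratio")
        base = self.thresholds or _PRESETS.get(self.species)
        if base is None:
            raise ValueError(f"no threshold preset for species {self.species!r}")
        ys = X[:, 1]
        cand = np.unique(np.concatenate([[base.male_y], ys[ys > 0], [base.male_y / 2, base.male_y * 2]]))
        best, best_acc = base, -1.0
        for m in cand:
            secondary = (
                {"band_y": min(base.band_y, m * 0.9)}
                if self.species == "human"
                else {"low_y": min(base.low_y, m * 0.9)}
            )
            try:
                t = SexThresholds(
                    species=base.species,
                    male_y=float(m),
                    male_x=base.male_x,
                    female_x_min=base.female_x_min,
                    female_x=base.female_x,
                    **secondary,
                )
            except ValueError:
                continue
            pred = np.array([_classify_one(xi, yi, t) for xi, yi in X], dtype=object)
            acc = float(np.mean(pred == y))
            if acc > best_acc:
                best, best_acc = t, acc
        self.thresholds_ = best
        self.score_ = best_acc
        self.classes_ = np.array(["female", "male", "mixed", "unknown"], dtype=object)
        return self

    def predict(self, X) -> np.ndarray:
        """Label each (x_ratio, y_ratio) row male/female/mixed/unknown."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_samples, 2): columns x_ratio, y_ratio")
        t = self._resolved_thresholds()
        return np.array([_classify_one(xi, yi, t) for xi, yi in X], dtype=object)


def classify_sex(
    x_ratio: float, y_ratio: float, species: str = "human",
    thresholds: SexThresholds | None = None,
) -> str:
    """Classify a single sample from its (X-Ratio, Y-Ratio) pair."""
    t = thresholds or _PRESETS.get(species)
    if t is None:
        raise ValueError(f"no threshold preset for species {species!r}")
    return _classify_one(float(x_ratio), float(y_ratio), t)


def compute_sex_ratios(
    pb_fpkm: PseudoBulkMatrix,
    annotation: GeneAnnotation,
    sry_symbol: str = "SRY",
) -> pd.DataFrame:
    """Per-sample Y-Ratio and X-Ratio from a pseudo-bulk FPKM matrix.

    Returns a DataFrame indexed by sample with columns sry_expr,
    chry_expr, chrx_uniq_expr, chrx_expr, y_ratio, x_ratio. Zero
    denominators yield a 0 ratio.
    """
    if pb_fpkm.unit != "FPKM":
        raise ValueError("compute_sex_ratios expects an FPKM pseudo-bulk matrix")
    genes = list(pb_fpkm.gene_symbols)
    pos = {g: i for i, g in enumerate(genes)}
    if sry_symbol not in pos:
        raise ValueError(f"SRY gene {sry_symbol!r} absent from the matrix")
    chry = [g for g in annotation.chromosome_symbols("chrY") if g in pos]
    if not chry:
        raise ValueError("annotation provides no chrY genes present in the matrix")
    chrx = [g for g in annotation.chromosome_symbols("chrX") if g in pos]
    chrx_uniq = [g for g in annotation.chrx_unique_symbols() if g in pos]

    V = pb_fpkm.values
    sry = V[:, pos[sry_symbol]]
    chry_sum = V[:, [pos[g] for g in chry]].sum(axis=1)
    chrx_sum = V[:, [pos[g] for g in chrx]].sum(axis=1) if chrx else np.zeros(len(V))
    uniq_sum = V[:, [pos[g] for g in chrx_uniq]].sum(axis=1) if chrx_uniq else np.zeros(len(V))
    y_ratio = np.where(chry_sum > 0, sry / np.where(chry_sum > 0, chry_sum, 1), 0.0)
    x_ratio = np.where(chrx_sum > 0, uniq_sum / np.where(chrx_sum > 0, chrx_sum, 1), 0.0)
    return pd.DataFrame(
        {
            "sry_expr": sry,
            "chry_expr": chry_sum,
            "chrx_uniq_expr": uniq_sum,
            "chrx_expr": chrx_sum,
            "y_ratio": y_ratio,
            "x_ratio": x_ratio,
        },
        index=pd.Index(pb_fpkm.group_ids, name="sample_id"),
    )


def correct_sample_sex(
    sample_metadata: pd.DataFrame, calls: pd.Series | dict
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replace declared sex labels by classifier calls.

    Returns the corrected metadata plus a correction table with one row
    per sample (sample_id, original, corrected, matched) supporting
    Sankey-style transition tallies; the transition tally sums to the
    number of samples.
    """
    calls = pd.Series(calls)
    meta = sample_metadata.copy()
    missing = [s for s in meta["sample_id"] if s not in calls.index]
    if missing:
        raise ValueError(f"no sex call for samples: {missing[:5]}")
    original = meta["declared_sex"].to_numpy(dtype=object)
    corrected = np.array([calls[s] for s in meta["sample_id"]], dtype=object)
    meta["declared_sex"] = corrected
    table = pd.DataFrame(
        {
            "sample_id": meta["sample_id"].to_numpy(),
            "original": original,
            "corrected": corrected,
            "matched": original == corrected,
        }
    )
    return meta, table
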