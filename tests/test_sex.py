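"""Sex-ratio computation and the rule-based classifier."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sccurate.io import GeneAnnotation
from sccurate.pseudobulk import PseudoBulkMatrix
from sccurate.sex import (
    HUMAN_THRESHOLDS,
    MOUSE_THRESHOLDS,
    SexClassifier,
    classify_sex,
    compute_sex_ratios,
    correct_sample_sex,
)

LABELS = {"male", "female", "mixed", "unknown"}


def _annotation():
    symbols = ["SRY", "Y1", "Y2", "XU1", "XU2", "XO1", "auto"]
    return GeneAnnotation(
        pd.DataFrame(
            {
                "chromosome": ["chrY", "chrY", "chrY", "chrX", "chrX", "chrX", "chr1"],
                "biotype": "protein_coding",
                "is_mitochondrial": False,
                "exonic_length_bp": 1000,
                "is_chrX_unique": [False, False, False, True, True, False, False],
            },
            index=pd.Index(symbols, name="symbol"),
        )
    )


class TestComputeRatios:
    def _pb(self, values):
        genes = ["SRY", "Y1", "Y2", "XU1", "XU2", "XO1", "auto"]
        return PseudoBulkMatrix(np.array([values], dtype=float), ["s"], genes, "FPKM")

    def test_y_ratio_is_sry_share_of_chry(self):
        # SRY 5 of chrY total 50
        r = compute_sex_ratios(self._pb([5, 40, 5, 0, 0, 0, 1]), _annotation())
        assert r.loc["s", "y_ratio"] == pytest.approx(0.1)

    def test_x_ratio_is_unique_share_of_chrx(self):
        # unique 30 of chrX total 40
        r = compute_sex_ratios(self._pb([0, 0, 0, 20, 10, 10, 1]), _annotation())
        assert r.loc["s", "x_ratio"] == pytest.approx(0.75)

    def test_zero_chry_gives_zero_y_ratio(self):
        r = compute_sex_ratios(self._pb([0, 0, 0, 5, 5, 5, 1]), _annotation())
        assert r.loc["s", "y_ratio"] == 0.0

    def test_missing_sry_errors(self):
        pb = PseudoBulkMatrix(np.ones((1, 2)), ["s"], ["Y1", "auto"], "FPKM")
        with pytest.raises(ValueError, match="SRY"):
            compute_sex_ratios(pb, _annotation())


class TestClassifier:
    @pytest.mark.parametrize(
        "species,x,y,expected",
        [
            ("human", 0.5, 0.002, "male"),          # high Y-Ratio branch
            ("human", 0.3, 0.00005, "female"),      # low-Y, X present
            ("human", 0.3, 0.0005, "mixed"),        # mid-band, high X
            ("human", 0.0000005, 0.00005, "unknown"),
            ("human", 0.000070, 0.0005, "male"),    # low-X male sub-branch
            ("mouse", 0.1, 0.000002, "female"),     # X>0 with Y below floor
            ("mouse", 0.5, 0.000065, "male"),
            ("mouse", 0.0006, 0.00003, "female"),
            ("mouse", 0.0001, 0.00003, "mixed"),
            ("mouse", 0.0, 0.0, "unknown"),
        ],
    )
    def test_published_rule_branches(self, species, x, y, expected):
        assert classify_sex(x, y, species) == expected

    @given(
        x=st.floats(min_value=0, max_value=1, allow_nan=False),
        y=st.floats(min_value=0, max_value=1, allow_nan=False),
        species=st.sampled_from(["human", "mouse"]),
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_partition_property(self, x, y, species):
        """Every (x, y) pair maps to exactly one of the four labels."""
        assert classify_sex(x, y, species) in LABELS

    def test_threshold_boundaries_are_single_labeled(self):
        # probing exactly on every published constant still yields a label
        for t in (HUMAN_THRESHOLDS, MOUSE_THRESHOLDS):
            consts = [t.male_y, t.male_x, t.band_y, t.female_x_min, t.female_x, t.low_y]
            for x in consts:
                for y in consts:
                    assert classify_sex(x, y, t.species) in LABELS

    def test_monotone_in_y_for_fixed_x_human(self):
        """Increasing Y-Ratio never moves a human call from male to female."""
        for x in [0.0, 1e-6, 5e-5, 7e-5, 1e-4, 0.3, 1.0]:
            order = {"female": 0, "unknown": 1, "mixed": 1, "male": 2}
            seen_male = False
            for y in np.linspace(0, 0.002, 400):
                lab = classify_sex(x, float(y), "human")
                if seen_male:
                    assert lab != "female"
                if lab == "male":
                    seen_male = True

    def test_estimator_predict_matches_function(self):
        X = np.array([[0.5, 0.002], [0.3, 0.00005], [0.3, 0.0005]])
        clf = SexClassifier("human")
        assert list(clf.predict(X)) == ["male", "female", "mixed"]

    def test_fit_calibrates_on_shifted_boundary(self):
        """Grid-search recovers a usable male threshold when the planted
        boundary differs from the preset."""
        rng = np.random.default_rng(0)
        n = 60
        y_male = rng.uniform(0.01, 0.1, n)
        y_female = np.zeros(n)
        X = np.vstack([
            np.column_stack([np.full(n, 0.7), y_male]),
            np.column_stack([np.full(n, 0.7), y_female]),
        ])
        labels = np.array(["male"] * n + ["female"] * n, dtype=object)
        clf = SexClassifier("human").fit(X, labels)
        assert clf.score_ == 1.0
        assert (clf.predict(X) == labels).all()

    def test_nan_ratio_labels_unknown_with_warning(self):
        with pytest.warns(UserWarning, match="NaN"):
            assert classify_sex(float("nan"), 0.1, "human") == "unknown"


class TestCorrection:
    def test_unknown_resolved_and_tally_conserved(self):
        meta = pd.DataFrame(
            {
                "sample_id": ["a", "b", "c"],
                "species": "human",
                "organ": "testis",
                "declared_sex": ["unknown", "female", "male"],
            }
        )
        calls = pd.Series({"a": "male", "b": "female", "c": "female"})
        corrected, table = correct_sample_sex(meta, calls)
        assert list(corrected["declared_sex"]) == ["male", "female", "female"]
        assert len(table) == 3  # transition tally sums to sample count
        row = table.set_index("sample_id")
        assert row.loc["a", "original"] == "unknown" and row.loc["a", "corrected"] == "male"
        assert bool(row.loc["b", "matched"]) is True
        assert bool(row.loc["c", "matched"]) is False
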