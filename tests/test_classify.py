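"""Frequency normalization, growth rates and the phenotype sign/sharing rule."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonetrace.classify import (
    DE_NOVO,
    PRE_EXISTING,
    SENSITIVE,
    classify_barcodes,
    compute_frequencies,
    growth_rate,
    growth_rate_table,
    phenotype_frequency_summary,
    unique_phenotype_counts,
)
from clonetrace.extract import filter_low_counts
from conftest import make_count_matrix

ARMS = {
    "dmso": "dmso",
    "replicate-A": "replicate-A",
    "replicate-B": "replicate-B",
    "replicate-C": "replicate-C",
}


def brute_force_labels(r_matrix: pd.DataFrame) -> pd.DataFrame:
    """Literal re-statement of the classification rule, row by row."""
    rows = []
    for barcode, row in r_matrix.iterrows():
        positives = [rep for rep in r_matrix.columns if not math.isnan(row[rep]) and row[rep] > 0]
        for rep in r_matrix.columns:
            r = row[rep]
            if math.isnan(r):
                continue
            if r > 0 and len(positives) >= 2:
                label = PRE_EXISTING
            elif r > 0:
                label = DE_NOVO
            else:
                label = SENSITIVE
            rows.append((barcode, rep, r, label))
    return pd.DataFrame(rows, columns=["barcode_id", "replicate", "r", "label"])


class TestFrequencies:
    def test_single_barcode_sample(self):
        cm = make_count_matrix({"dmso": [7]}, {"dmso": "dmso"})
        assert compute_frequencies(cm)["dmso"].iloc[0] == 1.0

    def test_three_one_split(self):
        cm = make_count_matrix({"dmso": [3, 1]}, {"dmso": "dmso"})
        np.testing.assert_allclose(compute_frequencies(cm)["dmso"], [0.75, 0.25])

    def test_columns_sum_to_one(self, rng):
        counts = {f"s{i}": rng.integers(1, 50, 200).tolist() for i in range(5)}
        cm = make_count_matrix(counts, {f"s{i}": "replicate-A" for i in range(5)})
        sums = compute_frequencies(cm).sum(axis=0)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_zero_column_names_sample(self):
        cm = make_count_matrix({"good": [1], "bad": [0]}, {"good": "dmso", "bad": "dmso"})
        with pytest.raises(ValueError, match="bad"):
            compute_frequencies(cm)


class TestGrowthRate:
    def test_equal_frequencies_give_zero(self):
        assert growth_rate(0.05, 0.05, 26.0) == 0.0

    def test_tenfold_expansion_over_26_weeks(self):
        r = growth_rate(0.1, 0.01, 26.0)
        assert r == pytest.approx(math.log(10) / 26, rel=1e-12)
        assert r == pytest.approx(0.08856, abs=5e-6)

    def test_antisymmetry(self):
        assert growth_rate(0.01, 0.1, 26.0) == pytest.approx(-math.log(10) / 26)

    def test_vanished_barcode_is_minus_infinity(self):
        assert growth_rate(0.0, 0.1, 26.0) == -math.inf

    @pytest.mark.parametrize("bad", [dict(f_0=0.0), dict(T=0.0), dict(f_R=-0.1)])
    def test_invalid_inputs(self, bad):
        kwargs = dict(f_R=0.1, f_0=0.1, T=26.0) | bad
        with pytest.raises(ValueError):
            growth_rate(**kwargs)

    @given(
        f1=st.floats(1e-6, 1.0),
        f2=st.floats(1e-6, 1.0),
        f0=st.floats(1e-6, 1.0),
        T=st.floats(1.0, 100.0),
    )
    @settings(derandomize=True, max_examples=200, deadline=None)
    def test_strictly_increasing_in_f_R_and_base_invariant_sign(self, f1, f2, f0, T):
        r1, r2 = growth_rate(f1, f0, T), growth_rate(f2, f0, T)
        if f1 < f2:
            assert r1 < r2
        r10 = growth_rate(f1, f0, T, log_base="10")
        assert np.sign(r10) == np.sign(r1)


class TestClassifyBarcodes:
    def _gr(self, rows):
        return pd.DataFrame(rows, columns=["A", "B", "C"], index=range(1, len(rows) + 1))

    def test_two_positive_one_negative(self):
        calls = classify_barcodes(self._gr([[0.1, 0.2, -0.1]]))
        by_rep = calls.set_index("replicate")["label"]
        assert by_rep["A"] == by_rep["B"] == PRE_EXISTING
        assert by_rep["C"] == SENSITIVE

    def test_single_positive_is_de_novo(self):
        calls = classify_barcodes(self._gr([[0.1, -0.2, -0.1]]))
        by_rep = calls.set_index("replicate")["label"]
        assert by_rep["A"] == DE_NOVO
        assert by_rep["B"] == by_rep["C"] == SENSITIVE

    def test_exact_zero_rate_is_sensitive(self):
        calls = classify_barcodes(self._gr([[0.0, 0.1, 0.2]]))
        assert calls.set_index("replicate")["label"]["A"] == SENSITIVE

    def test_matches_brute_force_on_random_matrices(self, rng):
        r = rng.normal(0, 0.1, size=(2000, 3))
        r[rng.random(r.shape) < 0.3] = np.nan  # undetected cells
        gr = pd.DataFrame(r, columns=["A", "B", "C"], index=range(1, 2001))
        got = classify_barcodes(gr).sort_values(["barcode_id", "replicate"]).reset_index(drop=True)
        want = brute_force_labels(gr).sort_values(["barcode_id", "replicate"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(got, want)

    def test_invariant_to_uniform_count_scaling(self):
        cm = make_count_matrix(
            {
                "dmso": [50, 30, 20],
                "replicate-A": [90, 5, 5],
                "replicate-B": [80, 15, 5],
                "replicate-C": [10, 40, 50],
            },
            ARMS,
        )
        scaled = make_count_matrix(
            {s: (cm.counts[s] * (7 if s == "replicate-A" else 3)).tolist() for s in cm.samples},
            ARMS,
        )
        a = classify_barcodes(growth_rate_table(cm))
        b = classify_barcodes(growth_rate_table(scaled))
        pd.testing.assert_series_equal(a["label"], b["label"])

    def test_log_base_never_flips_labels(self):
        cm = make_count_matrix(
            {
                "dmso": [50, 30, 20],
                "replicate-A": [90, 5, 5],
                "replicate-B": [80, 15, 5],
                "replicate-C": [10, 40, 50],
            },
            ARMS,
        )
        e = classify_barcodes(growth_rate_table(cm, log_base="e"))
        ten = classify_barcodes(growth_rate_table(cm, log_base="10"))
        pd.testing.assert_series_equal(e["label"], ten["label"])


class TestGrowthRateTable:
    def test_detection_requires_min_count(self):
        cm = make_count_matrix(
            {"dmso": [10, 10], "replicate-A": [1, 5], "replicate-B": [5, 5]},
            {"dmso": "dmso", "replicate-A": "replicate-A", "replicate-B": "replicate-B"},
        )
        gr = growth_rate_table(cm, min_count=2)
        assert math.isnan(gr.loc[1, "replicate-A"])
        assert not math.isnan(gr.loc[2, "replicate-A"])

    def test_absent_from_dmso_uses_pseudo_frequency(self):
        cm = make_count_matrix(
            {"dmso": [0, 100], "replicate-A": [50, 50], "replicate-B": [50, 50]},
            {"dmso": "dmso", "replicate-A": "replicate-A", "replicate-B": "replicate-B"},
        )
        gr = growth_rate_table(cm, T=26.0)
        # barcode 1 invisible in DMSO: baseline is half a read out of 100
        expected = math.log(0.5 / (0.5 / 100)) / 26.0
        assert gr.loc[1, "replicate-A"] == pytest.approx(expected)

    def test_max_dmso_mode_uses_common_baseline(self):
        cm = make_count_matrix(
            {"dmso": [60, 40], "replicate-A": [50, 50], "replicate-B": [50, 50]},
            {"dmso": "dmso", "replicate-A": "replicate-A", "replicate-B": "replicate-B"},
        )
        gr = growth_rate_table(cm, T=26.0, f0_mode="max_dmso")
        for b in (1, 2):
            assert gr.loc[b, "replicate-A"] == pytest.approx(math.log(0.5 / 0.6) / 26.0)


class TestSummaries:
    @pytest.fixture
    def calls_and_freqs(self):
        cm = make_count_matrix(
            {
                "dmso": [10, 10, 10],
                "replicate-A": [60, 40, 0],
                "replicate-B": [50, 10, 40],
            },
            {"dmso": "dmso", "replicate-A": "replicate-A", "replicate-B": "replicate-B"},
        )
        calls = pd.DataFrame(
            {
                "barcode_id": [1, 2, 1, 3],
                "replicate": ["replicate-A", "replicate-A", "replicate-B", "replicate-B"],
                "r": [0.1, 0.1, 0.1, -0.1],
                "label": [PRE_EXISTING, DE_NOVO, PRE_EXISTING, SENSITIVE],
            }
        )
        return compute_frequencies(cm), calls

    def test_two_barcode_split(self, calls_and_freqs):
        freqs, calls = calls_and_freqs
        pct = phenotype_frequency_summary(freqs, calls, "replicate-A")
        assert pct[PRE_EXISTING] == pytest.approx(60.0)
        assert pct[DE_NOVO] == pytest.approx(40.0)
        assert pct[SENSITIVE] == 0.0
        assert sum(pct.values()) == pytest.approx(100.0, abs=1e-6)

    def test_all_sensitive_is_0_0_100(self):
        cm = make_count_matrix(
            {"dmso": [10], "replicate-A": [10], "replicate-B": [10]},
            {"dmso": "dmso", "replicate-A": "replicate-A", "replicate-B": "replicate-B"},
        )
        calls = pd.DataFrame(
            {"barcode_id": [1], "replicate": ["replicate-A"], "r": [-0.1], "label": [SENSITIVE]}
        )
        pct = phenotype_frequency_summary(compute_frequencies(cm), calls, "replicate-A")
        assert (pct[PRE_EXISTING], pct[DE_NOVO], pct[SENSITIVE]) == (0.0, 0.0, 100.0)

    def test_unique_counts(self, calls_and_freqs):
        _, calls = calls_and_freqs
        counts = unique_phenotype_counts(calls)
        assert counts.loc["replicate-A", "n_pre_existing"] == 1
        assert counts.loc["replicate-A", "n_de_novo"] == 1
        assert counts.loc["replicate-B", "n_sensitive"] == 1
        assert counts.loc["replicate-B", "n_total_detected"] == 2

    def test_empty_calls_give_empty_table(self):
        counts = unique_phenotype_counts(pd.DataFrame(columns=["barcode_id", "replicate", "r", "label"]))
        assert counts.empty
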