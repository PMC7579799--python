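"""Effect sizes, paired t, agreement ICC, cancellation and corrected tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from difagree import (
    CrossInformantAgreement,
    ResponseMatrix,
    cancellation_partition,
    cohen_effect_size,
    corrected_agreement_table,
    effect_size_label,
    icc_agreement,
    icc_label,
    paired_t,
)
from difagree.simulate import make_subscale_instrument


class TestEffectSize:
    @pytest.mark.parametrize("m1,s1,m2,s2,expected", [
        # published parent/child total- and subscale-score summaries
        (76.67, 13.90, 78.58, 13.52, 0.14),
        (78.11, 13.41, 81.20, 11.86, 0.24),
        (79.37, 17.39, 82.17, 14.43, 0.18),
        (69.05, 19.02, 67.83, 21.66, 0.06),
        (73.30, 18.87, 68.04, 21.31, 0.26),
    ])
    def test_pooled_sd_worked_examples(self, m1, s1, m2, s2, expected):
        assert round(cohen_effect_size(m1, s1, m2, s2), 2) == expected

    def test_equal_means_give_zero(self):
        assert cohen_effect_size(50.0, 10.0, 50.0, 12.0) == 0.0

    @settings(max_examples=50, deadline=None)
    @given(m1=st.floats(0, 100), m2=st.floats(0, 100),
           s1=st.floats(0.1, 30), s2=st.floats(0.1, 30))
    def test_symmetry(self, m1, m2, s1, s2):
        assert cohen_effect_size(m1, s1, m2, s2) == pytest.approx(
            cohen_effect_size(m2, s2, m1, s1))

    @pytest.mark.parametrize("es,label", [
        (0.0, "negligible"), (0.19, "negligible"), (0.2, "small"),
        (0.49, "small"), (0.5, "medium"), (0.79, "medium"),
        (0.8, "large"), (2.0, "large"), (-0.3, "small")])
    def test_labels_total_with_boundaries(self, es, label):
        assert effect_size_label(es) == label


class TestPairedT:
    def test_identical_vectors_convention(self):
        t, p, md = paired_t([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert md == 0.0 and p == 1.0

    def test_constant_nonzero_difference(self):
        t, p, md = paired_t([2.0, 3, 4, 5], [1.0, 2, 3, 4])
        assert md == 1.0 and p == 0.0 and np.isinf(t)

    def test_matches_textbook_formula(self):
        """10 fixed pairs vs the hand-rolled t = d_bar/(s_d/sqrt(n))."""
        rng = np.random.default_rng(8)
        x = rng.normal(70, 10, 10)
        y = x + rng.normal(1.5, 3, 10)
        d = x - y
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(10))
        from scipy.stats import t as tdist

        p_oracle = 2 * tdist.sf(abs(t_oracle), df=9)
        t, p, md = paired_t(x, y)
        assert t == pytest.approx(t_oracle, abs=1e-10)
        assert p == pytest.approx(p_oracle, abs=1e-10)
        assert md == pytest.approx(d.mean())


class TestICC:
    def test_perfect_agreement(self):
        x = np.array([10.0, 20, 30, 40, 55])
        assert icc_agreement(x, x) == pytest.approx(1.0)

    def test_independent_scores_near_zero(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=3000)
        y = rng.normal(size=3000)
        assert abs(icc_agreement(x, y)) < 0.05

    def test_matches_anova_mean_squares_oracle(self):
        """Six fixed pairs vs a hand computation from the two-way ANOVA
        mean squares, to 4 decimals."""
        x = np.array([70.0, 75, 82, 60, 90, 68])
        y = np.array([72.0, 70, 85, 66, 88, 61])
        n, k = 6, 2
        data = np.column_stack([x, y])
        grand = data.mean()
        msr = k * np.sum((data.mean(axis=1) - grand) ** 2) / (n - 1)
        msc = n * np.sum((data.mean(axis=0) - grand) ** 2) / (k - 1)
        mse = (np.sum((data - grand) ** 2)
               - (n - 1) * msr - (k - 1) * msc) / ((n - 1) * (k - 1))
        oracle = (msr - mse) / (msr + mse + (2 / n) * (msc - mse))
        assert icc_agreement(x, y) == pytest.approx(oracle, abs=1e-4)

    def test_matches_pingouin_icc2(self):
        """Cross-check the absolute-agreement single-rater form (ICC2)
        against an independent implementation."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        x = rng.normal(75, 12, 40)
        y = 0.7 * x + rng.normal(20, 8, 40)
        df = pd.DataFrame({
            "target": np.r_[np.arange(40), np.arange(40)],
            "rater": ["a"] * 40 + ["b"] * 40,
            "score": np.r_[x, y],
        })
        ref = pingouin.intraclass_corr(df, targets="target", raters="rater",
                                       ratings="score")
        icc2 = ref.loc[ref["Type"].isin(["ICC2", "ICC(A,1)"]), "ICC"].iloc[0]
        assert icc_agreement(x, y) == pytest.approx(icc2, abs=1e-6)

    def test_systematic_shift_lowers_agreement_not_consistency(self):
        rng = np.random.default_rng(5)
        x = rng.normal(70, 10, 200)
        y = x + 8.0          # constant offset
        assert icc_agreement(x, y, variant="consistency") == pytest.approx(1.0)
        assert icc_agreement(x, y) < 0.9

    @pytest.mark.parametrize("icc,label", [
        (0.2, "poor"), (0.40, "poor"), (0.41, "moderate"), (0.60, "moderate"),
        (0.61, "good"), (0.80, "good"), (0.81, "excellent"), (0.95, "excellent")])
    def test_icc_labels(self, icc, label):
        assert icc_label(icc) == label


class TestCancellation:
    def test_opposite_pair_cancels(self):
        flags = {"a": ("uniform", 0.8), "b": ("uniform", -0.6)}
        pairs, uncancelled = cancellation_partition(flags)
        assert pairs == [("a", "b")]
        assert uncancelled == []

    def test_lone_uniform_item_uncancelled(self):
        flags = {"a": ("uniform", 0.8), "b": ("none", 0.0)}
        pairs, uncancelled = cancellation_partition(flags)
        assert pairs == [] and uncancelled == ["a"]

    def test_nonuniform_items_never_removed(self):
        flags = {"a": ("nonuniform", 0.9), "b": ("uniform", -0.6)}
        pairs, uncancelled = cancellation_partition(flags)
        assert uncancelled == ["b"]
        assert all("a" not in p for p in pairs)

    def test_largest_magnitude_paired_first(self):
        flags = {"a": ("uniform", 0.9), "b": ("uniform", 0.2),
                 "c": ("uniform", -0.5)}
        pairs, uncancelled = cancellation_partition(flags)
        assert pairs == [("a", "c")]
        assert uncancelled == ["b"]     # weakest excess item left over

    def test_no_uniform_items_no_op(self):
        pairs, uncancelled = cancellation_partition({"a": ("none", 0.0)})
        assert pairs == [] and uncancelled == []


def _dyadic_matrix(n=40, seed=0):
    spec = make_subscale_instrument(5)
    rng = np.random.default_rng(seed)
    rows = []
    for d in range(n):
        for g in ("child", "parent"):
            rec = {"respondent_id": f"{g}{d}", "dyad_id": f"d{d}", "group": g}
            rec.update({f"item_{j + 1}": int(v) for j, v in
                        enumerate(rng.integers(0, 5, 5))})
            rows.append(rec)
    return ResponseMatrix(pd.DataFrame(rows), spec)


class TestCorrectedTable:
    def test_no_flags_corrected_equals_raw(self):
        m = _dyadic_matrix()
        flags = {"scale": {f"item_{j}": ("none", 0.0) for j in range(1, 6)}}
        tab = corrected_agreement_table(m, ("child", "parent"), flags)
        raw = tab[~tab["corrected"]].reset_index(drop=True)
        cor = tab[tab["corrected"]].reset_index(drop=True)
        for col in ("mean_1", "sd_1", "mean_2", "sd_2", "effect_size", "icc"):
            np.testing.assert_allclose(raw[col], cor[col])

    def test_all_items_removed_row_undefined(self):
        m = _dyadic_matrix()
        flags = {"scale": {f"item_{j}": ("uniform", 0.5) for j in range(1, 6)}}
        tab = corrected_agreement_table(m, ("child", "parent"), flags)
        cor = tab[tab["corrected"] & (tab["scale"] == "scale")].iloc[0]
        assert not cor["defined"]
        assert np.isnan(cor["effect_size"])

    def test_model_results_interface(self):
        m = _dyadic_matrix()
        res = CrossInformantAgreement(m, ("child", "parent")).fit()
        assert set(res.table["scale"]) == {"scale", "total"}
        assert "Cross-informant agreement" in res.summary()
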