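"""Unit and property tests for the score formulas and categorical transforms.

Expected values marked as frozen were computed with the independent
hand-arithmetic oracles defined at the top of this file (plain scalar
math, no shared code with the implementation).
"""

import math

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

from ihc4pipe.scores import (
    ClinicalFactors,
    CoreMeasurement,
    MarkerPanel,
    ScoreOptions,
    Subtype,
    aggregate_cores,
    assign_quartiles,
    c_score,
    classify_subtype,
    classify_subtypes,
    compute_c_score,
    compute_ihc4,
    compute_predict_score,
    dichotomize_mean_plus_sd,
    ihc4_score,
    predict_score,
    standardize_per_sd,
)

# ---------------------------------------------------------------------------
# independent arithmetic oracles (scalar, no numpy)
# ---------------------------------------------------------------------------


def oracle_ihc4(er, pr, her2, ki67):
    return 94.7 * (
        -0.100 * (er / 10.0)
        - 0.079 * (pr / 10.0)
        + 0.586 * her2
        + 0.240 * math.log(1.0 + 10.0 * ki67)
    )


def oracle_c(nodes, size_mm, grade, age):
    n13 = 1.0 if 1 <= nodes <= 3 else 0.0
    n4 = 1.0 if nodes >= 4 else 0.0
    t12 = 1.0 if 10 < size_mm <= 20 else 0.0
    t23 = 1.0 if 20 < size_mm <= 30 else 0.0
    t3 = 1.0 if size_mm > 30 else 0.0
    return 100.0 * (
        0.417 * n13
        + 1.566 * n4
        + 0.930 * 0.497 * t12
        + 0.882 * t23
        + 1.838 * t3
        + 0.559 * (grade == 2)
        + 0.970 * (grade == 3)
        + 0.130 * (age >= 65)
    )


def oracle_predict(age, size_mm, nodes, grade):
    a = age / 10.0
    return (
        (34.53 * a ** -2 - 0.0287)
        + (-34.20 * a ** -2 * math.log(a) - 0.0510)
        + (0.7531 * math.log(size_mm / 100.0) + 1.5452)
        + (0.7069 * math.log((nodes + 1) / 10.0) + 1.3876)
        + 0.7467 * grade
    )


# ---------------------------------------------------------------------------
# core aggregation
# ---------------------------------------------------------------------------


class TestAggregateCores:
    def test_single_core_is_identity(self):
        panel = aggregate_cores(
            [CoreMeasurement("c1", er_pct=80, pr_pct=60, ki67_pct=10, her2_herceptest=1)]
        )
        assert panel == MarkerPanel(er_pct=80, pr_pct=60, ki67_pct=10, her2_herceptest=1)

    def test_two_core_mean(self):
        panel = aggregate_cores(
            [CoreMeasurement("a", er_pct=60), CoreMeasurement("b", er_pct=80)]
        )
        assert panel.er_pct == pytest.approx(70)

    def test_three_core_means_including_her2(self):
        cores = [
            CoreMeasurement("a", ki67_pct=0, her2_herceptest=0),
            CoreMeasurement("b", ki67_pct=9, her2_herceptest=3),
            CoreMeasurement("c", ki67_pct=27, her2_herceptest=3),
        ]
        panel = aggregate_cores(cores)
        assert panel.ki67_pct == pytest.approx(12)
        assert panel.her2_herceptest == pytest.approx(2.0)

    def test_missing_marker_stays_missing(self):
        panel = aggregate_cores([CoreMeasurement("a", er_pct=50)])
        assert panel.pr_pct is None

    def test_empty_list_errors(self):
        with pytest.raises(ValueError, match="empty"):
            aggregate_cores([])

    def test_core_validation(self):
        with pytest.raises(ValueError, match="er_pct"):
            CoreMeasurement("a", er_pct=150)
        with pytest.raises(ValueError, match="no marker"):
            CoreMeasurement("a")


# ---------------------------------------------------------------------------
# IHC4
# ---------------------------------------------------------------------------


class TestIHC4:
    def test_zero_case(self):
        assert ihc4_score(0, 0, 0, 0) == 0.0

    def test_printed_coefficients_at_full_receptors(self):
        assert ihc4_score(100, 100, 0, 0) == pytest.approx(-169.513, abs=1e-9)

    def test_cohort_medians(self):
        # frozen from oracle_ihc4(62, 57, 0, 9) = 1.1654048641...
        assert ihc4_score(62, 57, 0, 9) == pytest.approx(1.1654048641149466, abs=1e-9)
        assert ihc4_score(62, 57, 0, 9) == pytest.approx(oracle_ihc4(62, 57, 0, 9))

    def test_ki67_fraction_unit(self):
        assert ihc4_score(0, 0, 0, 50, ki67_unit="fraction") == pytest.approx(
            94.7 * 0.240 * math.log(6.0)
        )

    def test_missing_component_named(self):
        with pytest.raises(ValueError, match="pr_pct"):
            ihc4_score(50, float("nan"), 0, 5)
        with pytest.raises(ValueError, match="ki67"):
            ihc4_score(50, 50, 0, -1)

    def test_panel_wrapper_her2_codings(self):
        panel = MarkerPanel(er_pct=50, pr_pct=50, ki67_pct=5,
                            her2_herceptest=2.0, her2_clinical_pos=False)
        ordinal = compute_ihc4(panel, ScoreOptions())
        binary = compute_ihc4(panel, ScoreOptions(her2_coding="clinical_binary"))
        assert ordinal - binary == pytest.approx(94.7 * 0.586 * 2.0)

    def test_panel_wrapper_missing_component(self):
        with pytest.raises(ValueError, match="her2"):
            compute_ihc4(MarkerPanel(er_pct=50, pr_pct=50, ki67_pct=5))

    @given(
        er=st.floats(0, 100), pr=st.floats(0, 100),
        her2=st.floats(0, 3), ki67=st.floats(0, 100),
        bump=st.floats(0.1, 10),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotonicity(self, er, pr, her2, ki67, bump):
        base = ihc4_score(er, pr, her2, ki67)
        if er + bump <= 100:
            assert ihc4_score(er + bump, pr, her2, ki67) < base
        if pr + bump <= 100:
            assert ihc4_score(er, pr + bump, her2, ki67) < base
        if her2 + bump <= 3:
            assert ihc4_score(er, pr, her2 + bump, ki67) > base
        assert ihc4_score(er, pr, her2, ki67 + bump) > base

    @given(
        er=st.floats(0, 100), pr=st.floats(0, 100),
        her2=st.floats(0, 3), ki67=st.floats(0, 100),
    )
    @settings(max_examples=200, deadline=None)
    def test_oracle_agreement(self, er, pr, her2, ki67):
        assert ihc4_score(er, pr, her2, ki67) == pytest.approx(
            oracle_ihc4(er, pr, her2, ki67), abs=1e-9
        )


# ---------------------------------------------------------------------------
# C-score
# ---------------------------------------------------------------------------


class TestCScore:
    def test_reference_category_is_zero(self):
        assert c_score(0, 8, 1, 50) == 0.0

    def test_printed_example_mid_categories(self):
        # frozen from oracle_c: 100*(0.417 + 0.930*0.497 + 0.559 + 0.130)
        assert c_score(2, 15, 2, 70) == pytest.approx(156.821, abs=1e-9)

    def test_printed_example_high_categories(self):
        assert c_score(5, 35, 3, 50) == pytest.approx(437.4, abs=1e-9)

    def test_whole_bracket_convention(self):
        printed = c_score(0, 15, 1, 50)
        whole = c_score(0, 15, 1, 50, bracket_convention="whole_bracket")
        assert printed == pytest.approx(whole)  # only T12 term differs by none here
        assert c_score(0, 25, 1, 50, bracket_convention="whole_bracket") == pytest.approx(
            100 * 0.930 * 0.882
        )

    def test_errors(self):
        with pytest.raises(ValueError):
            c_score(-1, 10, 1, 50)
        with pytest.raises(ValueError):
            c_score(0, -5, 1, 50)

    def test_dataclass_wrapper(self):
        cf = ClinicalFactors(age_years=70, tumor_size_mm=15, grade=2, positive_nodes=2)
        assert compute_c_score(cf) == pytest.approx(156.821)

    @given(
        nodes=st.integers(0, 30),
        size=st.floats(0.5, 90),
        grade=st.integers(1, 3),
        age=st.floats(20, 95),
    )
    @settings(max_examples=200, deadline=None)
    def test_oracle_agreement_and_nonnegative(self, nodes, size, grade, age):
        v = c_score(nodes, size, grade, age)
        assert v == pytest.approx(oracle_c(nodes, size, grade, age), abs=1e-9)
        assert v >= 0.0


# ---------------------------------------------------------------------------
# PREDICT
# ---------------------------------------------------------------------------


class TestPredict:
    def test_example_one(self):
        # frozen from oracle_predict(50, 20, 0, 2) = 0.6862238416985...
        assert predict_score(50, 20, 0, 2) == pytest.approx(0.6862238416985389, abs=1e-9)

    def test_example_two(self):
        # frozen from oracle_predict(65, 15, 2, 1) = 0.6221057249503...
        assert predict_score(65, 15, 2, 1) == pytest.approx(0.6221057249503693, abs=1e-9)

    def test_grade_term_is_linear(self):
        d = predict_score(50, 20, 0, 3) - predict_score(50, 20, 0, 2)
        assert d == pytest.approx(0.7467, abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            predict_score(0, 20, 0, 2)
        with pytest.raises(ValueError):
            predict_score(50, 0, 0, 2)

    def test_dataclass_wrapper(self):
        cf = ClinicalFactors(age_years=50, tumor_size_mm=20, grade=2, positive_nodes=0)
        assert compute_predict_score(cf) == pytest.approx(0.6862238416985389)

    @given(
        age=st.floats(20, 95), size=st.floats(1, 90),
        nodes=st.integers(0, 30), grade=st.integers(1, 3),
    )
    @settings(max_examples=200, deadline=None)
    def test_oracle_agreement(self, age, size, nodes, grade):
        assert predict_score(age, size, nodes, grade) == pytest.approx(
            oracle_predict(age, size, nodes, grade), abs=1e-9
        )


# ---------------------------------------------------------------------------
# subtype classification
# ---------------------------------------------------------------------------


def _panel(er, pr, her2_pos, ki67):
    return MarkerPanel(
        er_pct=er, pr_pct=pr, ki67_pct=ki67,
        her2_herceptest=3.0 if her2_pos else 0.0,
    )


class TestSubtype:
    def test_a_like(self):
        assert classify_subtype(_panel(80, 80, False, 10)) is Subtype.A_LIKE

    def test_b_like_via_her2(self):
        assert classify_subtype(_panel(80, 0, True, 5)) is Subtype.B_LIKE

    def test_b_like_via_ki67(self):
        assert classify_subtype(_panel(80, 80, False, 13)) is Subtype.B_LIKE

    def test_unclassified_gap(self):
        assert classify_subtype(_panel(80, 0, False, 5)) is Subtype.UNCLASSIFIED

    def test_ki67_boundary_is_low(self):
        assert classify_subtype(_panel(80, 80, False, 12)) is Subtype.A_LIKE

    def test_non_luminal_errors(self):
        with pytest.raises(ValueError, match="non-luminal"):
            classify_subtype(_panel(0, 0, False, 5))

    def test_clinical_status_precedence(self):
        panel = MarkerPanel(er_pct=5, pr_pct=5, ki67_pct=20,
                            her2_herceptest=0.0, er_clinical_pos=True)
        assert classify_subtype(panel) is Subtype.B_LIKE

    def test_exhaustive_grid_truth_table(self):
        for er_pos in (True, False):
            for pr_pos in (True, False):
                for her2_pos in (True, False):
                    for ki67 in range(0, 101):
                        panel = _panel(80 if er_pos else 0, 80 if pr_pos else 0,
                                       her2_pos, ki67)
                        if not (er_pos or pr_pos):
                            with pytest.raises(ValueError):
                                classify_subtype(panel)
                            continue
                        got = classify_subtype(panel)
                        expect_b = ki67 > 12 or her2_pos
                        expect_a = er_pos and pr_pos and not her2_pos and ki67 <= 12
                        assert not (expect_a and expect_b)
                        if expect_b:
                            assert got is Subtype.B_LIKE
                        elif expect_a:
                            assert got is Subtype.A_LIKE
                        else:
                            assert got is Subtype.UNCLASSIFIED
                        if er_pos and pr_pos:
                            assert got is not Subtype.UNCLASSIFIED

    @given(
        er=st.floats(0, 100), pr=st.floats(0, 100),
        her2_pos=st.booleans(), ki67=st.floats(0, 100),
    )
    @settings(max_examples=200, deadline=None)
    def test_threshold_relaxation_never_moves_b_to_a(self, er, pr, her2_pos, ki67):
        def _cls(thr):
            panel = _panel(er, pr, her2_pos, ki67)
            try:
                return classify_subtype(panel, ScoreOptions(er_pr_positivity_threshold=thr))
            except ValueError:
                return None

        at10, at1 = _cls(10.0), _cls(1.0)
        assert not (at10 is Subtype.B_LIKE and at1 is Subtype.A_LIKE)

    def test_vectorized_matches_scalar(self, small_cohort):
        import pandas as pd

        labels = classify_subtypes(small_cohort)
        for i in small_cohort.index[:50]:
            row = small_cohort.loc[i]
            panel = MarkerPanel(
                er_pct=row.er_pct, pr_pct=row.pr_pct, ki67_pct=row.ki67_pct,
                her2_herceptest=row.her2_herceptest,
                er_clinical_pos=bool(row.er_clinical_pos),
                pr_clinical_pos=bool(row.pr_clinical_pos),
                her2_clinical_pos=bool(row.her2_clinical_pos),
            )
            assert labels.loc[i] == classify_subtype(panel).value


# ---------------------------------------------------------------------------
# categorical transforms
# ---------------------------------------------------------------------------


class TestStandardize:
    def test_hand_example(self):
        z = standardize_per_sd([0, 0, 10, 10])
        assert z == pytest.approx([-0.8660254, -0.8660254, 0.8660254, 0.8660254])

    def test_constant_errors(self):
        with pytest.raises(ValueError, match="variance"):
            standardize_per_sd([3.0, 3.0, 3.0])

    @given(st.lists(st.floats(-1e4, 1e4), min_size=3, max_size=50, unique=True))
    @settings(max_examples=100, deadline=None)
    def test_normalization_identity(self, xs):
        assume(np.std(xs, ddof=1) > 1e-9)
        z = standardize_per_sd(xs)
        assert np.mean(z) == pytest.approx(0, abs=1e-8)
        assert np.std(z, ddof=1) == pytest.approx(1, abs=1e-8)


class TestDichotomize:
    def test_hand_example(self):
        high, thr = dichotomize_mean_plus_sd([0, 0, 0, 10])
        assert thr == pytest.approx(7.5)
        assert list(high) == [False, False, False, True]

    def test_single_outlier(self):
        vals = [1.0] * 20 + [100.0]
        high, _ = dichotomize_mean_plus_sd(vals)
        assert high.sum() == 1 and high[-1]

    def test_gaussian_tail_fraction(self, rng):
        x = rng.standard_normal(100_000)
        high, _ = dichotomize_mean_plus_sd(x)
        # P(Z > 1) = 0.1587
        assert high.mean() == pytest.approx(0.1587, abs=0.01)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            dichotomize_mean_plus_sd([1.0, 1.0])


class TestQuartiles:
    def test_uniform_ranks(self):
        q = assign_quartiles(range(1, 9))
        assert list(q) == [1, 1, 2, 2, 3, 3, 4, 4]

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=101)
        assert list(assign_quartiles(x)) == list(assign_quartiles(np.exp(x)))

    def test_boundary_value_goes_to_lower_bin(self):
        # n=9: the 25th percentile is exactly the 3rd value (30)
        x = [10, 20, 30, 40, 50, 60, 70, 80, 90]
        assert np.percentile(x, 25) == 30
        assert assign_quartiles(x)[2] == 1

    def test_all_bins_nonempty(self, rng):
        x = rng.normal(size=37)
        q = assign_quartiles(x)
        assert set(q) == {1, 2, 3, 4}

    def test_too_few_distinct_errors(self):
        with pytest.raises(ValueError, match="distinct"):
            assign_quartiles([1, 1, 2, 2, 3])
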