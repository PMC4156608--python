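"""Welch tests, percent change, fold factors and multiple-testing corrections."""

import numpy as np
import pytest
from scipy import stats as sps
from hypothesis import given
from hypothesis import strategies as st

from _oracles import brute_force_holm, permutation_welch_p
from lamap import stats as lst
from lamap.errors import CompletenessError, DomainError, SampleSizeError


class TestWelch:
    def test_identical_vectors_null(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = lst.welch_test(a, a)
        assert res.t == 0.0 and res.p == 1.0

    def test_cortex_cu_summary_below_bonferroni(self):
        # control 2.7 ± 0.7 (n=8) vs WD 5.5 ± 1.2 (n=9)
        res = lst.welch_from_summary(2.7, 0.7, 8, 5.5, 1.2, 9)
        assert res.p < 0.0006

    def test_summary_hand_arithmetic(self):
        res = lst.welch_from_summary(4.2, 1.4, 8, 6.7, 1.5, 9)
        assert abs(res.t) == pytest.approx(3.553, abs=0.005)
        assert res.p == pytest.approx(0.003, abs=0.001)

    def test_summary_matches_vector_form(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 2, 9)
        v = lst.welch_test(a, b)
        s = lst.welch_from_summary(
            a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
        )
        assert v.t == pytest.approx(s.t) and v.p == pytest.approx(s.p)
        assert v.df == pytest.approx(s.df)

    def test_equal_means_unequal_sds_null(self):
        res = lst.welch_from_summary(5.0, 1.0, 8, 5.0, 3.0, 9)
        assert res.t == 0.0 and res.p == 1.0

    def test_zero_variance_equal_means_p_one(self):
        res = lst.welch_from_summary(5.0, 0.0, 8, 5.0, 0.0, 9)
        assert res.p == 1.0

    def test_short_vectors_rejected(self):
        with pytest.raises(SampleSizeError):
            lst.welch_test(np.array([1.0]), np.array([1.0, 2.0]))

    @given(st.integers(0, 200))
    def test_symmetry_up_to_sign(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, int(rng.integers(2, 8)))
        b = rng.normal(0.5, 2, int(rng.integers(2, 8)))
        ab, ba = lst.welch_test(a, b), lst.welch_test(b, a)
        assert ab.t == pytest.approx(-ba.t)
        assert ab.p == pytest.approx(ba.p)

    @given(st.integers(0, 100))
    def test_matches_scipy_ttest_ind(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, int(rng.integers(2, 12)))
        b = rng.normal(0.3, 1.7, int(rng.integers(2, 12)))
        res = lst.welch_test(a, b)
        ref_t, ref_p = sps.ttest_ind(a, b, equal_var=False)
        assert res.t == pytest.approx(float(ref_t), rel=1e-12)
        assert res.p == pytest.approx(float(ref_p), rel=1e-9)

    def test_agrees_with_permutation_oracle(self):
        # mean signed Welch-vs-permutation difference consistent with zero,
        # each pair within the coarse approximation bound for n ≤ 10
        rng = np.random.default_rng(2024)
        diffs = []
        for trial in range(8):
            na, nb = rng.integers(5, 11, 2)
            a = rng.normal(0, 1, na)
            b = rng.normal(rng.uniform(0, 1), 1, nb)
            p_w = lst.welch_test(a, b).p
            p_perm = permutation_welch_p(a, b, n_draws=20_000, seed=trial)
            diffs.append(p_w - p_perm)
            assert abs(p_w - p_perm) <= max(0.25 * max(p_w, p_perm), 0.02)
        diffs = np.array(diffs)
        assert abs(diffs.mean()) < 3 * diffs.std(ddof=1) / np.sqrt(diffs.size)


class TestEffectSizes:
    @pytest.mark.parametrize(
        "control,wd,expected",
        [(5.2, 8.9, 71), (39.0, 17.0, -56), (3.0, 3.0, 0)],
    )
    def test_percent_change_rounding(self, control, wd, expected):
        assert lst.round_percent(lst.percent_change(control, wd)) == expected

    def test_percent_change_domain(self):
        with pytest.raises(DomainError):
            lst.percent_change(0.0, 5.0)

    @pytest.mark.parametrize(
        "control,wd,direction,expected",
        [(67.0, 19.0, "decrease", 3.5), (2.7, 5.5, "increase", 2.0),
         (4.0, 4.0, "auto", 1.0)],
    )
    def test_fold_factor_rounding(self, control, wd, direction, expected):
        assert lst.round_fold(lst.fold_factor(control, wd, direction)) == expected

    @given(st.floats(0.1, 100), st.floats(0.1, 100))
    def test_increase_factor_consistent_with_percent(self, control, wd):
        # unrounded: increase factor = 1 + %/100
        factor = lst.fold_factor(control, wd, "increase")
        assert factor == pytest.approx(1 + lst.percent_change(control, wd) / 100)


class TestThresholds:
    def test_reference_family(self):
        th = lst.bonferroni_threshold(21, 4, 0.05)
        assert th == pytest.approx(0.05 / 84)
        assert lst.round_one_significant(th) == pytest.approx(0.0006)

    @pytest.mark.parametrize(
        "regions,elements,alpha,expected",
        [(1, 1, 0.05, 0.05), (2, 5, 0.05, 0.005)],
    )
    def test_hand_arithmetic(self, regions, elements, alpha, expected):
        assert lst.bonferroni_threshold(regions, elements, alpha) == pytest.approx(expected)


class TestHolm:
    def test_single_p_both_modes(self):
        for mode in lst.HOLM_MODES:
            res = lst.holm_adjust([0.04], alpha=0.05, mode=mode)
            assert res.flags.tolist() == [True]
            assert res.mode == mode

    def test_step_down_rule_hand_case(self):
        res = lst.holm_adjust([0.001, 0.02, 0.04], alpha=0.05, mode="standard")
        assert res.flags.tolist() == [True, True, True]

    def test_literal_mode_uses_alpha_over_rank(self):
        # thresholds 0.05, 0.025, 0.0167 down the sorted list
        res = lst.holm_adjust([0.03, 0.024, 0.02], alpha=0.05, mode="literal")
        assert res.flags.tolist() == [False, True, True]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            p = rng.uniform(1e-6, 1.0, int(rng.integers(1, 30)))
            flags = lst.holm_adjust(p, alpha=0.05, mode="standard").flags
            np.testing.assert_array_equal(flags, brute_force_holm(p, 0.05))

    def test_standard_holm_dominates_bonferroni(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            p = rng.uniform(1e-6, 1.0, int(rng.integers(1, 40)))
            holm = lst.holm_adjust(p, alpha=0.05, mode="standard").flags
            bonf = lst.bonferroni_flags(p, 0.05)
            assert np.all(holm >= bonf)

    def test_empty_input_rejected(self):
        with pytest.raises(DomainError):
            lst.holm_adjust([])


class TestBuildReport:
    def test_zero_noise_cohort_reproduces_group_means(self):
        cohort = {
            ("cortex", "Cu63"): {
                "control": np.full(8, 2.7),
                "wd": np.full(9, 5.5),
            },
            ("cortex", "Fe57"): {
                "control": np.full(8, 12.4),
                "wd": np.full(9, 12.1),
            },
        }
        report = lst.build_report(cohort)
        cu = report[report.channel == "Cu63"].iloc[0]
        assert cu["control_mean"] == 2.7 and cu["wd_mean"] == 5.5
        assert lst.round_percent(cu["percent_change"]) == 104
        assert cu["p"] < 1e-10

    def test_empty_group_rejected(self):
        cohort = {("cortex", "Cu63"): {"control": np.full(8, 2.7), "wd": np.array([])}}
        with pytest.raises(CompletenessError):
            lst.build_report(cohort)

    def test_formatted_report_suppresses_nonsignificant_change(self):
        rng = np.random.default_rng(4)
        cohort = {
            ("cortex", "Cu63"): {
                "control": rng.normal(2.7, 0.7, 8),
                "wd": rng.normal(5.5, 1.2, 9),
            },
            ("cortex", "Mn55"): {
                "control": rng.normal(0.23, 0.06, 8),
                "wd": rng.normal(0.23, 0.06, 9),
            },
        }
        report = lst.build_report(cohort)
        text = lst.format_report(report)
        cu_line = next(l for l in text.splitlines() if "Cu63" in l)
        mn_line = next(l for l in text.splitlines() if "Mn55" in l)
        assert "%" in cu_line and "%" not in mn_line
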