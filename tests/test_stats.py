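"""Rank tests, directional follow-up and the comparison battery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from cytoscout.stats import (
    ComparisonSpec,
    TestResult,
    correlate_clinical,
    default_comparison_specs,
    directional_followup,
    mann_whitney_u,
    run_comparisons,
    spearman_correlation,
    wilcoxon_signed_rank,
)

from _oracles import mwu_exact_two_sided, spearman_exact_two_sided, wilcoxon_exact_two_sided


class TestMannWhitney:
    @pytest.mark.parametrize(
        "x, y, u_expected, p_expected",
        [
            ([1, 2, 3], [4, 5, 6], 0.0, 0.1),     # fully separated, 2/20
            ([1, 3], [2, 4], 1.0, 2 / 3),          # interleaved, 4/6
        ],
    )
    def test_exact_small_sample(self, x, y, u_expected, p_expected):
        u, p = mann_whitney_u(x, y, mode="exact")
        assert u == u_expected
        assert p == pytest.approx(p_expected, abs=1e-12)

    def test_two_sided_symmetry_under_swap(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            x = rng.integers(0, 6, size=4).astype(float)
            y = rng.integers(0, 6, size=5).astype(float)
            _, p_xy = mann_whitney_u(x, y, mode="exact")
            _, p_yx = mann_whitney_u(y, x, mode="exact")
            assert p_xy == pytest.approx(p_yx, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_exact_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            n_x = int(rng.integers(2, 5))
            n_y = int(rng.integers(2, 5))
            x = rng.integers(0, 4, size=n_x).astype(float)
            y = rng.integers(0, 4, size=n_y).astype(float)
            _, p = mann_whitney_u(x, y, mode="exact")
            assert p == pytest.approx(mwu_exact_two_sided(x, y), abs=1e-12)

    def test_approx_close_to_scipy_on_large_samples(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 40)
        y = rng.normal(0.5, 1, 35)
        _, p = mann_whitney_u(x, y, mode="approx")
        p_ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic").pvalue
        assert p == pytest.approx(p_ref, rel=1e-6)


class TestWilcoxonSignedRank:
    @pytest.mark.parametrize(
        "diffs, p_expected",
        [
            ([1, 2, 3], 0.25),  # all-positive, extreme mass 2/8
            ([5], 1.0),          # single pair: both sign patterns extreme
        ],
    )
    def test_exact_small_sample(self, diffs, p_expected):
        _, p, degenerate = wilcoxon_signed_rank(diffs, mode="exact")
        assert not degenerate
        assert p == pytest.approx(p_expected, abs=1e-12)

    def test_all_zero_differences_degenerate(self):
        w, p, degenerate = wilcoxon_signed_rank([0.0, 0.0, 0.0])
        assert degenerate and p == 1.0

    def test_exact_matches_brute_force_with_ties_and_zeros(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            n = int(rng.integers(2, 8))
            d = rng.integers(-3, 4, size=n).astype(float)
            if (d != 0).sum() == 0:
                continue
            _, p, _ = wilcoxon_signed_rank(d, mode="exact")
            assert p == pytest.approx(wilcoxon_exact_two_sided(d), abs=1e-12)

    def test_pratt_zero_handling_changes_ranks(self):
        # zeros kept in the ranking shift the non-zero ranks upward
        d = [0.0, 1.0, -2.0, 3.0]
        w_drop, _, _ = wilcoxon_signed_rank(d, zero_method="drop")
        w_pratt, _, _ = wilcoxon_signed_rank(d, zero_method="pratt")
        assert w_pratt > w_drop


class TestSpearman:
    def test_perfect_monotone(self):
        rho, p = spearman_correlation([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_correlation([1, 2, 3, 4], [8, 6, 4, 2])
        assert rho == pytest.approx(-1.0)

    def test_closed_form_three_points(self):
        rho, _ = spearman_correlation([1, 2, 3], [2, 1, 3])
        assert rho == pytest.approx(0.5)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_correlation([1, 1, 1], [1, 2, 3])

    def test_exact_matches_permutation_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            x = rng.permutation(5).astype(float)
            y = rng.integers(0, 4, size=5).astype(float)
            if np.std(sps.rankdata(y)) == 0:
                continue
            rho, p = spearman_correlation(x, y, mode="exact")
            rho_ref, p_ref = spearman_exact_two_sided(x, y)
            assert rho == pytest.approx(rho_ref, abs=1e-12)
            assert p == pytest.approx(p_ref, abs=1e-12)


class TestDirectionalFollowup:
    def _result(self, p):
        return TestResult("a", "c", "m", 10, 1.0, p)

    def test_not_significant_keeps_direction_none(self):
        res = directional_followup(self._result(0.20), 0.10, 0.90)
        assert res.direction == "none" and res.p_one_sided is None

    def test_significant_picks_smaller_tail(self):
        res = directional_followup(self._result(0.03), 0.015, 0.99)
        assert res.direction == "increase" and res.p_one_sided == 0.015
        res = directional_followup(self._result(0.03), 0.99, 0.015)
        assert res.direction == "decrease"

    def test_exactly_alpha_is_not_significant(self):
        res = directional_followup(self._result(0.05), 0.01, 0.99, alpha=0.05)
        assert res.direction == "none"


def _toy_cohort():
    samples = pd.DataFrame({
        "sample_id": ["p1a", "p1b", "p2a", "p2b", "p3a", "n1", "n2", "n3"],
        "patient_id": ["P1", "P1", "P2", "P2", "P3", "N1", "N2", "N3"],
        "cohort": ["PDAC"] * 5 + ["ND"] * 3,
        "site": ["PB"] * 8,
        "timepoint": ["Pre", "Post", "Pre", "Post", "Pre", "Pre", "Pre", "Pre"],
    })
    enum = pd.DataFrame(
        {"ctc": [5.0, 9.0, 4.0, 8.0, 6.0, 1.0, 2.0, 1.5]},
        index=pd.Index(samples["sample_id"], name="sample_id"))
    return enum, samples


class TestRunComparisons:
    def test_patient_missing_post_draw_excluded_from_pairs(self):
        enum, samples = _toy_cohort()
        specs = [ComparisonSpec("ctc", "paired", "timepoint", ("Pre", "Post"),
                                {"cohort": "PDAC", "site": "PB"})]
        out = run_comparisons(enum, samples, specs)
        assert out.loc[0, "n"] == 2  # P3 has no Post draw

    def test_row_order_invariance(self):
        enum, samples = _toy_cohort()
        specs = default_comparison_specs(samples, ["ctc"])
        out1 = run_comparisons(enum, samples, specs)
        shuffled = samples.sample(frac=1.0, random_state=1).reset_index(drop=True)
        out2 = run_comparisons(enum.iloc[::-1], shuffled, specs)
        pd.testing.assert_frame_equal(out1, out2)

    def test_insufficient_data_flagged_not_dropped(self):
        enum, samples = _toy_cohort()
        only_p3 = samples[samples["sample_id"].isin(["p3a"])]
        specs = [ComparisonSpec("ctc", "unpaired", "cohort", ("ND", "PDAC"))]
        out = run_comparisons(enum.loc[["p3a"]], only_p3, specs)
        assert len(out) == 1 and out.loc[0, "note"] == "insufficient"

    def test_planted_increase_detected_with_direction(self):
        enum, samples = _toy_cohort()
        specs = [ComparisonSpec("ctc", "unpaired", "cohort", ("ND", "PDAC"))]
        out = run_comparisons(enum, samples, specs)
        assert out.loc[0, "p_two_sided"] < 0.05
        assert out.loc[0, "direction"] == "increase"  # PDAC exceeds ND


class TestCorrelateClinical:
    def test_monotone_tumor_volume_gives_rho_one(self):
        clin = pd.DataFrame({"patient_id": [f"P{i}" for i in range(8)],
                             "tumor_volume": np.arange(8) + 1.0})
        enum = pd.DataFrame({"ctc": (np.arange(8) + 1.0) * 2},
                            index=pd.Index([f"P{i}" for i in range(8)], name="patient_id"))
        out = correlate_clinical(enum, clin, {"tumor_volume": "continuous"})
        assert out.loc[0, "statistic"] == pytest.approx(1.0)
        assert out.loc[0, "p"] < 0.01

    def test_binary_variable_uses_signed_z(self):
        rng = np.random.default_rng(2)
        n = 30
        sex = np.array(["F"] * 15 + ["M"] * 15)
        vals = np.where(sex == "M", rng.normal(10, 1, n), rng.normal(2, 1, n))
        clin = pd.DataFrame({"patient_id": [f"P{i}" for i in range(n)], "sex": sex})
        enum = pd.DataFrame({"ctc": vals},
                            index=pd.Index([f"P{i}" for i in range(n)], name="patient_id"))
        out = correlate_clinical(enum, clin, {"sex": "categorical"})
        # M sorts after F, so M-high values give a positive signed z
        assert out.loc[0, "method"] == "rank-sum-z"
        assert out.loc[0, "statistic"] > 3
        assert out.loc[0, "p"] < 0.001

    def test_multilevel_categorical_rejected(self):
        clin = pd.DataFrame({"patient_id": ["a", "b", "c"],
                             "race": ["White", "Black", "Other"]})
        enum = pd.DataFrame({"ctc": [1.0, 2.0, 3.0]},
                            index=pd.Index(["a", "b", "c"], name="patient_id"))
        with pytest.raises(ValueError, match="binary"):
            correlate_clinical(enum, clin, {"race": "categorical"})

    def test_ordinal_stage_codes_recover_planted_effect(self):
        stages = ["pT0", "pT1", "pT2", "pT3", "pT4"] * 3
        clin = pd.DataFrame({"patient_id": [f"P{i}" for i in range(15)], "pT": stages})
        codes = {"pT0": 0, "pT1": 1, "pT2": 2, "pT3": 3, "pT4": 4}
        vals = np.array([codes[s] for s in stages], dtype=float) * 3 + 1
        enum = pd.DataFrame({"ctc": vals},
                            index=pd.Index([f"P{i}" for i in range(15)], name="patient_id"))
        out = correlate_clinical(enum, clin, {"pT": "ordinal"}, ordinal_codes={"pT": codes})
        assert out.loc[0, "statistic"] > 0.9


_small_ints = st.lists(st.integers(-5, 5), min_size=2, max_size=8)


@settings(deadline=None, derandomize=True, max_examples=60)
@given(x=_small_ints, y=_small_ints)
def test_mwu_p_valid_and_symmetric(x, y):
    """p stays in [0,1] and is invariant under swapping the two samples."""
    _, p_xy = mann_whitney_u(x, y)
    _, p_yx = mann_whitney_u(y, x)
    assert 0.0 <= p_xy <= 1.0
    assert p_xy == pytest.approx(p_yx, abs=1e-12)


@settings(deadline=None, derandomize=True, max_examples=60)
@given(d=st.lists(st.integers(-5, 5), min_size=1, max_size=12))
def test_wilcoxon_p_valid_and_sign_antisymmetric(d):
    """p stays in [0,1] and is invariant under negating every difference."""
    _, p, _ = wilcoxon_signed_rank(d)
    _, p_neg, _ = wilcoxon_signed_rank([-v for v in d])
    assert 0.0 <= p <= 1.0
    assert p == pytest.approx(p_neg, abs=1e-12)


class TestInvariants:
    def test_two_sided_at_least_each_one_sided(self):
        from cytoscout.stats import _mwu_one_sided

        rng = np.random.default_rng(17)
        for _ in range(25):
            x = rng.integers(0, 5, size=4).astype(float)
            y = rng.integers(0, 5, size=4).astype(float)
            _, p2 = mann_whitney_u(x, y, mode="exact")
            pg = _mwu_one_sided(x, y, "greater", mode="exact")
            pl = _mwu_one_sided(x, y, "less", mode="exact")
            assert 0.0 <= p2 <= 1.0
            assert p2 >= min(1.0, 2 * min(pg, pl)) - 1e-12
            assert p2 <= 1.0 + 1e-12
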