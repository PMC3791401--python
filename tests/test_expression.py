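"""Misregulation calling and the binding-vs-expression statistics, each
checked against an independent closed-form or enumeration oracle."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from tboxscan.expression import (
    bh_adjust, call_misregulated, chip_enrichment, fisher_overlap,
    fold_change_test, mannwhitney_binding, quantify_from_standard_curve,
    signed_fold,
)


def mw_enumeration_oracle(x, y):
    """Exact one-tailed Mann-Whitney p by enumerating group assignments and
    counting pairwise wins directly (no ranks): U = #{x_i > y_j} + 0.5 ties."""
    def u_stat(a, b):
        return sum((1.0 if ai > bj else 0.5 if ai == bj else 0.0)
                   for ai in a for bj in b)

    pooled = list(x) + list(y)
    n1 = len(x)
    u_obs = u_stat(x, y)
    count = total = 0
    for idx in combinations(range(len(pooled)), n1):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        if u_stat(a, b) >= u_obs - 1e-12:
            count += 1
        total += 1
    return count / total


class TestSignedFold:
    @pytest.mark.parametrize("ratio,expected", [
        (2.0, 2.0), (1.0, 1.0), (0.5, -2.0), (0.25, -4.0),
    ])
    def test_convention(self, ratio, expected):
        assert signed_fold(ratio) == pytest.approx(expected)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            signed_fold(0.0)


class TestFoldChangeTest:
    def test_identical_groups_p_one(self):
        fold, p = fold_change_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)
        assert fold == pytest.approx(1.0)

    def test_twofold_knockdown_down(self):
        rng = np.random.default_rng(0)
        ctrl = 5.0 + rng.normal(0, 0.01, 4)
        kd = 4.0 + rng.normal(0, 0.01, 4)  # one log2 unit lower
        fold, p = fold_change_test(ctrl, kd)
        assert fold == pytest.approx(-2.0, abs=0.05)
        assert p < 1e-6

    def test_matches_t_cdf_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            a = rng.normal(size=3)
            b = rng.normal(size=3)
            _, p = fold_change_test(a, b)
            # pooled-variance two-sample t, two-tailed, df = n1+n2-2
            n1, n2 = len(a), len(b)
            sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) \
                / (n1 + n2 - 2)
            t = (b.mean() - a.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
            oracle = 2.0 * stats.t.sf(abs(t), n1 + n2 - 2)
            assert p == pytest.approx(oracle, abs=1e-9)

    def test_linear_scale_mode(self):
        fold, _ = fold_change_test([10.0, 10.0], [20.0, 20.0],
                                   log_scale=False)
        assert fold == pytest.approx(2.0)
        with pytest.raises(ValueError):
            fold_change_test([0.0, 0.0], [1.0, 2.0], log_scale=False)

    def test_too_few_replicates(self):
        with pytest.raises(ValueError):
            fold_change_test([1.0], [1.0, 2.0])


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        # p*(n/rank) = (.04, .04, .04, .04) after monotonisation
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_monotone_bounded_order_preserving(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=50)
        fdr = bh_adjust(p)
        assert np.all((fdr >= 0) & (fdr <= 1))
        order = np.argsort(p)
        assert np.all(np.diff(fdr[order]) >= -1e-12)

    def test_matches_statsmodels(self):
        statsmodels = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(6)
        p = rng.uniform(size=40)
        _, ref, _, _ = statsmodels.multipletests(p, method="fdr_bh")
        assert np.allclose(bh_adjust(p), ref)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestCallMisregulated:
    @pytest.mark.parametrize("fold,fdr,expected", [
        (-1.6, 0.05, "down"),
        (-1.4, 0.001, "unaffected"),  # fold below cut
        (2.0, 0.2, "unaffected"),     # fdr above cut
        (1.5, 0.09, "up"),
        (-1.5, 0.09, "down"),
    ])
    def test_thresholds(self, fold, fdr, expected):
        (call,) = call_misregulated([("g", fold, 0.01, fdr)])
        assert call.direction == expected


class TestFisherOverlap:
    def test_hypergeometric_enumeration_example(self):
        # N=10, |A|=5, |B|=4, observed 4: p = C(5,4) C(5,0) / C(10,4) = 5/210
        a = set("abcde")
        b = set("abcd")
        res = fisher_overlap(a, b, 10)
        assert res.expected_overlap == pytest.approx(2.0)
        assert res.p_value == pytest.approx(5.0 / 210.0)

    def test_empty_set_p_one(self):
        res = fisher_overlap(set(), set("ab"), 10)
        assert res.expected_overlap == 0.0 and res.p_value == 1.0

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_direct_summation(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(10, 40))
        universe = list(range(N))
        a = set(rng.choice(universe, rng.integers(1, N), replace=False))
        b = set(rng.choice(universe, rng.integers(1, N), replace=False))
        res = fisher_overlap(a, b, N)
        k = len(a & b)
        oracle = sum(
            math.comb(len(a), i) * math.comb(N - len(a), len(b) - i)
            for i in range(k, min(len(a), len(b)) + 1)
        ) / math.comb(N, len(b))
        assert res.p_value == pytest.approx(oracle, rel=1e-12)

    def test_null_calibration(self):
        # with random same-size sets, P(p <= 0.05) should be at most ~0.05
        # (discreteness makes the test conservative)
        rng = np.random.default_rng(7)
        N, na, nb = 200, 40, 40
        rejections = 0
        n_draws = 400
        for _ in range(n_draws):
            a = set(rng.choice(N, na, replace=False))
            b = set(rng.choice(N, nb, replace=False))
            rejections += fisher_overlap(a, b, N).p_value <= 0.05
        assert rejections / n_draws <= 0.08


class TestMannWhitney:
    def test_spec_example_exact(self):
        res = mannwhitney_binding([3, 4, 5], [1, 2])
        assert res.u_statistic == 6.0
        assert res.p_value == pytest.approx(0.1)  # 1 of C(5,2)=10 assignments
        assert res.exact

    def test_identical_sets_no_evidence(self):
        res = mannwhitney_binding([1, 2, 3], [1, 2, 3])
        assert res.p_value >= 0.5

    def test_zero_handling_changes_sample_sizes(self):
        with_zeros = mannwhitney_binding([0, 0, 5], [0, 1],
                                         include_zeros=True)
        without = mannwhitney_binding([0, 0, 5], [0, 1],
                                      include_zeros=False)
        assert (with_zeros.n1, with_zeros.n2) == (3, 2)
        assert (without.n1, without.n2) == (1, 1)

    def test_empty_after_zero_removal_raises(self):
        with pytest.raises(ValueError, match="set 1"):
            mannwhitney_binding([0, 0], [1, 2], include_zeros=False)

    @pytest.mark.parametrize("seed", range(30))
    def test_exact_branch_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1 = int(rng.integers(2, 6))
        n2 = int(rng.integers(2, 11 - n1))
        # integer values force ties regularly
        x = rng.integers(0, 5, n1).astype(float).tolist()
        y = rng.integers(0, 5, n2).astype(float).tolist()
        res = mannwhitney_binding(x, y)
        assert res.exact
        assert res.p_value == pytest.approx(mw_enumeration_oracle(x, y),
                                            abs=1e-12)

    def test_u_statistic_bounds(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.normal(size=8).tolist()
            y = rng.normal(size=9).tolist()
            res = mannwhitney_binding(x, y)
            assert 0 <= res.u_statistic <= res.n1 * res.n2

    def test_large_sample_branch_close_to_scipy_exact(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0.3, 1.0, 15).tolist()
        y = rng.normal(0.0, 1.0, 15).tolist()
        res = mannwhitney_binding(x, y)
        assert not res.exact
        ref = stats.mannwhitneyu(x, y, alternative="greater",
                                 method="exact").pvalue
        assert res.p_value == pytest.approx(ref, abs=0.02)


class TestStandardCurve:
    def test_line_inversion(self):
        # ct = -3.32 log10 q + 20; ct 16.68 -> q = 10
        pts = [(0.0, 20.0), (1.0, 16.68), (2.0, 13.36)]
        assert quantify_from_standard_curve(16.68, pts) == pytest.approx(
            10.0, rel=1e-9)

    def test_ct_at_intercept_gives_unity(self):
        pts = [(0.0, 20.0), (1.0, 16.68), (2.0, 13.36)]
        assert quantify_from_standard_curve(20.0, pts) == pytest.approx(1.0)

    def test_degenerate_curve_rejected(self):
        with pytest.raises(ValueError):
            quantify_from_standard_curve(15.0, [(1.0, 16.0), (1.0, 16.0)])

    def test_positive_slope_rejected(self):
        with pytest.raises(ValueError, match="slope"):
            quantify_from_standard_curve(15.0, [(0.0, 10.0), (1.0, 12.0),
                                                (2.0, 14.0)])


class TestChipEnrichment:
    def test_vs_igg_unity_when_equal(self):
        assert chip_enrichment(2.0, 2.0, mode="vs_igg") == 1.0

    def test_percent_input_formula(self):
        # 5% input aliquot measuring 40 -> full input 800; 2/800 = 0.25%
        assert chip_enrichment(2.0, 40.0, mode="percent_input",
                               input_fraction=0.05) == pytest.approx(0.25)

    def test_percent_input_full_aliquot(self):
        assert chip_enrichment(3.0, 3.0, mode="percent_input",
                               input_fraction=1.0) == pytest.approx(100.0)

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            chip_enrichment(1.0, 0.0)
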