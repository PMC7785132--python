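import itertools
import math
from types import SimpleNamespace

import numpy as np
import pytest
from scipy.special import ndtri
from scipy.stats import norm

from enrichsurv import (PartitionSummaries, ScoreSummary,
                        SelectionResult, closed_test, combine_p,
                        duality_intervals, naive_ci, pM_plus, sidak)
from enrichsurv.interval_estimation import (lower_bound_all_rejected,
                                            lower_bound_mixed)

W_EQ = (1.0 / math.sqrt(2.0), 1.0 / math.sqrt(2.0))


def design_ns(weights=W_EQ, alpha=0.05):
    """Minimal design stand-in (only weights/alpha are consumed here)."""
    return SimpleNamespace(weights=weights, alpha=alpha)


def make_summaries(th_tilde, s_tilde2, th_s2, s_s22, selected):
    """Exact-normal summaries: interim == t~1 data, stage-2 == increment."""
    K = len(th_tilde)
    stage1 = [ScoreSummary.from_estimate(t, v)
              for t, v in zip(th_tilde, s_tilde2)]
    stage2 = [ScoreSummary.from_estimate(th_s2[j], s_s22[j])
              if (j + 1) in selected else None for j in range(K)]
    combined = [None] * K
    increment = [None] * K
    for j in selected:
        combined[j - 1] = ScoreSummary(S=stage1[j - 1].S + stage2[j - 1].S,
                                       V=stage1[j - 1].V + stage2[j - 1].V)
        increment[j - 1] = stage2[j - 1]
    return PartitionSummaries(K=K, stage1=stage1, stage1_tilde=stage1,
                              combined=combined, increment=increment,
                              stage2=stage2)


class TestNaiveCI:
    def test_worked_example(self):
        lo, hi = naive_ci(-0.746, 0.089, 0.05, 2)
        assert (round(lo, 3), round(hi, 3)) == (-1.415, -0.077)

    def test_single_selection_quantile(self):
        lo, hi = naive_ci(0.0, 1.0, 0.05, 1)
        assert hi == pytest.approx(1.960, abs=5e-4)

    def test_symmetric_about_estimate(self):
        lo, hi = naive_ci(0.37, 0.2, 0.05, 3)
        assert (lo + hi) / 2 == pytest.approx(0.37)
        assert lo < 0.37 < hi


class TestCombiners:
    def test_sidak_examples(self):
        assert sidak([0.0, 0.5], 2) == 0.0
        assert sidak([0.3], 1) == pytest.approx(0.3)
        assert sidak([0.2, 0.5, 0.9], 3) == pytest.approx(1 - 0.8 ** 3)

    def test_combine_p_median_fixed_point(self):
        assert combine_p(0.5, 0.5, W_EQ) == pytest.approx(0.5)

    def test_combine_p_degenerate_weight_returns_first(self):
        assert combine_p(0.123, 0.9, (1.0, 0.0)) == pytest.approx(0.123,
                                                                  abs=1e-12)

    def test_combine_p_monotone_in_each_argument(self):
        grid = np.linspace(0.01, 0.99, 25)
        for p2 in (0.1, 0.5, 0.9):
            vals = [combine_p(p1, p2, W_EQ) for p1 in grid]
            assert all(b >= a for a, b in zip(vals, vals[1:]))
            vals = [combine_p(p2, p1, W_EQ) for p1 in grid]
            assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_combine_p_extremes_clamped(self):
        assert combine_p(0.0, 0.0, W_EQ) == 0.0
        assert combine_p(1.0, 1.0, W_EQ) == 1.0
        assert 0.0 < combine_p(0.0, 0.9, W_EQ) < 1.0


def brute_force_adjusted(th_tilde, s_tilde2, th_s2, s_s22, selected, weights,
                         sign=1.0):
    """Subset-enumeration oracle for the closed test, written independently
    with scipy.stats.norm."""
    K = len(th_tilde)
    p1 = {j + 1: norm.sf(sign * th_tilde[j] / math.sqrt(s_tilde2[j]))
          for j in range(K)}
    p2 = {j: norm.sf(sign * th_s2[j - 1] / math.sqrt(s_s22[j - 1]))
          for j in selected}
    adjusted = {}
    for j in range(1, K + 1):
        worst = 0.0
        for r in range(1, K + 1):
            for I in itertools.combinations(range(1, K + 1), r):
                if j not in I:
                    continue
                p1I = 1 - (1 - min(p1[i] for i in I)) ** len(I)
                I2 = [i for i in I if i in selected]
                p2I = 1 - (1 - min(p2[i] for i in I2)) ** len(I2) if I2 else 1.0
                z = (weights[0] * ndtri(1 - min(max(p1I, 1e-15), 1 - 1e-15))
                     + weights[1] * ndtri(1 - min(max(p2I, 1e-15), 1 - 1e-15)))
                worst = max(worst, float(norm.sf(z)))
        adjusted[j] = worst
    return adjusted


class TestClosedTest:
    def test_matches_subset_enumeration_oracle(self, rng):
        for _ in range(25):
            K = 3
            th = rng.normal(0, 0.5, K)
            sv = rng.uniform(0.05, 0.3, K)
            th2 = rng.normal(0, 0.5, K)
            sv2 = rng.uniform(0.05, 0.3, K)
            selected = tuple(j for j in range(1, K + 1) if rng.random() < 0.7)
            if not selected:
                selected = (1,)
            summ = make_summaries(th, sv, th2, sv2, selected)
            sel = SelectionResult(rule="independent", selected=selected,
                                  bounds={j: (-math.inf, math.inf)
                                          for j in selected})
            for direction, sign in (("greater", 1.0), ("less", -1.0)):
                grid = closed_test(summ, sel, design_ns(), direction)
                oracle = brute_force_adjusted(th, sv, th2, sv2, selected,
                                              W_EQ, sign)
                for j in range(1, K + 1):
                    assert grid.adjusted[j] == pytest.approx(oracle[j],
                                                             abs=1e-12)

    def test_all_null_pvalues_reject_nothing(self):
        summ = make_summaries([-9.0, -9.0], [0.1, 0.1], [-9.0, -9.0],
                              [0.1, 0.1], (1, 2))
        sel = SelectionResult(rule="independent", selected=(1, 2),
                              bounds={1: (-math.inf, 0), 2: (-math.inf, 0)})
        grid = closed_test(summ, sel, design_ns(), "greater")
        assert not any(grid.rejected.values())
        grid_less = closed_test(summ, sel, design_ns(), "less")
        assert all(grid_less.rejected.values())

    def test_rejection_implies_elementary_p_small(self, rng):
        for _ in range(20):
            th = rng.normal(-0.5, 0.7, 3)
            summ = make_summaries(th, [0.05] * 3, th, [0.05] * 3, (1, 2, 3))
            sel = SelectionResult(rule="independent", selected=(1, 2, 3),
                                  bounds={j: (-math.inf, 0) for j in (1, 2, 3)})
            grid = closed_test(summ, sel, design_ns(), "less")
            for j, rej in grid.rejected.items():
                if rej:
                    elem = grid.subsets[frozenset({j})][2]
                    assert elem <= grid.alpha / 2


class TestPMPlus:
    def test_all_selected_gives_zero(self):
        sel = SelectionResult(rule="independent", selected=(1, 2))
        assert pM_plus({1: 0.3, 2: 0.9}, sel) == 0.0

    def test_single_dropped_partition(self):
        sel = SelectionResult(rule="independent", selected=(1,))
        assert pM_plus({1: 0.2, 2: 0.7}, sel) == pytest.approx(0.7)

    def test_two_dropped_matches_enumeration(self, rng):
        sel = SelectionResult(rule="independent", selected=(1, 2))
        for _ in range(20):
            p3, p4 = rng.random(2)
            got = pM_plus({1: 0.1, 2: 0.2, 3: p3, 4: p4}, sel)
            expect = max(p3, p4, 1 - (1 - min(p3, p4)) ** 2)
            assert got == pytest.approx(expect)


def grid_search_sup(f, lo, hi, level):
    """Dense two-pass grid search for sup{v : f(v) <= level}."""
    vs = np.arange(lo, hi, 1e-2)
    ok = [v for v in vs if f(v) <= level]
    coarse = max(ok)
    vs = np.arange(coarse, coarse + 2e-2, 1e-6)
    ok = [v for v in vs if f(v) <= level]
    return max(ok)


class TestBoundInversion:
    def _single_partition(self):
        th, sv = 0.8, 0.15 ** 2
        th2, sv2 = 0.7, 0.2 ** 2
        summ = make_summaries([th], [sv], [th2], [sv2], (1,))
        sel = SelectionResult(rule="independent", selected=(1,),
                              bounds={1: (-math.inf, math.inf)})
        return summ, sel

    def test_single_partition_matches_grid_search(self):
        summ, sel = self._single_partition()
        d = design_ns()
        bound = lower_bound_all_rejected(1, summ, sel, d, pM=0.0)

        th, s = 0.8, 0.15
        th2, s2 = 0.7, 0.2

        def f(v):
            p1 = norm.sf((th - v) / s)
            p2 = norm.sf((th2 - v) / s2)
            return combine_p(p1, p2, W_EQ)

        oracle = grid_search_sup(f, -1.0, 2.0, d.alpha / 2)
        assert bound == pytest.approx(oracle, abs=1e-5)
        assert bound > 0.0

    def test_bound_shrinks_with_alpha(self):
        summ, sel = self._single_partition()
        bounds = [lower_bound_all_rejected(1, summ, sel, design_ns(alpha=a),
                                           pM=0.0)
                  for a in (0.2, 0.1, 0.05, 0.01)]
        assert all(b >= a for a, b in zip(bounds[1:], bounds[:-1]))

    def test_nonnegative_by_construction(self):
        # weak evidence: the inner sup is negative, the outer max clips at 0
        summ = make_summaries([0.1], [0.2], [0.0], [0.2], (1,))
        sel = SelectionResult(rule="independent", selected=(1,))
        assert lower_bound_all_rejected(1, summ, sel, design_ns(), 0.0) == 0.0

    def test_mixed_case_rejected_partition_pinned_at_zero(self):
        # partition 1 overwhelmingly positive, partition 2 near the null:
        # mixed conclusions in the 'greater' direction
        summ = make_summaries([1.5, 0.05], [0.02, 0.02], [1.4, 0.0],
                              [0.02, 0.02], (1, 2))
        sel = SelectionResult(rule="independent", selected=(1, 2),
                              bounds={1: (-math.inf, math.inf),
                                      2: (-math.inf, math.inf)})
        d = design_ns()
        grid = closed_test(summ, sel, d, "greater")
        assert grid.rejected[1] and not grid.rejected[2]
        assert lower_bound_mixed(1, summ, sel, d, grid) == 0.0
        b2 = lower_bound_mixed(2, summ, sel, d, grid)
        assert math.isfinite(b2) and b2 < 0.05
        dual = duality_intervals(summ, sel, d)
        assert not dual[1].lower_informative
        assert dual[2].lower_informative


class TestDualityIntervals:
    def _random_case(self, rng, K=3):
        th = rng.normal(0, 0.6, K)
        sv = rng.uniform(0.02, 0.2, K)
        th2 = rng.normal(0, 0.6, K)
        sv2 = rng.uniform(0.02, 0.2, K)
        selected = tuple(j for j in range(1, K + 1) if rng.random() < 0.8) or (1,)
        summ = make_summaries(th, sv, th2, sv2, selected)
        sel = SelectionResult(rule="independent", selected=selected,
                              bounds={j: (-math.inf, math.inf)
                                      for j in selected})
        return summ, sel

    def test_sign_antisymmetry(self, rng):
        from enrichsurv.interval_estimation import _negate

        d = design_ns()
        for _ in range(10):
            summ, sel = self._random_case(rng)
            dual = duality_intervals(summ, sel, d)
            flipped = duality_intervals(_negate(summ), sel, d)
            for j in sel.selected:
                assert flipped[j].lower == pytest.approx(-dual[j].upper,
                                                         abs=1e-9)
                assert flipped[j].upper == pytest.approx(-dual[j].lower,
                                                         abs=1e-9)

    def test_ordered_when_informative(self, rng):
        d = design_ns()
        for _ in range(10):
            summ, sel = self._random_case(rng)
            for j, di in duality_intervals(summ, sel, d).items():
                if di.lower_informative and di.upper_informative:
                    assert di.lower <= di.upper

    def test_exact_normal_simultaneous_coverage(self):
        """K=2, independent rule, exact normal model under the global null:
        simultaneous coverage is at least 1 - alpha (within MC error) and
        the tail error stays below alpha/2."""
        rng = np.random.default_rng(911)
        d = design_ns()
        theta = np.zeros(2)
        s1v = s2v = 0.02
        n_rep, covered, tail, n_done = 20_000, 0, 0, 0
        for _ in range(n_rep):
            th1 = rng.normal(theta, math.sqrt(s1v))
            th2 = rng.normal(theta, math.sqrt(s2v))
            selected = tuple(j + 1 for j in range(2) if th1[j] <= 0.0)
            if not selected:
                continue
            summ = make_summaries(th1, [s1v] * 2, th2, [s2v] * 2, selected)
            sel = SelectionResult(rule="independent", selected=selected,
                                  bounds={j: (-math.inf, 0.0)
                                          for j in selected})
            dual = duality_intervals(summ, sel, d)
            n_done += 1
            covered += all(di.lower <= 0.0 <= di.upper
                           for di in dual.values())
            tail += any(di.upper < 0.0 for di in dual.values())
        cov = covered / n_done
        se = math.sqrt(0.95 * 0.05 / n_done)
        assert cov >= 0.95 - 3 * se
        assert tail / n_done <= 0.025
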