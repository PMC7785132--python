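"""Naive and duality (closed-testing) confidence intervals.

Naive intervals split the two-sided level alpha equally across the |S|
selected partitions: ``theta_N +/- z_{alpha/(2|S|)} sigma_N``.

The duality intervals invert the trial's confirmatory test.  Evidence
against an intersection hypothesis ``H_I`` is summarised per stage by a
Sidak-adjusted p-value ``1 - (1 - min_i p_{k,i})^{|I|}`` (independent
partitions), the stages are combined with the weighted inverse-normal
function

    C(p1, p2) = 1 - Phi(w1 * Phi^-1(1-p1) + w2 * Phi^-1(1-p2)),

and the closure principle rejects an elementary hypothesis H_j iff every
intersection containing j is rejected at level alpha/2.  Stage-1 p-values
use the stage-1 patients followed to t~1 (dropped partitions at t1 unless
kept on follow-up); stage-2 p-values use the stage-2 patients only, so the
two stages are independent.  A confidence bound for theta_j is the
supremum of shifts v for which the shifted-null test still accepts; upper
bounds follow by applying the lower-bound machinery to the sign-flipped
data.  When the elementary conclusions are mixed, bounds for the rejected
partitions collapse to 0 regardless of the data — these are flagged
non-informative.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Dict, FrozenSet, Sequence, Tuple

from scipy.optimize import brentq
from scipy.special import ndtri

from .score_stats import PartitionSummaries, ScoreSummary

if TYPE_CHECKING:  # pragma: no cover
    from .selection import SelectionResult

__all__ = [
    "naive_ci",
    "sidak",
    "combine_p",
    "closed_test",
    "pM_plus",
    "lower_bound_all_rejected",
    "lower_bound_mixed",
    "duality_intervals",
    "HypothesisGrid",
    "DualityInterval",
]

_P_EPS = 1e-15
_SQRT2 = math.sqrt(2.0)
_MAX_K = 15


def _Phi(x: float) -> float:
    return 0.5 * math.erfc(-x / _SQRT2)


def naive_ci(thetaN: float, sigma2_N: float, alpha: float,
             n_selected: int) -> Tuple[float, float]:
    """Two-sided interval with alpha split equally over the selected partitions."""
    if n_selected < 1:
        raise ValueError("n_selected must be >= 1")
    z = float(ndtri(1.0 - alpha / (2.0 * n_selected)))
    half = z * math.sqrt(sigma2_N)
    return thetaN - half, thetaN + half


def sidak(p_values: Sequence[float], m: int) -> float:
    """Sidak-adjusted intersection p-value ``1 - (1 - min p)^m``."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return 1.0 - (1.0 - min(p_values)) ** m


def combine_p(p1: float, p2: float, weights: Tuple[float, float],
              eps: float = _P_EPS) -> float:
    """Weighted inverse-normal combination of two stagewise p-values."""
    w1, w2 = weights
    if abs(w1 * w1 + w2 * w2 - 1.0) > 1e-9:
        raise ValueError("weights must satisfy w1^2 + w2^2 = 1")
    if p1 <= eps and p2 <= eps:
        return 0.0
    if p1 >= 1.0 - eps and p2 >= 1.0 - eps:
        return 1.0
    p1 = min(max(p1, eps), 1.0 - eps)
    p2 = min(max(p2, eps), 1.0 - eps)
    z = w1 * float(ndtri(1.0 - p1)) + w2 * float(ndtri(1.0 - p2))
    return 1.0 - _Phi(z)


def _pairwise_p(summary: ScoreSummary, v: float = 0.0) -> float:
    """One-sided p-value for theta = v against theta > v."""
    return 1.0 - _Phi((summary.theta - v) / math.sqrt(summary.sigma2))


@dataclass(frozen=True)
class HypothesisGrid:
    """Closed-test results over every nonempty subset of partitions."""

    direction: str                                   # 'greater' or 'less'
    alpha: float
    subsets: Dict[FrozenSet[int], Tuple[float, float, float]]  # (p1, p2, C)
    p1_pairwise: Dict[int, float]
    p2_pairwise: Dict[int, float]                    # selected partitions only
    adjusted: Dict[int, float]                       # max C over I containing j
    rejected: Dict[int, bool]

    @property
    def all_selected_rejected(self) -> bool:
        return all(self.rejected[j] for j in self.p2_pairwise)


def closed_test(summaries: PartitionSummaries, selection: "SelectionResult",
                design, direction: str = "greater") -> HypothesisGrid:
    """Closure-principle test of every H_j at one-sided level alpha/2.

    ``direction='greater'`` tests against theta_j > 0 (sign conventions as
    in the score module); ``direction='less'`` flips every estimate's sign
    first.
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    K = summaries.K
    if K > _MAX_K:
        raise ValueError(f"subset enumeration limited to K <= {_MAX_K}")
    sign = 1.0 if direction == "greater" else -1.0
    sel = set(selection.selected)
    p1 = {}
    for j in range(1, K + 1):
        s = summaries.require("stage1_tilde", j)
        p1[j] = 1.0 - _Phi(sign * s.theta / math.sqrt(s.sigma2))
    p2 = {}
    for j in sel:
        s = summaries.require("stage2", j)
        p2[j] = 1.0 - _Phi(sign * s.theta / math.sqrt(s.sigma2))
    weights = design.weights
    alpha = design.alpha
    subsets: Dict[FrozenSet[int], Tuple[float, float, float]] = {}
    adjusted = {j: 0.0 for j in range(1, K + 1)}
    for r in range(1, K + 1):
        for combo in itertools.combinations(range(1, K + 1), r):
            I = frozenset(combo)
            p1I = sidak([p1[i] for i in I], len(I))
            I2 = I & sel
            p2I = sidak([p2[i] for i in I2], len(I2)) if I2 else 1.0
            C = combine_p(p1I, p2I, weights)
            subsets[I] = (p1I, p2I, C)
            for j in I:
                if C > adjusted[j]:
                    adjusted[j] = C
    rejected = {j: adjusted[j] <= alpha / 2.0 for j in adjusted}
    return HypothesisGrid(direction=direction, alpha=alpha, subsets=subsets,
                          p1_pairwise=p1, p2_pairwise=p2,
                          adjusted=adjusted, rejected=rejected)


def pM_plus(stage1_pairwise: Dict[int, float],
            selection: "SelectionResult") -> float:
    """Largest stage-1 intersection p-value over the dropped partitions.

    Zero when every partition was selected.
    """
    dropped = sorted(set(stage1_pairwise) - set(selection.selected))
    best = 0.0
    for r in range(1, len(dropped) + 1):
        for combo in itertools.combinations(dropped, r):
            val = sidak([stage1_pairwise[i] for i in combo], r)
            if val > best:
                best = val
    return best


def _sup_shift(f, center: float, scale: float, level: float) -> float:
    """sup{v : f(v) <= level} for a nondecreasing f, by bracketed root finding.

    Returns +inf when even a shift 20 scales above the centre still passes
    (the constraint is non-binding); raises if no bracket exists within
    +/- 20 scales.
    """
    lo, hi = center - 10.0 * scale, center + 10.0 * scale
    if f(hi) <= level:
        hi = center + 20.0 * scale
        if f(hi) <= level:
            return math.inf
    if f(lo) > level:
        lo = center - 20.0 * scale
        if f(lo) > level:
            raise RuntimeError("could not bracket the confidence bound "
                               "within 20 standard errors")
    return float(brentq(lambda v: f(v) - level, lo, hi, xtol=1e-6))


def lower_bound_all_rejected(j: int, summaries: PartitionSummaries,
                             selection: "SelectionResult", design,
                             pM: float) -> float:
    """Lower bound for theta_j when every selected partition's H was rejected.

    Inverts the elementary shifted-null test
    ``C(max{pM, 1-(1-p1_j(v))^K}, 1-(1-p2_j(v))^{|S|}) <= alpha/2`` and
    clips at zero (the rejection already establishes theta_j > 0).
    """
    K = summaries.K
    nsel = selection.n_selected
    s1 = summaries.require("stage1_tilde", j)
    s2 = summaries.require("stage2", j)
    weights, level = design.weights, design.alpha / 2.0

    def f(v: float) -> float:
        p1 = max(pM, 1.0 - (1.0 - _pairwise_p(s1, v)) ** K)
        p2 = 1.0 - (1.0 - _pairwise_p(s2, v)) ** nsel
        return combine_p(p1, p2, weights)

    sup = _sup_shift(f, s1.theta, math.sqrt(s1.sigma2), level)
    return max(0.0, sup)


def lower_bound_mixed(j: int, summaries: PartitionSummaries,
                      selection: "SelectionResult", design,
                      grid: HypothesisGrid) -> float:
    """Lower bound for theta_j when the elementary conclusions are mixed.

    For a rejected partition the bound is fixed at 0 (non-informative).
    Otherwise it is the smallest, over subsets I containing j, of the
    largest shift v of theta_j alone for which the shifted-null test of
    H_I still accepts; subsets rejected at the null contribute +inf.
    """
    if grid.rejected[j]:
        return 0.0
    K = summaries.K
    sel = set(selection.selected)
    s1j = summaries.require("stage1_tilde", j)
    scale = math.sqrt(s1j.sigma2)
    s2j = summaries.require("stage2", j) if j in sel else None
    weights, level = design.weights, design.alpha / 2.0
    best = math.inf
    for I, (_, _, C0) in grid.subsets.items():
        if j not in I or C0 < level:
            continue
        others1 = [grid.p1_pairwise[i] for i in I if i != j]
        I2 = I & sel
        others2 = [grid.p2_pairwise[i] for i in I2 if i != j]

        def f(v: float, others1=others1, others2=others2, I=I, I2=I2) -> float:
            p1min = min(others1 + [_pairwise_p(s1j, v)])
            p1I = 1.0 - (1.0 - p1min) ** len(I)
            if I2:
                vals = list(others2)
                if s2j is not None and j in I2:
                    vals.append(_pairwise_p(s2j, v))
                p2I = 1.0 - (1.0 - min(vals)) ** len(I2)
            else:
                p2I = 1.0
            return combine_p(p1I, p2I, weights)

        bound = _sup_shift(f, s1j.theta, scale, level)
        if bound < best:
            best = bound
    return best


@dataclass(frozen=True)
class DualityInterval:
    """Simultaneous test-inversion interval with informativeness flags."""

    lower: float
    upper: float
    lower_informative: bool = True
    upper_informative: bool = True


def _negate(summaries: PartitionSummaries) -> PartitionSummaries:
    def flip(block):
        return [None if s is None else ScoreSummary(S=-s.S, V=s.V) for s in block]

    return PartitionSummaries(K=summaries.K,
                              stage1=flip(summaries.stage1),
                              stage1_tilde=flip(summaries.stage1_tilde),
                              combined=flip(summaries.combined),
                              increment=flip(summaries.increment),
                              stage2=flip(summaries.stage2))


def _one_sided_lower(summaries: PartitionSummaries, selection: "SelectionResult",
                     design) -> Dict[int, Tuple[float, bool]]:
    """Lower bounds (value, informative) in the 'greater' orientation."""
    grid = closed_test(summaries, selection, design, "greater")
    out: Dict[int, Tuple[float, bool]] = {}
    if grid.all_selected_rejected:
        pM = pM_plus(grid.p1_pairwise, selection)
        for j in selection.selected:
            out[j] = (lower_bound_all_rejected(j, summaries, selection,
                                               design, pM), True)
    else:
        for j in selection.selected:
            if grid.rejected[j]:
                out[j] = (0.0, False)
            else:
                out[j] = (lower_bound_mixed(j, summaries, selection,
                                            design, grid), True)
    return out


def duality_intervals(summaries: PartitionSummaries,
                      selection: "SelectionResult",
                      design) -> Dict[int, DualityInterval]:
    """Simultaneous confidence intervals for every selected partition.

    Lower bounds come from the 'greater'-direction machinery; upper bounds
    from the same machinery applied to the sign-flipped summaries,
    negated back (theta_U = -delta_L with delta = -theta).
    """
    if selection.stopped:
        raise ValueError("trial stopped at interim; no intervals")
    lower = _one_sided_lower(summaries, selection, design)
    upper_neg = _one_sided_lower(_negate(summaries), selection, design)
    out = {}
    for j in selection.selected:
        lo, lo_inf = lower[j]
        dl, up_inf = upper_neg[j]
        out[j] = DualityInterval(lower=lo, upper=-dl,
                                 lower_informative=lo_inf,
                                 upper_informative=up_inf)
    return out
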