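"""Interim subpopulation-selection rules and their truncation bounds.

Two rules are implemented.

* ``adaptive_threshold`` — for a biomarker with a presumed monotone
  effect, the partitions are ordered and the trial continues with the
  largest prefix ``{1..s}`` whose prevalence-weighted mean stage-1 log
  hazard ratio is at most the futility threshold ``b``; ``s = 0`` stops
  the trial.
* ``independent`` — each partition continues iff its own stage-1 estimate
  is at most ``b``.

For each selected partition ``j`` the rule also determines the truncation
interval ``(l_j, w_j)``: the set of values the stage-1 estimate for ``j``
could have taken, holding the other partitions' estimates fixed, without
changing the selection.  These bounds drive the conditionally unbiased
point estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np

__all__ = [
    "SelectionResult",
    "select_adaptive_threshold",
    "select_independent",
    "bounds_adaptive",
    "bounds_independent",
    "apply_selection",
    "RULES",
]

RULES = ("adaptive_threshold", "independent")


@dataclass(frozen=True)
class SelectionResult:
    """Rule, selected index set and per-partition truncation bounds."""

    rule: str
    selected: Tuple[int, ...]
    bounds: Dict[int, Tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ValueError(f"unknown selection rule {self.rule!r}")
        object.__setattr__(self, "selected", tuple(sorted(self.selected)))
        for j in self.bounds:
            if j not in self.selected:
                raise ValueError(f"bounds given for unselected partition {j}")

    @property
    def stopped(self) -> bool:
        return len(self.selected) == 0

    @property
    def n_selected(self) -> int:
        return len(self.selected)


def select_adaptive_threshold(theta1: Sequence[float],
                              prevalences: Sequence[float],
                              b: float) -> int:
    """Largest ``s`` with prefix-weighted mean estimate at most ``b`` (0 = stop)."""
    theta1 = np.asarray(theta1, dtype=float)
    p = np.asarray(prevalences, dtype=float)
    if theta1.shape != p.shape:
        raise ValueError("theta1 and prevalences must have equal length")
    num = np.cumsum(p * theta1)
    den = np.cumsum(p)
    ok = np.nonzero(num / den <= b)[0]
    return int(ok[-1] + 1) if ok.size else 0


def select_independent(theta1: Sequence[float], b: float) -> Tuple[int, ...]:
    """Partitions whose own stage-1 estimate is at most ``b``."""
    theta1 = np.asarray(theta1, dtype=float)
    return tuple(int(j + 1) for j in np.nonzero(theta1 <= b)[0])


def bounds_adaptive(theta1: Sequence[float], prevalences: Sequence[float],
                    b: float, s: int, j: int) -> Tuple[float, float]:
    """Truncation interval for partition ``j`` under the prefix rule.

    ``w_j = (p'_s b - sum_{i<=s, i!=j} p_i theta_i) / p_j`` and
    ``l_j = max_{m=s+1..K} (p'_m b - sum_{i<=m, i!=j} p_i theta_i) / p_j``
    (``-inf`` when all partitions are selected).  Any substituted value of
    the stage-1 estimate inside ``(l_j, w_j]`` reproduces the same
    selection; values outside change it.
    """
    theta1 = np.asarray(theta1, dtype=float)
    p = np.asarray(prevalences, dtype=float)
    K = theta1.size
    if not (1 <= s <= K):
        raise ValueError("s must be in 1..K")
    if not (1 <= j <= s):
        raise ValueError("j must be a selected (prefix) partition")
    jj = j - 1
    weighted = p * theta1

    def edge(m: int) -> float:
        # (p'_m * b - sum_{i<=m, i!=j} p_i theta_i) / p_j
        total = weighted[:m].sum() - weighted[jj]
        return (p[:m].sum() * b - total) / p[jj]

    w = edge(s)
    if s == K:
        l = -math.inf
    else:
        l = max(edge(m) for m in range(s + 1, K + 1))
    return l, w


def bounds_independent(b: float) -> Tuple[float, float]:
    """Truncation interval under independent selection: ``(-inf, b)``."""
    return -math.inf, b


def apply_selection(theta1: Sequence[float], design) -> SelectionResult:
    """Run the design's rule on the stage-1 estimates and attach bounds."""
    theta1 = np.asarray(theta1, dtype=float)
    if theta1.size != design.K:
        raise ValueError("theta1 must have one entry per partition")
    if design.rule == "adaptive_threshold":
        s = select_adaptive_threshold(theta1, design.prevalences,
                                      design.futility_threshold)
        selected = tuple(range(1, s + 1))
        bounds = {j: bounds_adaptive(theta1, design.prevalences,
                                     design.futility_threshold, s, j)
                  for j in selected}
    elif design.rule == "independent":
        selected = select_independent(theta1, design.futility_threshold)
        bounds = {j: bounds_independent(design.futility_threshold)
                  for j in selected}
    else:  # pragma: no cover - guarded by TrialDesign validation
        raise ValueError(f"unknown selection rule {design.rule!r}")
    return SelectionResult(rule=design.rule, selected=selected, bounds=bounds)
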