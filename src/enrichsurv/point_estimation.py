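"""Naive and conditionally unbiased (UMVCUE) point estimation.

The naive estimator ``theta_N`` is the inverse-variance combination of the
interim estimate ``theta_1`` and the post-interim increment ``theta_2``;
it ignores the fact that the partition was selected because ``theta_1``
looked favourable and is therefore biased.

The UMVCUE is the Rao-Blackwell estimator
``E[theta_2 | theta_N, selection]``.  Conditional on the complete
sufficient statistic ``theta_N``, the interim estimate is normal,

    theta_1 | theta_N  ~  N(theta_N, s^2),   s = sigma1^2 / sqrt(sigma1^2 + sigma2^2),

free of the unknown log hazard ratio, and the selection event confines it
to the truncation interval ``(l, w)``.  Writing ``m`` for the mean of that
truncated normal, the estimator is

    theta_U = theta_N - (sigma2^2 / sigma1^2) * (m - theta_N)
            = theta_N - sigma2^2 / sqrt(sigma1^2 + sigma2^2)
                      * [phi(g(l)) - phi(g(w))] / [Phi(g(l)) - Phi(g(w))],

with ``g(x) = sqrt(sigma1^2 + sigma2^2) / sigma1^2 * (theta_N - x)``.
With no truncation the correction vanishes and ``theta_U = theta_N``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING, Dict, Union

import numpy as np
from scipy.stats import truncnorm

if TYPE_CHECKING:  # pragma: no cover
    from .score_stats import PartitionSummaries
    from .selection import SelectionResult

__all__ = ["umvcue", "point_estimates", "PointEstimates"]

ArrayLike = Union[float, np.ndarray]


def umvcue(thetaN: ArrayLike, sigma2_1: ArrayLike, sigma2_2: ArrayLike,
           l: ArrayLike = -math.inf, w: ArrayLike = math.inf) -> ArrayLike:
    """Conditionally unbiased estimate of the log hazard ratio.

    Parameters
    ----------
    thetaN : naive (combined) estimate.
    sigma2_1, sigma2_2 : variances of the interim estimate and of the
        post-interim increment (both positive).
    l, w : truncation bounds on the interim estimate implied by the
        selection; ``-inf`` / ``+inf`` encode one-sided or absent
        truncation.  Requires ``l < w``.

    All arguments broadcast; returns a float for scalar input.  If the
    truncated-normal mass is numerically degenerate the naive estimate is
    returned for the affected entries with a warning.
    """
    thetaN, s1, s2, l, w = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (thetaN, sigma2_1, sigma2_2, l, w)))
    if np.any(s1 <= 0) or np.any(s2 <= 0):
        raise ValueError("variances must be positive")
    if np.any(l >= w):
        raise ValueError("require l < w")
    s_cond = s1 / np.sqrt(s1 + s2)
    a = (l - thetaN) / s_cond
    b = (w - thetaN) / s_cond
    # mean shift of a standard normal truncated to (a, b)
    with np.errstate(all="ignore"):
        shift = truncnorm.mean(a, b)
    shift = np.where((a == -np.inf) & (b == np.inf), 0.0, shift)
    out = thetaN - (s2 / s1) * s_cond * shift
    bad = ~np.isfinite(out)
    if np.any(bad):
        warnings.warn("degenerate truncation region; returning naive estimate",
                      RuntimeWarning, stacklevel=2)
        out = np.where(bad, thetaN, out)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class PointEstimates:
    """Per-selected-partition naive and bias-adjusted estimates."""

    naive: Dict[int, float]
    umvcue: Dict[int, float]

    @property
    def correction(self) -> Dict[int, float]:
        return {j: self.umvcue[j] - self.naive[j] for j in self.naive}


def point_estimates(summaries: "PartitionSummaries",
                    selection: "SelectionResult") -> PointEstimates:
    """Naive and UMVCUE estimates for every selected partition."""
    if selection.stopped:
        raise ValueError("trial stopped at interim; no estimates")
    naive: Dict[int, float] = {}
    adjusted: Dict[int, float] = {}
    for j in selection.selected:
        comb = summaries.require("combined", j)
        s1 = summaries.require("stage1", j)
        inc = summaries.require("increment", j)
        l, w = selection.bounds[j]
        naive[j] = comb.theta
        adjusted[j] = umvcue(comb.theta, s1.sigma2, inc.sigma2, l, w)
    return PointEstimates(naive=naive, umvcue=adjusted)
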