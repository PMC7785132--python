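"""Log-rank score statistics, Fisher information and stagewise decompositions.

Inference throughout the package is based on the asymptotic distribution of
the log-rank score statistic: for partition ``j`` the score ``S`` computed
from a snapshot of the data is approximately ``N(theta_j * V, V)`` where
``V`` is the Fisher information, so ``theta_hat = S / V`` estimates the log
hazard ratio with variance ``1 / V``.  The sign convention is that a
positive score corresponds to an excess of events on the experimental arm,
i.e. ``theta_hat > 0`` means the experimental treatment is worse and
``theta_hat < 0`` means it delays the event.

Repeated looks at accruing survival data have the independent-increments
property: the score accumulated after an interim analysis, ``S_N - S_1``,
is asymptotically independent of the interim score ``S_1`` with mean
``theta * (V_N - V_1)``.  This module forms interim, incremental and pooled
summaries for every partition of a two-stage enrichment trial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Optional, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - annotations only
    from .data_io import AnalysisTimes, SubjectRecord, TrialDesign
    from .selection import SelectionResult

__all__ = [
    "ScoreSummary",
    "Snapshot",
    "PartitionSummaries",
    "censor_at",
    "logrank_summary",
    "logrank_score",
    "increment_summary",
    "combine_estimates",
    "all_summaries",
    "stage1_summaries",
]


class InsufficientDataError(ValueError):
    """Raised when a snapshot carries no usable log-rank information."""


@dataclass(frozen=True)
class ScoreSummary:
    """A (score, information) pair for one partition and one analysis set.

    Attributes
    ----------
    S : float
        Log-rank score statistic (observed minus expected experimental
        events).
    V : float
        Fisher information (hypergeometric variance of the score).
    """

    S: float
    V: float

    def __post_init__(self) -> None:
        if not (self.V > 0.0) or not math.isfinite(self.V):
            raise ValueError(f"information must be positive, got V={self.V}")
        if not math.isfinite(self.S):
            raise ValueError(f"score must be finite, got S={self.S}")

    @property
    def theta(self) -> float:
        """Log hazard ratio estimate ``S / V``."""
        return self.S / self.V

    @property
    def sigma2(self) -> float:
        """Variance of the estimate, ``1 / V``."""
        return 1.0 / self.V

    @classmethod
    def from_estimate(cls, theta: float, sigma2: float) -> "ScoreSummary":
        """Build a summary from an estimate and its variance (``V = 1/sigma2``)."""
        if not (sigma2 > 0.0):
            raise ValueError(f"variance must be positive, got {sigma2}")
        return cls(S=theta / sigma2, V=1.0 / sigma2)


@dataclass(frozen=True)
class Snapshot:
    """Survival data for one partition frozen at a calendar analysis time."""

    time: np.ndarray      # observed time on study, days
    status: np.ndarray    # 1 = event by the analysis time, 0 = censored
    arm: np.ndarray       # True = experimental

    def __post_init__(self) -> None:
        for name in ("time", "status", "arm"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        if self.time.size and self.time.min() < 0:
            raise ValueError("negative observed time in snapshot")

    @property
    def n(self) -> int:
        return int(self.time.size)

    @property
    def n_events(self) -> int:
        return int(np.count_nonzero(self.status))


@dataclass
class PartitionSummaries:
    """All stagewise score summaries of a two-stage enrichment trial.

    Entries are ``None`` where a summary is undefined (for example the
    stage-2 summaries of a dropped partition).  Lists are indexed by
    partition - 1.

    ``stage1``        stage-1 patients at the interim time t1 (all partitions)
    ``stage1_tilde``  stage-1 patients at t~1 for selected partitions; at t1
                      (or t~1, if dropped patients stay on follow-up) for
                      dropped partitions
    ``combined``      stage-1 patients at t~1 pooled with stage-2 patients at
                      t2, a single log-rank analysis (theta_N)
    ``increment``     combined minus stage-1-at-t1 (theta_2)
    ``stage2``        stage-2 patients at t2 analysed separately
    """

    K: int
    stage1: Sequence[Optional[ScoreSummary]]
    stage1_tilde: Sequence[Optional[ScoreSummary]] = None
    combined: Sequence[Optional[ScoreSummary]] = None
    increment: Sequence[Optional[ScoreSummary]] = None
    stage2: Sequence[Optional[ScoreSummary]] = None

    def __post_init__(self) -> None:
        for name in ("stage1", "stage1_tilde", "combined", "increment", "stage2"):
            val = getattr(self, name)
            if val is None:
                val = [None] * self.K
            val = list(val)
            if len(val) != self.K:
                raise ValueError(f"{name} must have one entry per partition")
            setattr(self, name, val)

    def get(self, block: str, j: int) -> Optional[ScoreSummary]:
        """Summary of ``block`` for 1-based partition ``j`` (or None)."""
        return getattr(self, block)[j - 1]

    def require(self, block: str, j: int) -> ScoreSummary:
        s = self.get(block, j)
        if s is None:
            raise ValueError(f"missing {block!r} summary for partition {j}")
        return s

    @property
    def theta1(self) -> np.ndarray:
        """Vector of stage-1 estimates at t1 (selection input)."""
        return np.array([self.require("stage1", j).theta for j in range(1, self.K + 1)])


def censor_at(records: Iterable["SubjectRecord"], analysis_day: float,
              partition: int) -> Snapshot:
    """Snapshot of one partition's data administratively censored at a calendar day.

    Subjects entering after ``analysis_day`` are excluded (not counted as
    censored at zero).  Observed time is
    ``min(event_day, last_followup_day, analysis_day) - entry_day`` and the
    status is 1 iff the event occurred by that minimum.
    """
    if analysis_day < 0:
        raise ValueError("analysis_day must be non-negative")
    times, status, arm = [], [], []
    for r in records:
        if r.partition != partition or r.entry_day > analysis_day:
            continue
        event = r.event_day if r.event_day is not None else math.inf
        horizon = min(r.last_followup_day, analysis_day)
        times.append(min(event, horizon) - r.entry_day)
        status.append(1 if event <= horizon else 0)
        arm.append(r.arm == "experimental")
    return Snapshot(np.asarray(times, dtype=float),
                    np.asarray(status, dtype=np.int8),
                    np.asarray(arm, dtype=bool))


def logrank_score(time: np.ndarray, status: np.ndarray,
                  arm: np.ndarray) -> tuple[float, float]:
    """Raw log-rank score and information for arrays (no validity checks).

    ``S = sum_t (dE - d * nE/n)`` over distinct event times and
    ``V = sum_t d * (nE/n) * (nC/n) * (n-d)/(n-1)`` with the tie factor
    ``(n-d)/(n-1)``; terms with a single subject at risk are skipped.
    A subject censored at an event time is still at risk at that time.
    """
    time = np.asarray(time, dtype=float)
    status = np.asarray(status, dtype=bool)
    arm = np.asarray(arm, dtype=bool)
    n = time.size
    if n == 0 or not status.any():
        return 0.0, 0.0
    order = np.argsort(time, kind="stable")
    t = time[order]
    d = status[order]
    e = arm[order]
    ut, inv, dcnt = np.unique(t[d], return_inverse=True, return_counts=True)
    dE = np.bincount(inv, weights=e[d].astype(float))
    idx = np.searchsorted(t, ut, side="left")
    n_at = (n - idx).astype(float)
    cum_e = np.concatenate(([0.0], np.cumsum(e)))
    nE = float(e.sum()) - cum_e[idx]
    frac = nE / n_at
    S = float(np.sum(dE - dcnt * frac))
    ok = n_at > 1
    V = float(np.sum(dcnt[ok] * frac[ok] * (1.0 - frac[ok])
                     * (n_at[ok] - dcnt[ok]) / (n_at[ok] - 1.0)))
    return S, V


def logrank_summary(snapshot: Snapshot) -> ScoreSummary:
    """Log-rank (score, information) summary of a snapshot.

    Raises
    ------
    InsufficientDataError
        If the snapshot has no events, or both arms are never simultaneously
        at risk at an event time (``V = 0``).
    """
    if snapshot.n_events == 0:
        raise InsufficientDataError("snapshot has no events")
    S, V = logrank_score(snapshot.time, snapshot.status, snapshot.arm)
    if V <= 0.0:
        raise InsufficientDataError("insufficient events/information (V = 0)")
    return ScoreSummary(S=S, V=V)


def increment_summary(full: ScoreSummary, stage1: ScoreSummary) -> ScoreSummary:
    """Post-interim increment ``(S_N - S_1, V_N - V_1)``.

    By the independent-increments property this behaves like an independent
    log-rank summary with estimate ``theta_2 = (S_N - S_1) / (V_N - V_1)``.
    """
    if full.V <= stage1.V:
        raise InsufficientDataError("no incremental information (V_N <= V_1)")
    return ScoreSummary(S=full.S - stage1.S, V=full.V - stage1.V)


def combine_estimates(theta1: float, sigma2_1: float,
                      theta2: float, sigma2_2: float) -> tuple[float, float]:
    """Inverse-variance combination of the interim and incremental estimates.

    Returns ``theta_N = (s2*theta1 + s1*theta2)/(s1+s2)`` and
    ``sigma2_N = s1*s2/(s1+s2)``; identical to the pooled estimate
    ``S_N / V_N`` when the inputs come from the same score decomposition.
    """
    if not (sigma2_1 > 0 and sigma2_2 > 0):
        raise ValueError("variances must be positive")
    tot = sigma2_1 + sigma2_2
    theta_n = (sigma2_2 * theta1 + sigma2_1 * theta2) / tot
    sigma2_n = sigma2_1 * sigma2_2 / tot
    return theta_n, sigma2_n


def stage1_summaries(records: Iterable["SubjectRecord"], design: "TrialDesign",
                     t1: float) -> list[ScoreSummary]:
    """Interim log-rank summaries at t1 for every partition."""
    records = list(records)
    return [logrank_summary(censor_at(records, t1, j))
            for j in range(1, design.K + 1)]


def all_summaries(records: Iterable["SubjectRecord"], design: "TrialDesign",
                  times: "AnalysisTimes",
                  selection: "SelectionResult") -> PartitionSummaries:
    """Assemble every stagewise summary needed for estimation and testing.

    For each partition: the stage-1 summary at t1.  For selected partitions
    additionally: the stage-1 summary at t~1, the pooled (combined) summary
    of stage-1 patients at t~1 with stage-2 patients at t2, the increment,
    and the stage-2-only summary.  Dropped partitions get their t~1 summary
    at t1 unless the design keeps dropped patients on follow-up.
    """
    records = list(records)
    K = design.K
    selected = set(selection.selected)
    stage1 = [None] * K
    tilde = [None] * K
    combined = [None] * K
    increment = [None] * K
    stage2 = [None] * K
    for j in range(1, K + 1):
        s1_records = [r for r in records if r.entry_day <= times.t1]
        stage1[j - 1] = logrank_summary(censor_at(s1_records, times.t1, j))
        if j in selected:
            snap_tilde = censor_at(s1_records, times.t_tilde1, j)
            tilde[j - 1] = logrank_summary(snap_tilde)
            s2_records = [r for r in records if r.entry_day > times.t1]
            snap_s2 = censor_at(s2_records, times.t2, j)
            stage2[j - 1] = logrank_summary(snap_s2)
            pooled = Snapshot(
                np.concatenate([snap_tilde.time, snap_s2.time]),
                np.concatenate([snap_tilde.status, snap_s2.status]),
                np.concatenate([snap_tilde.arm, snap_s2.arm]),
            )
            combined[j - 1] = logrank_summary(pooled)
            increment[j - 1] = increment_summary(combined[j - 1], stage1[j - 1])
        else:
            day = times.t_tilde1 if design.dropped_followed_to_tilde else times.t1
            tilde[j - 1] = logrank_summary(censor_at(s1_records, day, j))
    return PartitionSummaries(K=K, stage1=stage1, stage1_tilde=tilde,
                              combined=combined, increment=increment,
                              stage2=stage2)
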