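"""End-to-end estimation: selection, point estimates and intervals.

Two entry points mirror the two input paths: subject-level records (the
analysis times are derived from the design's prespecified event counts)
and per-partition summary statistics (analysis times are not needed; the
provided summaries are used directly).
"""

from __future__ import annotations

from typing import Iterable, Optional

from . import score_stats
from .data_io import (AnalysisTimes, EstimateReport, PartitionEstimate,
                      SubjectRecord, TrialDesign)
from .interval_estimation import closed_test, duality_intervals, naive_ci
from .point_estimation import umvcue
from .score_stats import PartitionSummaries, ScoreSummary
from .selection import apply_selection

__all__ = ["estimate_from_summaries", "estimate_from_subjects",
           "analysis_times_from_records"]

_STOP_MESSAGE = "stopped at interim; no estimates"


def analysis_times_from_records(records, design: TrialDesign) -> AnalysisTimes:
    """Derive (t1, t~1, t2) from the design's prespecified event counts.

    t1 is the calendar day of the ``interim_event_count``-th event; t2 the
    day of the ``stage2_event_count``-th event among post-interim
    enrollees; t~1 is t1 plus the prespecified offset.
    """
    events = sorted(r.event_day for r in records if r.event_day is not None)
    k1 = design.interim_event_count
    if len(events) < k1:
        raise ValueError(f"only {len(events)} events; interim requires {k1}")
    t1 = events[k1 - 1]
    stage2_events = sorted(r.event_day for r in records
                           if r.event_day is not None and r.entry_day > t1)
    k2 = design.stage2_event_count
    if len(stage2_events) < k2:
        raise ValueError(f"only {len(stage2_events)} stage-2 events; "
                         f"final analysis requires {k2}")
    t2 = stage2_events[k2 - 1]
    return AnalysisTimes(t1=t1, t_tilde1=t1 + design.tilde_offset_days, t2=t2)


def _duality_available(summaries: PartitionSummaries, selection) -> bool:
    have_tilde = all(summaries.get("stage1_tilde", j) is not None
                     for j in range(1, summaries.K + 1))
    have_s2 = all(summaries.get("stage2", j) is not None
                  for j in selection.selected)
    return have_tilde and have_s2


def build_report(summaries: PartitionSummaries, design: TrialDesign,
                 selection=None,
                 times: Optional[AnalysisTimes] = None) -> EstimateReport:
    """Assemble the full report from stagewise summaries.

    A missing combined summary is derived from the stage-1 and increment
    summaries by inverse-variance combination.  Duality intervals and
    adjusted p-values are included only when the required t~1 and
    stage-2-only summaries are all present.
    """
    if selection is None:
        selection = apply_selection(summaries.theta1, design)
    if selection.stopped:
        return EstimateReport(design=design, selection=selection, times=times,
                              message=_STOP_MESSAGE)
    with_duality = _duality_available(summaries, selection)
    duality = grid_g = grid_l = None
    if with_duality:
        duality = duality_intervals(summaries, selection, design)
        grid_g = closed_test(summaries, selection, design, "greater")
        grid_l = closed_test(summaries, selection, design, "less")
    estimates = {}
    for j in selection.selected:
        s1 = summaries.require("stage1", j)
        inc = summaries.get("increment", j)
        comb = summaries.get("combined", j)
        if comb is None:
            if inc is None:
                raise ValueError(f"partition {j}: need a combined or an "
                                 "increment summary")
            comb = ScoreSummary(S=s1.S + inc.S, V=s1.V + inc.V)
        if inc is None:
            inc = score_stats.increment_summary(comb, s1)
        l, w = selection.bounds[j]
        estimates[j] = PartitionEstimate(
            theta1=s1.theta, sigma2_1=s1.sigma2,
            thetaN=comb.theta, sigma2_N=comb.sigma2,
            theta2=inc.theta, sigma2_2=inc.sigma2,
            umvcue=umvcue(comb.theta, s1.sigma2, inc.sigma2, l, w),
            bounds=(l, w),
            naive_ci=naive_ci(comb.theta, comb.sigma2, design.alpha,
                              selection.n_selected),
            duality=None if duality is None else duality[j],
            adjusted_p_greater=None if grid_g is None else grid_g.adjusted[j],
            adjusted_p_less=None if grid_l is None else grid_l.adjusted[j])
    return EstimateReport(design=design, selection=selection, times=times,
                          estimates=estimates)


def estimate_from_summaries(summaries: PartitionSummaries,
                            design: TrialDesign) -> EstimateReport:
    """Run selection and estimation directly on summary statistics."""
    if summaries.K != design.K:
        raise ValueError(f"summaries have {summaries.K} partitions, "
                         f"design expects {design.K}")
    return build_report(summaries, design)


def estimate_from_subjects(records: Iterable[SubjectRecord],
                           design: TrialDesign) -> EstimateReport:
    """Full pipeline from subject-level records."""
    records = list(records)
    for r in records:
        r.validate(design.K)
    t1_only = sorted(r.event_day for r in records if r.event_day is not None)
    if len(t1_only) < design.interim_event_count:
        raise ValueError("not enough events for the interim analysis")
    t1 = t1_only[design.interim_event_count - 1]
    stage1 = score_stats.stage1_summaries(records, design, t1)
    theta1 = [s.theta for s in stage1]
    selection = apply_selection(theta1, design)
    if selection.stopped:
        return EstimateReport(design=design, selection=selection,
                              message=_STOP_MESSAGE)
    times = analysis_times_from_records(records, design)
    summaries = score_stats.all_summaries(records, design, times, selection)
    return build_report(summaries, design, selection=selection, times=times)
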