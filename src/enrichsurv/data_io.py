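"""Domain types and validated readers/writers.

Subject-level data are CSV with columns
``subject_id,partition,arm,entry_day,event_day,last_followup_day,status``
(calendar days since trial start, day 0; status 1 = event, 0 = censored;
partitions 1-based).  Summary-level inputs and estimate reports are
JSON/YAML keyed by the usual symbols (theta, sigma2 or the information V).
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd
import yaml

from .interval_estimation import DualityInterval
from .score_stats import PartitionSummaries, ScoreSummary
from .selection import RULES, SelectionResult

__all__ = [
    "SubjectRecord",
    "TrialDesign",
    "AnalysisTimes",
    "PartitionSummaries",
    "ScoreSummary",
    "PartitionEstimate",
    "EstimateReport",
    "read_subjects",
    "write_subjects",
    "read_summaries",
    "write_summaries",
    "read_design",
    "write_report",
    "read_report",
]

SUBJECT_COLUMNS = ["subject_id", "partition", "arm", "entry_day",
                   "event_day", "last_followup_day", "status"]
ARMS = ("control", "experimental")


@dataclass(frozen=True)
class SubjectRecord:
    """One enrolled patient, in calendar time (days since trial start)."""

    subject_id: str
    partition: int
    arm: str
    entry_day: float
    event_day: Optional[float]
    last_followup_day: float

    def validate(self, K: Optional[int] = None) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"subject {self.subject_id}: arm must be one of {ARMS}")
        if K is not None and not (1 <= self.partition <= K):
            raise ValueError(f"subject {self.subject_id}: partition out of range "
                             f"(got {self.partition}, K={K})")
        if self.entry_day < 0:
            raise ValueError(f"subject {self.subject_id}: negative entry_day")
        if self.event_day is not None and self.event_day < self.entry_day:
            raise ValueError(f"subject {self.subject_id}: event_day before entry_day")
        if self.last_followup_day < self.entry_day:
            raise ValueError(f"subject {self.subject_id}: last_followup_day "
                             "before entry_day")

    def stage(self, t1: float) -> int:
        """1 for interim (stage-1) enrollees, 2 for post-interim enrollees."""
        return 1 if self.entry_day <= t1 else 2


@dataclass(frozen=True)
class TrialDesign:
    """Prespecified configuration of the two-stage enrichment design."""

    K: int
    prevalences: Tuple[float, ...]
    futility_threshold: float
    rule: str = "adaptive_threshold"
    alpha: float = 0.05
    weights: Tuple[float, float] = (1.0 / math.sqrt(2.0), 1.0 / math.sqrt(2.0))
    interim_event_count: int = 300
    stage2_event_count: int = 300
    tilde_offset_days: float = 250.0
    dropped_followed_to_tilde: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "prevalences", tuple(float(p) for p in self.prevalences))
        object.__setattr__(self, "weights", tuple(float(w) for w in self.weights))
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if len(self.prevalences) != self.K:
            raise ValueError("need one prevalence per partition")
        if any(p <= 0 for p in self.prevalences):
            raise ValueError("prevalences must be positive")
        if abs(sum(self.prevalences) - 1.0) > 1e-9:
            raise ValueError("prevalences must sum to 1")
        if self.rule not in RULES:
            raise ValueError(f"rule must be one of {RULES}")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        w1, w2 = self.weights
        if w1 <= 0 or w2 <= 0:
            raise ValueError("weights must be positive")
        if abs(w1 * w1 + w2 * w2 - 1.0) > 1e-9:
            raise ValueError("weights must satisfy w1^2 + w2^2 = 1")
        if self.interim_event_count < 1 or self.stage2_event_count < 1:
            raise ValueError("event counts must be positive")
        if self.tilde_offset_days < 0:
            raise ValueError("tilde_offset_days must be non-negative")

    @classmethod
    def from_dict(cls, d: dict) -> "TrialDesign":
        d = dict(d)
        # accept the stagewise event shares (weights squared) as an
        # alternative weight convention
        if "event_shares" in d:
            s1, s2 = d.pop("event_shares")
            d["weights"] = (math.sqrt(s1), math.sqrt(s2))
        return cls(**d)

    def to_dict(self) -> dict:
        return {
            "K": self.K, "prevalences": list(self.prevalences),
            "futility_threshold": self.futility_threshold, "rule": self.rule,
            "alpha": self.alpha, "weights": list(self.weights),
            "interim_event_count": self.interim_event_count,
            "stage2_event_count": self.stage2_event_count,
            "tilde_offset_days": self.tilde_offset_days,
            "dropped_followed_to_tilde": self.dropped_followed_to_tilde,
        }

    def digest(self) -> str:
        """Short stable hash of the design, for run logs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass(frozen=True)
class AnalysisTimes:
    """Calendar analysis days: interim t1, extended follow-up t~1, final t2."""

    t1: float
    t_tilde1: float
    t2: float

    def __post_init__(self) -> None:
        if self.t_tilde1 < self.t1:
            raise ValueError("t_tilde1 must be >= t1")
        if self.t2 < self.t1:
            raise ValueError("t2 must be >= t1")
        if self.t_tilde1 > self.t2:
            warnings.warn("t_tilde1 exceeds t2: follow-up beyond the final "
                          "analysis is not used", UserWarning, stacklevel=2)


def read_design(path: Union[str, Path]) -> TrialDesign:
    """Read a TrialDesign from a YAML/JSON mapping."""
    with open(path) as fh:
        return TrialDesign.from_dict(yaml.safe_load(fh))


def read_subjects(path: Union[str, Path],
                  design: Optional[TrialDesign] = None) -> List[SubjectRecord]:
    """Read and validate subject-level CSV data."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"subject file missing columns: {missing}")
    K = design.K if design is not None else None
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        try:
            status = int(row.status)
            event = float(row.event_day) if status == 1 else None
            if status == 1 and math.isnan(event):
                raise ValueError("status 1 but event_day missing")
            rec = SubjectRecord(
                subject_id=str(row.subject_id), partition=int(row.partition),
                arm=str(row.arm), entry_day=float(row.entry_day),
                event_day=event, last_followup_day=float(row.last_followup_day))
            rec.validate(K)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}, line {i}: {exc}") from exc
        records.append(rec)
    return records


def write_subjects(records: Sequence[SubjectRecord], path: Union[str, Path]) -> None:
    """Write subject records as CSV (floats via repr: lossless round trip)."""
    with open(path, "w") as fh:
        fh.write(",".join(SUBJECT_COLUMNS) + "\n")
        for r in records:
            event = "" if r.event_day is None else repr(float(r.event_day))
            status = 0 if r.event_day is None else 1
            fh.write(f"{r.subject_id},{r.partition},{r.arm},"
                     f"{float(r.entry_day)!r},{event},"
                     f"{float(r.last_followup_day)!r},{status}\n")


_BLOCKS = ("stage1", "stage1_tilde", "combined", "increment", "stage2")
_BLOCK_KEYS = {  # accepted aliases in summary files
    "stage1": ("stage1", "theta1"),
    "stage1_tilde": ("stage1_tilde", "theta1_tilde"),
    "combined": ("combined", "thetaN"),
    "increment": ("increment", "theta2"),
    "stage2": ("stage2", "thetaS2"),
}


def _parse_block(d: dict, where: str) -> ScoreSummary:
    if "sigma2" in d:
        sigma2 = float(d["sigma2"])
        if sigma2 <= 0:
            raise ValueError(f"{where}: variance must be positive, got {sigma2}")
        return ScoreSummary.from_estimate(float(d["theta"]), sigma2)
    if "V" in d:
        V = float(d["V"])
        if V <= 0:
            raise ValueError(f"{where}: information must be positive, got {V}")
        return ScoreSummary.from_estimate(float(d["theta"]), 1.0 / V)
    raise ValueError(f"{where}: need 'sigma2' or 'V' alongside 'theta'")


def read_summaries(path: Union[str, Path]) -> PartitionSummaries:
    """Read per-partition summary statistics (the no-raw-data input path).

    Expected structure::

        partitions:
          - partition: 1
            stage1:   {theta: -0.902, sigma2: 0.191}
            combined: {theta: -0.746, sigma2: 0.089}
            increment: {theta: -0.609, sigma2: 0.167}

    ``V`` (information) may replace ``sigma2``.  Missing blocks are left
    absent, not treated as zero.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    parts = (doc or {}).get("partitions") or []
    if not parts:
        raise ValueError(f"{path}: no partitions in summary file")
    K = len(parts)
    blocks = {b: [None] * K for b in _BLOCKS}
    seen = set()
    for entry in parts:
        j = int(entry.get("partition", len(seen) + 1))
        if not (1 <= j <= K) or j in seen:
            raise ValueError(f"{path}: bad or duplicate partition index {j}")
        seen.add(j)
        for block, keys in _BLOCK_KEYS.items():
            for key in keys:
                if key in entry and entry[key] is not None:
                    blocks[block][j - 1] = _parse_block(
                        entry[key], f"{path} partition {j} {block}")
                    break
    if any(s is None for s in blocks["stage1"]):
        raise ValueError(f"{path}: every partition needs a stage1 block")
    return PartitionSummaries(K=K, **blocks)


def _block_dict(s: Optional[ScoreSummary]) -> Optional[dict]:
    return None if s is None else {"theta": s.theta, "sigma2": s.sigma2}


def write_summaries(summaries: PartitionSummaries, path: Union[str, Path]) -> None:
    parts = []
    for j in range(1, summaries.K + 1):
        entry = {"partition": j}
        for block in _BLOCKS:
            d = _block_dict(summaries.get(block, j))
            if d is not None:
                entry[block] = d
        parts.append(entry)
    with open(path, "w") as fh:
        json.dump({"partitions": parts}, fh, indent=1)


@dataclass(frozen=True)
class PartitionEstimate:
    """Everything reported for one selected partition."""

    theta1: float
    sigma2_1: float
    thetaN: float
    sigma2_N: float
    theta2: Optional[float]
    sigma2_2: Optional[float]
    umvcue: float
    bounds: Tuple[float, float]          # (l_j, w_j)
    naive_ci: Tuple[float, float]
    duality: Optional[DualityInterval] = None
    adjusted_p_greater: Optional[float] = None
    adjusted_p_less: Optional[float] = None


@dataclass
class EstimateReport:
    """Full analysis output for one trial (or futility-stop record)."""

    design: TrialDesign
    selection: SelectionResult
    times: Optional[AnalysisTimes] = None
    estimates: Dict[int, PartitionEstimate] = field(default_factory=dict)
    message: Optional[str] = None

    @property
    def stopped(self) -> bool:
        return self.selection.stopped

    def to_dict(self) -> dict:
        d = {
            "design": self.design.to_dict(),
            "selection": {
                "rule": self.selection.rule,
                "selected": list(self.selection.selected),
                "bounds": {str(j): list(b) for j, b in self.selection.bounds.items()},
            },
            "times": None if self.times is None else {
                "t1": self.times.t1, "t_tilde1": self.times.t_tilde1,
                "t2": self.times.t2},
            "estimates": {},
            "message": self.message,
        }
        for j, e in self.estimates.items():
            d["estimates"][str(j)] = {
                "theta1": e.theta1, "sigma2_1": e.sigma2_1,
                "thetaN": e.thetaN, "sigma2_N": e.sigma2_N,
                "theta2": e.theta2, "sigma2_2": e.sigma2_2,
                "umvcue": e.umvcue, "bounds": list(e.bounds),
                "naive_ci": list(e.naive_ci),
                "duality": None if e.duality is None else {
                    "lower": e.duality.lower, "upper": e.duality.upper,
                    "lower_informative": e.duality.lower_informative,
                    "upper_informative": e.duality.upper_informative},
                "adjusted_p_greater": e.adjusted_p_greater,
                "adjusted_p_less": e.adjusted_p_less,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EstimateReport":
        design = TrialDesign.from_dict(d["design"])
        sel = d["selection"]
        selection = SelectionResult(
            rule=sel["rule"], selected=tuple(sel["selected"]),
            bounds={int(j): tuple(b) for j, b in sel["bounds"].items()})
        times = None
        if d.get("times"):
            times = AnalysisTimes(**d["times"])
        estimates = {}
        for j, e in (d.get("estimates") or {}).items():
            dual = e.get("duality")
            estimates[int(j)] = PartitionEstimate(
                theta1=e["theta1"], sigma2_1=e["sigma2_1"],
                thetaN=e["thetaN"], sigma2_N=e["sigma2_N"],
                theta2=e["theta2"], sigma2_2=e["sigma2_2"],
                umvcue=e["umvcue"], bounds=tuple(e["bounds"]),
                naive_ci=tuple(e["naive_ci"]),
                duality=None if dual is None else DualityInterval(**dual),
                adjusted_p_greater=e.get("adjusted_p_greater"),
                adjusted_p_less=e.get("adjusted_p_less"))
        return cls(design=design, selection=selection, times=times,
                   estimates=estimates, message=d.get("message"))


def write_report(report: EstimateReport, path: Union[str, Path]) -> None:
    """Serialize a report as JSON (futility stops carry an explanatory message)."""
    d = report.to_dict()
    if report.stopped and not d["message"]:
        d["message"] = "stopped at interim; no estimates"
    with open(path, "w") as fh:
        json.dump(d, fh, indent=1)


def read_report(path: Union[str, Path]) -> EstimateReport:
    with open(path) as fh:
        return EstimateReport.from_dict(json.load(fh))
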