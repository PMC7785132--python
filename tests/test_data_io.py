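import json
import math

import pytest
from hypothesis import given, settings, strategies as st

from enrichsurv import (SubjectRecord, TrialDesign, estimate_from_summaries,
                        read_report, read_subjects, read_summaries,
                        write_report, write_subjects, write_summaries)
from enrichsurv.data_io import AnalysisTimes


def make_design(**kw):
    base = dict(K=2, prevalences=(0.2, 0.8), futility_threshold=0.0,
                rule="independent")
    base.update(kw)
    return TrialDesign(**base)


class TestTrialDesign:
    def test_prevalences_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            make_design(prevalences=(0.2, 0.7))

    def test_weights_must_be_normalized(self):
        with pytest.raises(ValueError, match="w1"):
            make_design(weights=(0.75, 0.25))

    def test_event_share_convention_accepted(self):
        d = TrialDesign.from_dict(dict(K=2, prevalences=[0.2, 0.8],
                                       futility_threshold=0.0,
                                       event_shares=[0.75, 0.25]))
        assert d.weights[0] == pytest.approx(math.sqrt(0.75))

    def test_round_trips_through_dict(self):
        d = make_design()
        assert TrialDesign.from_dict(d.to_dict()) == d

    def test_digest_stable(self):
        assert make_design().digest() == make_design().digest()


class TestAnalysisTimes:
    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            AnalysisTimes(t1=100, t_tilde1=50, t2=200)

    def test_tilde_beyond_final_warns(self):
        with pytest.warns(UserWarning):
            AnalysisTimes(t1=100, t_tilde1=300, t2=200)


SUBJECTS = [
    SubjectRecord("s1", 1, "control", 0.0, 120.5, 400.0),
    SubjectRecord("s2", 1, "experimental", 10.25, None, 380.0),
    SubjectRecord("s3", 2, "control", 33.125, None, 420.0),
    SubjectRecord("s4", 2, "experimental", 55.0, 60.0, 500.0),
]


class TestSubjectIO:
    def test_round_trip_identical(self, tmp_path):
        path = tmp_path / "subjects.csv"
        write_subjects(SUBJECTS, path)
        back = read_subjects(path, make_design())
        assert back == SUBJECTS
        # second pass is byte-stable
        path2 = tmp_path / "again.csv"
        write_subjects(back, path2)
        assert path.read_text() == path2.read_text()

    def test_event_before_entry_names_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        write_subjects(SUBJECTS, path)
        lines = path.read_text().splitlines()
        lines[1] = "s1,1,control,200.0,120.5,400.0,1"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="line 2.*event_day before"):
            read_subjects(path, make_design())

    def test_partition_out_of_range(self, tmp_path):
        path = tmp_path / "bad.csv"
        write_subjects(SUBJECTS, path)
        path.write_text(path.read_text().replace("s3,2,", "s3,5,"))
        with pytest.raises(ValueError, match="partition out of range"):
            read_subjects(path, make_design())

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(entry=st.floats(-10, 100), event_offset=st.floats(-20, 200),
           followup_offset=st.floats(-20, 200), has_event=st.booleans(),
           partition=st.integers(0, 3))
    def test_validation_matches_invariants(self, entry, event_offset,
                                           followup_offset, has_event,
                                           partition):
        """A record is accepted exactly when every stated invariant holds."""
        rec = SubjectRecord("x", partition, "control", entry,
                            entry + event_offset if has_event else None,
                            entry + followup_offset)
        valid = (entry >= 0 and followup_offset >= 0
                 and (not has_event or event_offset >= 0)
                 and 1 <= partition <= 2)
        if valid:
            rec.validate(2)
        else:
            with pytest.raises(ValueError):
                rec.validate(2)


class TestSummaryIO:
    def test_worked_example_parses(self, tmp_path, table1_summaries):
        path = tmp_path / "summ.json"
        write_summaries(table1_summaries, path)
        back = read_summaries(path)
        s = back.require("stage1", 1)
        assert s.theta == pytest.approx(-0.902, abs=1e-9)
        assert s.sigma2 == pytest.approx(0.191, abs=1e-9)
        n = back.require("combined", 1)
        assert n.theta == pytest.approx(-0.746, abs=1e-9)
        assert back.get("stage2", 1) is None  # absent, not zero

    def test_information_keys_accepted(self, tmp_path):
        path = tmp_path / "summ.json"
        path.write_text(json.dumps({"partitions": [
            {"partition": 1, "stage1": {"theta": -0.5, "V": 10.0}},
            {"partition": 2, "stage1": {"theta": 0.1, "sigma2": 0.1}}]}))
        summ = read_summaries(path)
        assert summ.require("stage1", 1).sigma2 == pytest.approx(0.1)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.json"
        path.write_text(json.dumps({"partitions": []}))
        with pytest.raises(ValueError, match="no partitions"):
            read_summaries(path)

    def test_nonpositive_variance_rejected(self, tmp_path):
        path = tmp_path / "summ.json"
        path.write_text(json.dumps({"partitions": [
            {"partition": 1, "stage1": {"theta": -0.5, "sigma2": 0.0}}]}))
        with pytest.raises(ValueError, match="variance must be positive"):
            read_summaries(path)

    def test_numeric_round_trip_12_digits(self, tmp_path, table1_summaries):
        path = tmp_path / "summ.json"
        write_summaries(table1_summaries, path)
        back = read_summaries(path)
        for block in ("stage1", "combined", "increment"):
            for j in (1, 2):
                a = table1_summaries.require(block, j)
                b = back.require(block, j)
                assert b.theta == pytest.approx(a.theta, rel=1e-12)
                assert b.sigma2 == pytest.approx(a.sigma2, rel=1e-12)


class TestReportIO:
    def test_round_trip(self, tmp_path, table1_summaries):
        design = make_design()
        report = estimate_from_summaries(table1_summaries, design)
        path = tmp_path / "report.json"
        write_report(report, path)
        back = read_report(path)
        assert back.selection == report.selection
        assert back.design == report.design
        assert set(back.estimates) == set(report.estimates)
        for j in report.estimates:
            assert back.estimates[j].umvcue == report.estimates[j].umvcue
            assert back.estimates[j].naive_ci == report.estimates[j].naive_ci

    def test_futility_stop_message(self, tmp_path, table1_summaries):
        design = make_design(futility_threshold=-5.0)
        report = estimate_from_summaries(table1_summaries, design)
        assert report.stopped
        path = tmp_path / "stop.json"
        write_report(report, path)
        assert "stopped at interim; no estimates" in path.read_text()
        assert read_report(path).stopped
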