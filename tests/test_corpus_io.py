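import datetime as dt
import random

import pytest

from implantwatch import corpus_io
from implantwatch.corpus_io import (
    CodedRecord,
    CodeList,
    PatientRecord,
    build_cohort,
    extract_coded_revisions,
    load_corpus,
    write_corpus,
)

D = dt.date


def rec(pid, system, code, date):
    return CodedRecord(pid, system, code, date)


class TestBuildCohort:
    def test_primary_code_includes_patient_with_index_date(self):
        cohort = build_cohort([rec("p1", "ICD9-proc", "81.51", D(2005, 3, 1))])
        assert cohort == {"p1": D(2005, 3, 1)}

    def test_empty_table_gives_empty_cohort(self):
        assert build_cohort([]) == {}

    def test_toy_table_matches_brute_force_scan(self):
        # 10 patients, 3 carry CPT 27130 on known dates (earliest wins)
        records = []
        expected = {}
        for i in range(10):
            pid = f"p{i}"
            records.append(rec(pid, "ICD9-dx", "715.15", D(2004, 1, 1)))
            if i in (2, 5, 7):
                d1, d2 = D(2003, 1, 1 + i), D(2006, 2, 1 + i)
                records.append(rec(pid, "CPT", "27130", d2))
                records.append(rec(pid, "CPT", "27130", d1))
                expected[pid] = d1
        # independent oracle: exhaustive scan with set membership
        oracle = {}
        members = {("CPT", "27130"), ("CPT", "27132"), ("ICD9-proc", "81.51")}
        for r in records:
            if (r.code_system, r.code) in members:
                if r.patient_id not in oracle or r.date < oracle[r.patient_id]:
                    oracle[r.patient_id] = r.date
        assert oracle == expected
        assert build_cohort(records) == expected

    def test_order_independent_and_idempotent(self):
        records = [
            rec("a", "ICD9-proc", "81.51", D(2001, 5, 5)),
            rec("b", "CPT", "27132", D(2002, 6, 6)),
            rec("a", "CPT", "27130", D(2000, 1, 1)),
        ]
        base = build_cohort(records)
        for seed in range(5):
            shuffled = records[:]
            random.Random(seed).shuffle(shuffled)
            assert build_cohort(shuffled) == base
        assert build_cohort(records) == base

    def test_malformed_date_rejected_with_warning(self, caplog):
        records = [
            rec("a", "ICD9-proc", "81.51", "not-a-date"),
            rec("b", "ICD9-proc", "81.51", D(2001, 1, 1)),
        ]
        with caplog.at_level("WARNING"):
            cohort = build_cohort(records)
        assert cohort == {"b": D(2001, 1, 1)}
        assert any("malformed" in m for m in caplog.messages)


class TestExtractCodedRevisions:
    def patient(self, coded, index=D(2005, 1, 1)):
        return PatientRecord("p1", coded=coded, index_date=index)

    def test_revision_code_after_index_yields_event(self):
        p = self.patient([rec("p1", "ICD9-proc", "81.53", D(2009, 1, 1))])
        events = extract_coded_revisions(p)
        assert len(events) == 1
        assert events[0].kind == "revision" and events[0].source == "coded"
        assert events[0].date == D(2009, 1, 1)

    def test_no_matching_codes_gives_empty(self):
        p = self.patient([rec("p1", "ICD9-dx", "715.15", D(2009, 1, 1))])
        assert extract_coded_revisions(p) == []

    def test_same_day_duplicates_collapse(self):
        p = self.patient(
            [
                rec("p1", "CPT", "27134", D(2009, 1, 1)),
                rec("p1", "CPT", "27137", D(2009, 1, 1)),
            ]
        )
        events = extract_coded_revisions(p)
        assert len(events) == 1
        assert set(events[0].provenance) == {"CPT:27134", "CPT:27137"}

    def test_events_before_index_excluded(self):
        p = self.patient([rec("p1", "ICD9-proc", "81.53", D(2004, 1, 1))])
        assert extract_coded_revisions(p) == []

    def test_non_cohort_patient_is_error(self):
        p = PatientRecord("p1", coded=[], index_date=None)
        with pytest.raises(ValueError, match="index date"):
            extract_coded_revisions(p)

    def test_count_bounded_by_distinct_patient_dates(self):
        coded = [
            rec("p1", "CPT", "27134", D(2006, 1, 1)),
            rec("p1", "ICD9-proc", "81.53", D(2006, 1, 1)),
            rec("p1", "CPT", "27137", D(2007, 2, 2)),
        ]
        events = extract_coded_revisions(self.patient(coded))
        assert len(events) <= len({(c.patient_id, c.date) for c in coded})
        assert [e.date for e in events] == sorted(e.date for e in events)


class TestLoadCorpus:
    def write_fixture(self, tmp_path, note_lines):
        notes = tmp_path / "notes.jsonl"
        notes.write_text("\n".join(note_lines) + "\n")
        coded = tmp_path / "coded.csv"
        coded.write_text(
            "patient_id,code_system,code,date\n"
            "p1,ICD9-proc,81.51,2005-01-01\n"
            "p2,CPT,27130,2006-02-02\n"
        )
        demo = tmp_path / "demo.csv"
        demo.write_text(
            "patient_id,birth_date,gender,race,ethnicity\n"
            "p1,1950-05-05,F,white,non-hispanic\n"
            "p2,1940-04-04,M,asian,unknown\n"
        )
        return notes, coded, demo

    GOOD = [
        '{"patient_id": "p1", "note_id": "n1", "created": "2005-01-01T10:00:00", "note_class": "operative_report", "text": "A Zimmer VerSys stem was implanted."}',
        '{"patient_id": "p1", "note_id": "n2", "created": "2005-06-01T10:00:00", "note_class": "clinical_note", "text": "No hip pain."}',
        '{"patient_id": "p2", "note_id": "n3", "created": "2006-02-02T10:00:00", "note_class": "clinical_note", "text": "Doing well."}',
    ]

    def test_two_patient_fixture_round_trips(self, tmp_path):
        paths = self.write_fixture(tmp_path, self.GOOD)
        corpus, skipped = load_corpus(*paths)
        assert skipped == 0
        assert sorted(corpus) == ["p1", "p2"]
        assert len(corpus["p1"].notes) == 2 and len(corpus["p2"].notes) == 1
        assert corpus["p1"].demographics.gender == "F"
        out = (tmp_path / "n.jsonl", tmp_path / "c.csv", tmp_path / "d.csv")
        write_corpus(corpus, *out)
        corpus2, _ = load_corpus(*out)
        assert corpus2.keys() == corpus.keys()
        for pid in corpus:
            assert corpus2[pid].notes == corpus[pid].notes
            assert corpus2[pid].coded == corpus[pid].coded
            assert corpus2[pid].demographics == corpus[pid].demographics

    def test_empty_files_give_empty_corpus(self, tmp_path):
        notes = tmp_path / "notes.jsonl"
        notes.write_text("")
        coded = tmp_path / "coded.csv"
        coded.write_text("patient_id,code_system,code,date\n")
        demo = tmp_path / "demo.csv"
        demo.write_text("patient_id,birth_date,gender,race,ethnicity\n")
        corpus, skipped = load_corpus(notes, coded, demo)
        assert corpus == {} and skipped == 0

    def test_corrupt_line_counted_not_fatal(self, tmp_path):
        lines = self.GOOD[:2] + ["{corrupt json!!"] + self.GOOD[2:] + [
            '{"patient_id": "p3", "note_id": "n4", "created": "2007-01-01T00:00:00", "note_class": "clinical_note", "text": ""}'
        ]
        paths = self.write_fixture(tmp_path, lines)
        corpus, skipped = load_corpus(*paths)
        assert skipped == 1
        assert sum(len(r.notes) for r in corpus.values()) == 4

    def test_missing_column_is_fatal_and_named(self, tmp_path):
        coded = tmp_path / "coded.csv"
        coded.write_text("patient_id,code,date\np1,81.51,2005-01-01\n")
        with pytest.raises(ValueError, match="code_system"):
            load_corpus(None, coded, None)

    def test_patient_only_in_one_file_retained(self, tmp_path):
        paths = self.write_fixture(tmp_path, self.GOOD)
        demo = tmp_path / "demo2.csv"
        demo.write_text(
            "patient_id,birth_date,gender,race,ethnicity\n"
            "p9,1930-01-01,M,white,unknown\n"
        )
        corpus, _ = load_corpus(paths[0], paths[1], demo)
        assert "p9" in corpus
        assert corpus["p9"].notes == [] and corpus["p9"].coded == []


def test_code_list_normalizes_and_rejects_empty():
    cl = CodeList.of("x", [(" CPT ", " 27130 ")])
    assert ("CPT", "27130") in cl
    with pytest.raises(ValueError):
        CodeList.of("empty", [])
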