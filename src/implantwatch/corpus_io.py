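"""Reading and writing notes, coded records, and demographics; cohort
selection and coded revision extraction from explicit code lists.

File dialects: notes are JSONL (one object per note with keys patient_id,
note_id, created, note_class, text); coded records and demographics are
plain CSV. Dates are ISO-8601; ambiguous formats are rejected rather than
guessed.
"""

from __future__ import annotations

import csv
import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .events import Event

__all__ = [
    "Note",
    "CodedRecord",
    "CodeList",
    "Demographics",
    "PatientRecord",
    "Corpus",
    "DEFAULT_PRIMARY_CODES",
    "DEFAULT_REVISION_CODES",
    "build_cohort",
    "extract_coded_revisions",
    "load_corpus",
    "write_corpus",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Note:
    patient_id: str
    note_id: str
    created: dt.datetime
    text: str
    note_class: str = "clinical_note"  # operative_report | clinical_note


@dataclass(frozen=True)
class CodedRecord:
    patient_id: str
    code_system: str  # ICD9-proc | CPT | ICD9-dx
    code: str
    date: dt.date


@dataclass(frozen=True)
class CodeList:
    name: str
    members: frozenset[tuple[str, str]]

    @classmethod
    def of(cls, name: str, pairs: Iterable[tuple[str, str]]) -> "CodeList":
        normed = frozenset((s.strip(), c.strip().upper()) for s, c in pairs)
        if not normed:
            raise ValueError("code list must be non-empty")
        return cls(name, normed)

    def __contains__(self, item: tuple[str, str]) -> bool:
        system, code = item
        return (system.strip(), code.strip().upper()) in self.members


# ICD-9 procedure 81.51 = total hip replacement; CPT 27130/27132 = total hip
# arthroplasty / conversion to THA.
DEFAULT_PRIMARY_CODES = CodeList.of(
    "primary_hip_replacement",
    [("ICD9-proc", "81.51"), ("CPT", "27130"), ("CPT", "27132")],
)
# ICD-9 81.53 + 00.70-00.73 and CPT 27134/27137/27138 = revision of total
# hip arthroplasty (both / acetabular-only / femoral-only components).
DEFAULT_REVISION_CODES = CodeList.of(
    "hip_revision",
    [
        ("ICD9-proc", "81.53"),
        ("ICD9-proc", "00.70"),
        ("ICD9-proc", "00.71"),
        ("ICD9-proc", "00.72"),
        ("ICD9-proc", "00.73"),
        ("CPT", "27134"),
        ("CPT", "27137"),
        ("CPT", "27138"),
    ],
)


@dataclass(frozen=True)
class Demographics:
    birth_date: dt.date | None = None
    gender: str = ""
    race: str = ""
    ethnicity: str = ""


@dataclass
class PatientRecord:
    patient_id: str
    demographics: Demographics = field(default_factory=Demographics)
    notes: list[Note] = field(default_factory=list)
    coded: list[CodedRecord] = field(default_factory=list)
    index_date: dt.date | None = None


Corpus = dict[str, PatientRecord]


def _parse_date(value) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value).strip())


def build_cohort(
    coded_records: Iterable[CodedRecord] | pd.DataFrame,
    primary_codes: CodeList = DEFAULT_PRIMARY_CODES,
) -> dict[str, dt.date]:
    """Select patients with >= 1 primary-replacement code.

    Returns ``{patient_id: index_date}`` where the index date is the
    earliest matching record's date. Malformed dates reject the record with
    a warning, never a crash. Order-independent and idempotent.
    """
    if isinstance(coded_records, pd.DataFrame):
        coded_records = (
            CodedRecord(str(r.patient_id), str(r.code_system), str(r.code), r.date)
            for r in coded_records.itertuples()
        )
    cohort: dict[str, dt.date] = {}
    for rec in coded_records:
        if (rec.code_system, rec.code) not in primary_codes:
            continue
        try:
            date = _parse_date(rec.date)
        except (ValueError, TypeError):
            log.warning("rejecting record with malformed date: %r", rec)
            continue
        prev = cohort.get(rec.patient_id)
        if prev is None or date < prev:
            cohort[rec.patient_id] = date
    return cohort


def extract_coded_revisions(
    patient: PatientRecord,
    revision_codes: CodeList = DEFAULT_REVISION_CODES,
) -> list[Event]:
    """Coded revision events strictly after the index date.

    Same-day duplicate codes (e.g. CPT 27134 + 27137 billed together)
    collapse to one event: the unit is the revision surgery, not the
    billing row. Output is chronological.
    """
    if patient.index_date is None:
        raise ValueError(
            f"patient {patient.patient_id} has no index date (not in cohort)"
        )
    dates: dict[dt.date, list[str]] = {}
    for rec in patient.coded:
        if (rec.code_system, rec.code) not in revision_codes:
            continue
        date = _parse_date(rec.date)
        if date <= patient.index_date:
            continue
        dates.setdefault(date, []).append(f"{rec.code_system}:{rec.code}")
    return [
        Event(patient.patient_id, "revision", date, "coded", tuple(sorted(set(codes))))
        for date, codes in sorted(dates.items())
    ]


def _read_csv(path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def load_corpus(
    notes_path=None, coded_path=None, demo_path=None
) -> tuple[Corpus, int]:
    """Load and join notes, coded records, and demographics.

    Patients present in only one file are retained with empty complements.
    Unparseable JSONL lines are skipped and counted; the skip count is
    returned alongside the corpus. Missing required CSV columns are fatal.
    """
    corpus: Corpus = {}
    skipped = 0

    def patient(pid: str) -> PatientRecord:
        return corpus.setdefault(pid, PatientRecord(pid))

    if notes_path is not None:
        with open(notes_path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                    note = Note(
                        str(obj["patient_id"]),
                        str(obj["note_id"]),
                        dt.datetime.fromisoformat(obj["created"]),
                        obj["text"],
                        obj.get("note_class", "clinical_note"),
                    )
                except (json.JSONDecodeError, KeyError, ValueError) as exc:
                    skipped += 1
                    log.warning("skipping unparseable note line: %s", exc)
                    continue
                patient(note.patient_id).notes.append(note)

    if coded_path is not None:
        df = _read_csv(coded_path, ["patient_id", "code_system", "code", "date"])
        for row in df.itertuples():
            try:
                date = _parse_date(row.date)
            except ValueError:
                skipped += 1
                log.warning("skipping coded row with bad date: %r", row)
                continue
            patient(str(row.patient_id)).coded.append(
                CodedRecord(str(row.patient_id), row.code_system, row.code, date)
            )

    if demo_path is not None:
        df = _read_csv(
            demo_path, ["patient_id", "birth_date", "gender", "race", "ethnicity"]
        )
        for row in df.itertuples():
            try:
                birth = _parse_date(row.birth_date) if row.birth_date else None
            except ValueError:
                birth = None
            patient(str(row.patient_id)).demographics = Demographics(
                birth, row.gender, row.race, row.ethnicity
            )

    for rec in corpus.values():
        rec.notes.sort(key=lambda n: (n.created, n.note_id))
        rec.coded.sort(key=lambda c: (c.date, c.code_system, c.code))
    return corpus, skipped


def write_corpus(corpus: Corpus, notes_path, coded_path, demo_path) -> None:
    """Inverse of load_corpus up to field normalization."""
    with open(notes_path, "w") as fh:
        for rec in corpus.values():
            for note in rec.notes:
                fh.write(
                    json.dumps(
                        {
                            "patient_id": note.patient_id,
                            "note_id": note.note_id,
                            "created": note.created.isoformat(),
                            "note_class": note.note_class,
                            "text": note.text,
                        }
                    )
                    + "\n"
                )
    with open(coded_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "code_system", "code", "date"])
        for rec in corpus.values():
            for c in rec.coded:
                w.writerow([c.patient_id, c.code_system, c.code, c.date.isoformat()])
    with open(demo_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "birth_date", "gender", "race", "ethnicity"])
        for rec in corpus.values():
            d = rec.demographics
            w.writerow(
                [
                    rec.patient_id,
                    d.birth_date.isoformat() if d.birth_date else "",
                    d.gender,
                    d.race,
                    d.ethnicity,
                ]
            )


def assign_index_dates(corpus: Corpus, primary_codes: CodeList = DEFAULT_PRIMARY_CODES) -> None:
    """Set each patient's index date from their own coded records."""
    all_coded = [c for rec in corpus.values() for c in rec.coded]
    cohort = build_cohort(all_coded, primary_codes)
    for pid, rec in corpus.items():
        rec.index_date = cohort.get(pid)
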