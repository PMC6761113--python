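"""Timestamped patient events: conversion from positive relation mentions,
coded/text merging, pain-mention counting, and registry comparison.

A text-derived event carries the creation date of the note it came from:
only present-positive mentions (contemporaneous with the note) become
events, so the note timestamp is the event timestamp.
"""

from __future__ import annotations

import datetime as dt
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Event",
    "RegistryRecord",
    "RegistryComparison",
    "EVENT_KINDS",
    "mentions_to_events",
    "collapse_text_events",
    "merge_events",
    "count_pain_mentions",
    "compare_registry",
]

EVENT_KINDS = (
    "revision",
    "component_wear",
    "mechanical_failure",
    "particle_disease",
    "radiographic_abnormality",
    "infection",
    "pain_mention",
)


@dataclass(frozen=True)
class Event:
    patient_id: str
    kind: str
    date: dt.date
    source: str  # coded | text | merged
    provenance: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.source not in ("coded", "text", "merged"):
            raise ValueError(f"unknown source {self.source!r}")


@dataclass(frozen=True)
class RegistryRecord:
    patient_id: str
    surgery_date: dt.date
    component: str  # acetabular | femoral
    manufacturer: str
    model: str


@dataclass
class RegistryComparison:
    statuses: list[tuple[str, dt.date, str, str]]  # (patient, surgery, component, status)
    proportions: dict[str, float] = field(default_factory=dict)


def mentions_to_events(predictions, candidates, notes) -> list[Event]:
    """Turn positive relation predictions into timestamped text events.

    ``predictions`` and ``candidates`` are aligned sequences; ``notes`` maps
    note_id to either a Note or a creation date. Positive
    implant_complication candidates yield one event of the complication's
    subclass; positive pain_anatomy candidates with hip-type anatomy yield
    one pain_mention event. One event per positive mention — frequency is
    informative, so mentions are not capped per note.
    """
    out: list[Event] = []
    for pred, cand in zip(predictions, candidates):
        decision = getattr(pred, "decision", pred)
        if decision not in ("positive", True, 1):
            continue
        note_id = cand.note_id
        note = notes[note_id]
        created = getattr(note, "created", note)
        date = created.date() if isinstance(created, dt.datetime) else created
        if cand.relation_type == "implant_complication":
            subclass = cand.entity_a.attributes.get("subclass")
            if subclass in EVENT_KINDS:
                out.append(
                    Event(cand.patient_id, subclass, date, "text", (note_id,))
                )
        elif cand.relation_type == "pain_anatomy":
            if cand.entity_b.canonical_id == "anat:hip":
                out.append(
                    Event(cand.patient_id, "pain_mention", date, "text", (note_id,))
                )
    out.sort(key=lambda e: (e.patient_id, e.date, e.kind))
    return out


def collapse_text_events(text_events: Sequence[Event], window_days: int = 60) -> list[Event]:
    """Collapse repeated text mentions of the same complication subclass.

    An event, not a mention, is the unit for merging: mentions of one
    subclass within ``window_days`` of the first mention become a single
    event dated at the earliest mention. pain_mention events are never
    collapsed (their frequency is the analysed quantity).
    """
    out: list[Event] = []
    by_key: dict[tuple[str, str], list[Event]] = defaultdict(list)
    for ev in sorted(text_events, key=lambda e: (e.patient_id, e.kind, e.date)):
        if ev.kind == "pain_mention":
            out.append(ev)
            continue
        by_key[(ev.patient_id, ev.kind)].append(ev)
    for group in by_key.values():
        anchor: Event | None = None
        prov: list[str] = []
        for ev in group:
            if anchor is None or (ev.date - anchor.date).days > window_days:
                if anchor is not None:
                    out.append(replace(anchor, provenance=tuple(prov)))
                anchor, prov = ev, list(ev.provenance)
            else:
                prov.extend(ev.provenance)
        if anchor is not None:
            out.append(replace(anchor, provenance=tuple(prov)))
    out.sort(key=lambda e: (e.patient_id, e.date, e.kind))
    return out


def merge_events(
    coded: Sequence[Event], text: Sequence[Event], window_days: int = 60
) -> list[Event]:
    """Merge coded and text-derived events of the same kind per patient.

    A coded and a text event for one patient within ``window_days`` of each
    other are the same real-world event seen through two channels: they
    merge into one Event(source="merged") dated at the earlier of the two,
    carrying both provenances. Pairing is greedy-chronological (earliest
    coded event claims the earliest compatible unmatched text event); ties
    break on provenance string order. Unmatched events pass through, so
    ``len(output) == len(coded) + len(text) - n_merged_pairs``.
    """
    text_pool: dict[tuple[str, str], list[Event]] = defaultdict(list)
    for ev in sorted(text, key=lambda e: (e.date, e.provenance)):
        text_pool[(ev.patient_id, ev.kind)].append(ev)
    used: set[int] = set()
    out: list[Event] = []
    for ev in sorted(coded, key=lambda e: (e.date, e.provenance)):
        pool = text_pool.get((ev.patient_id, ev.kind), [])
        match = None
        for cand in pool:
            if id(cand) in used:
                continue
            if abs((cand.date - ev.date).days) <= window_days:
                match = cand
                break
        if match is None:
            out.append(ev)
        else:
            used.add(id(match))
            out.append(
                Event(
                    ev.patient_id,
                    ev.kind,
                    min(ev.date, match.date),
                    "merged",
                    tuple(ev.provenance) + tuple(match.provenance),
                )
            )
    for pool in text_pool.values():
        out.extend(ev for ev in pool if id(ev) not in used)
    out.sort(key=lambda e: (e.patient_id, e.date, e.kind, e.source))
    return out


def count_pain_mentions(
    events: Iterable[Event],
    index_date: dt.date,
    window: tuple[int, int],
    hip_only: bool = True,
) -> int:
    """Count pain_mention events in a half-open day window around index.

    ``window`` is ``[start, end)`` in days relative to the index date, so
    ``(0, 365)`` is the first post-operative year and ``(-365, 0)`` the year
    before surgery. The generating pipeline only emits pain_mention events
    for hip-type anatomy, so ``hip_only`` is a no-op safeguard here.
    """
    lo, hi = window
    n = 0
    for ev in events:
        if ev.kind != "pain_mention":
            continue
        day = (ev.date - index_date).days
        if lo <= day < hi:
            n += 1
    return n


def _canon(manufacturer: str, model: str) -> tuple[str, str]:
    man = manufacturer.strip().lower()
    if man in ("zimmer", "zimmer biomet", "biomet"):
        man = "zimmer biomet"
    return man, model.strip().lower()


def compare_registry(
    system_output: Sequence[RegistryRecord], registry: Sequence[RegistryRecord]
) -> RegistryComparison:
    """Compare extracted implant components against a registry snapshot.

    Per (patient, surgery date, component slot): agreement means identical
    manufacturer/model after canonicalization, conflict means both sides
    recorded the slot but with different entries, and a record present on
    only one side is missing_in_system or missing_in_registry.
    """
    sys_map = {
        (r.patient_id, r.surgery_date, r.component): r for r in system_output
    }
    reg_map = {(r.patient_id, r.surgery_date, r.component): r for r in registry}
    statuses = []
    for key in sorted(set(sys_map) | set(reg_map), key=lambda k: (k[0], str(k[1]), k[2])):
        if key in sys_map and key in reg_map:
            s, r = sys_map[key], reg_map[key]
            same = _canon(s.manufacturer, s.model) == _canon(r.manufacturer, r.model)
            status = "agreement" if same else "conflict"
        elif key in reg_map:
            status = "missing_in_system"
        else:
            status = "missing_in_registry"
        statuses.append((*key, status))
    total = len(statuses)
    proportions = {
        k: (sum(1 for s in statuses if s[3] == k) / total if total else 0.0)
        for k in ("agreement", "conflict", "missing_in_system", "missing_in_registry")
    }
    return RegistryComparison(statuses, proportions)
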