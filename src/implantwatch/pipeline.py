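"""Convenience orchestration: notes -> markup -> entities -> candidates.

Thin glue over the stage modules so tests, examples, the CLI, and users
all assemble candidates the same way.
"""

from __future__ import annotations

from typing import Sequence

from . import entity_tagging, text_markup, weak_supervision
from .corpus_io import Corpus, Note
from .entity_tagging import Lexicon
from .weak_supervision import CandidateRelation

__all__ = ["note_candidates", "corpus_candidates", "patient_implant_systems"]


def note_candidates(
    note: Note,
    patient_id: str,
    lexicon: Lexicon,
    relation_types: Sequence[str] = ("pain_anatomy", "implant_complication"),
    trigger_table=None,
    header_lexicon=None,
) -> list[CandidateRelation]:
    """Markup and tag one note, returning all candidate relations."""
    sentences = text_markup.segment_and_tokenize(note)
    sections = text_markup.detect_sections(note, header_lexicon)
    dates = text_markup.normalize_dates(note)
    out: list[CandidateRelation] = []
    for sent in sentences:
        modifiers = text_markup.detect_modifiers(sent, sections, trigger_table)
        entities = entity_tagging.tag_entities(sent, lexicon, modifiers)
        if not entities:
            continue
        section = text_markup.section_at(sections, sent.char_span[0])
        bins = tuple(
            d.delta_bin
            for d in dates
            if sent.char_span[0] <= d.char_span[0] < sent.char_span[1]
        )
        for rel in relation_types:
            out.extend(
                weak_supervision.generate_candidates(
                    entities, rel, sent, patient_id, section, bins, modifiers
                )
            )
    return out


def corpus_candidates(
    corpus: Corpus,
    lexicon: Lexicon | None = None,
    relation_types: Sequence[str] = ("pain_anatomy", "implant_complication"),
) -> list[CandidateRelation]:
    lexicon = lexicon or entity_tagging.load_lexicon()
    trigger_table = text_markup.load_trigger_table()
    header_lexicon = text_markup.load_section_lexicon()
    out: list[CandidateRelation] = []
    for pid in sorted(corpus):
        for note in corpus[pid].notes:
            out.extend(
                note_candidates(
                    note, pid, lexicon, relation_types, trigger_table, header_lexicon
                )
            )
    return out


def patient_implant_systems(corpus: Corpus, lexicon: Lexicon | None = None) -> dict[str, object]:
    """Compose each patient's implant system from operative-report entities."""
    lexicon = lexicon or entity_tagging.load_lexicon()
    trigger_table = text_markup.load_trigger_table()
    out: dict[str, object] = {}
    for pid, rec in corpus.items():
        entities = []
        for note in rec.notes:
            if note.note_class != "operative_report":
                continue
            for sent in text_markup.segment_and_tokenize(note):
                entities.extend(entity_tagging.tag_entities(sent, lexicon))
        out[pid] = entity_tagging.compose_implant_system(entities)
    return out
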