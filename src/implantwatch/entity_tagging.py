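"""Dictionary-based tagging of implant, complication, anatomy, and pain
mentions, with canonicalization to manufacturer/model and composition of
per-patient implant systems.

Matching is longest-match-wins, left-to-right, case-insensitive over token
sequences; matched spans never overlap and never cross sentence
boundaries. The bundled lexicon covers the Zimmer Biomet and Depuy implant
families plus common complication/anatomy/pain surface forms; it is a
starter dictionary that users extend with their own CSV (UMLS-scale
coverage is an extension, not a default).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources as _ilres
from typing import Iterable, Mapping, Sequence

from .text_markup import ModifierSpan, Sentence

__all__ = [
    "LexiconEntry",
    "Lexicon",
    "Entity",
    "ImplantSystem",
    "load_lexicon",
    "tag_entities",
    "compose_implant_system",
]

ENTITY_TYPES = ("implant", "complication", "anatomy", "pain")
COMPONENTS = ("acetabular", "femoral", "liner", "head", "unknown")
SUBCLASSES = (
    "revision",
    "component_wear",
    "mechanical_failure",
    "particle_disease",
    "radiographic_abnormality",
    "infection",
)

_MANUFACTURER_ALIASES = {
    "zimmer": "Zimmer Biomet",
    "biomet": "Zimmer Biomet",
    "zimmer biomet": "Zimmer Biomet",
    "depuy": "Depuy",
}


@dataclass(frozen=True)
class LexiconEntry:
    surface: str
    entity_type: str
    canonical_id: str
    attributes: Mapping[str, str]


class Lexicon:
    """Surface-form dictionary indexed by first token for fast matching."""

    def __init__(self, entries: Iterable[LexiconEntry]):
        self.entries: dict[str, LexiconEntry] = {}
        self._by_first: dict[str, list[tuple[tuple[str, ...], LexiconEntry]]] = {}
        for e in sorted(entries, key=lambda e: e.surface):
            surface = e.surface.lower()
            if e.entity_type not in ENTITY_TYPES:
                raise ValueError(f"unknown entity type {e.entity_type!r}")
            self.entries[surface] = e
            toks = tuple(surface.split())
            self._by_first.setdefault(toks[0], []).append((toks, e))
        for bucket in self._by_first.values():
            bucket.sort(key=lambda item: (-len(item[0]), item[0]))

    def __len__(self) -> int:
        return len(self.entries)

    def candidates_at(self, first_token: str):
        return self._by_first.get(first_token.lower(), ())


@dataclass(frozen=True)
class Entity:
    note_id: str
    sentence_index: int
    char_span: tuple[int, int]
    entity_type: str
    canonical_id: str
    text: str
    attributes: Mapping[str, str] = field(default_factory=dict)
    modifiers: frozenset[str] = frozenset()


@dataclass(frozen=True)
class ImplantSystem:
    manufacturer: str
    acetabular: str
    femoral: str

    @property
    def label(self) -> str:
        return f"{self.manufacturer} {self.acetabular} + {self.femoral}"


def load_lexicon(path=None) -> Lexicon:
    """Load a lexicon CSV (surface,entity_type,canonical_id,manufacturer,
    model,component,subclass); defaults to the bundled starter lexicon."""
    if path is None:
        raw = _ilres.files("implantwatch.resources").joinpath("lexicon.csv").read_text()
    else:
        raw = open(path).read()
    entries = []
    for row in csv.DictReader(raw.splitlines()):
        attrs = {}
        if row["entity_type"] == "implant":
            man = _MANUFACTURER_ALIASES.get(
                row.get("manufacturer", "").strip().lower(),
                row.get("manufacturer", "").strip(),
            )
            attrs = {
                "manufacturer": man,
                "model": row.get("model", "").strip(),
                "component": row.get("component", "").strip() or "unknown",
            }
        elif row["entity_type"] == "complication":
            attrs = {"subclass": row.get("subclass", "").strip()}
        entries.append(
            LexiconEntry(
                row["surface"].strip().lower(),
                row["entity_type"].strip(),
                row["canonical_id"].strip(),
                attrs,
            )
        )
    return Lexicon(entries)


def tag_entities(
    sentence: Sentence,
    lexicon: Lexicon,
    modifiers: Sequence[ModifierSpan] = (),
) -> list[Entity]:
    """Tag all lexicon matches in a sentence.

    Left-to-right scan; at each position the longest matching surface wins
    and consumes its tokens, so returned entities never overlap. Each
    entity absorbs the kinds of any modifier scope overlapping its span.
    """
    toks = sentence.tokens
    out: list[Entity] = []
    i = 0
    while i < len(toks):
        best: tuple[int, LexiconEntry] | None = None
        for surface_toks, entry in lexicon.candidates_at(toks[i][0]):
            n = len(surface_toks)
            if i + n > len(toks):
                continue
            if all(toks[i + k][0].lower() == surface_toks[k] for k in range(n)):
                best = (n, entry)
                break  # buckets are sorted longest-first
        if best is None:
            i += 1
            continue
        n, entry = best
        span = (toks[i][1][0], toks[i + n - 1][1][1])
        mods = frozenset(
            m.kind
            for m in modifiers
            if m.scope[0] < span[1] and span[0] < m.scope[1]
        )
        out.append(
            Entity(
                sentence.note_id,
                sentence.index,
                span,
                entry.entity_type,
                entry.canonical_id,
                " ".join(toks[i + k][0] for k in range(n)),
                dict(entry.attributes),
                mods,
            )
        )
        i += n
    return out


def compose_implant_system(entities: Iterable[Entity]):
    """Compose a patient's implant system from operative-report entities.

    Returns an ImplantSystem when exactly one distinct canonical acetabular
    model and one distinct femoral model are present; otherwise the string
    flag "incomplete" (a slot has no model) or "multiple" (a slot has
    conflicting models). Flags, not exceptions: downstream analyses filter
    on them.
    """
    slots: dict[str, set[tuple[str, str]]] = {"acetabular": set(), "femoral": set()}
    for e in entities:
        if e.entity_type != "implant":
            continue
        comp = e.attributes.get("component")
        model = e.attributes.get("model")
        if comp in slots and model:
            slots[comp].add((e.attributes.get("manufacturer", ""), model))
    if any(len(s) > 1 for s in slots.values()):
        return "multiple"
    if any(not s for s in slots.values()):
        return "incomplete"
    (ace_man, ace_model), = slots["acetabular"]
    (_fem_man, fem_model), = slots["femoral"]
    return ImplantSystem(ace_man, ace_model, fem_model)
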