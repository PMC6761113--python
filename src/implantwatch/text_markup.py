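"""Sentence segmentation, tokenization, sections, date normalization, and
NegEx/ConText-style modifier detection.

All spans are 0-based, half-open character offsets into the owning note's
text. Tokenization is deliberately rule-based: dictionary matching of
device names needs stable tokens, so hyphenated and slashed compounds
("metal-on-metal", "M/L") stay whole.
"""

from __future__ import annotations

import csv
import datetime as dt
import re
from dataclasses import dataclass, field
from importlib import resources as _ilres
from typing import Iterable, Sequence

__all__ = [
    "Sentence",
    "SectionSpan",
    "DateMention",
    "ModifierSpan",
    "TriggerRule",
    "DeltaBinTable",
    "DEFAULT_BIN_TABLE",
    "segment_and_tokenize",
    "detect_sections",
    "normalize_dates",
    "detect_modifiers",
    "load_section_lexicon",
    "load_trigger_table",
]

Span = tuple[int, int]

# Tokens: alphanumeric runs glued by internal - / ' (device names like
# "metal-on-metal", "M/L", "Ranawat/Burstein" stay single tokens), else
# single non-space characters (punctuation).
_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:[-/'][A-Za-z0-9]+)*|[^\sA-Za-z0-9]")

# Sentence boundary: terminal punctuation followed by whitespace, or a
# newline that starts a new header-like or capitalised line.
_BOUNDARY_RE = re.compile(r"(?<=[.!?])\s+|(?<=:)\n|\n\s*\n|\n(?=[A-Z][A-Z /&]+:)")


@dataclass(frozen=True)
class Sentence:
    note_id: str
    index: int
    char_span: Span
    tokens: tuple[tuple[str, Span], ...]

    @property
    def token_texts(self) -> tuple[str, ...]:
        return tuple(t for t, _ in self.tokens)


@dataclass(frozen=True)
class SectionSpan:
    note_id: str
    canonical_header: str
    char_span: Span


@dataclass(frozen=True)
class DateMention:
    char_span: Span
    resolved_date: dt.date
    delta_bin: str


@dataclass(frozen=True)
class ModifierSpan:
    kind: str  # negated | hypothetical | historical
    trigger: str
    scope: Span


@dataclass(frozen=True)
class TriggerRule:
    phrase: str
    kind: str  # negated | hypothetical | historical | terminator
    direction: str  # forward | backward | bidirectional
    max_scope: int  # tokens


class DeltaBinTable:
    """Total, non-overlapping partition of the signed day-difference line.

    Day-scale bins out to one year, then signed whole-year bins capped at
    "+10+ years" / "-10+ years".
    """

    _DAY_EDGES = ((0, 1), (2, 7), (8, 30), (31, 182), (183, 365))

    def bin_for(self, delta_days: int) -> str:
        sign = "+" if delta_days >= 0 else "-"
        d = abs(delta_days)
        if delta_days in (-1, 0, 1) or d <= 1:
            return "0-1 days" if delta_days >= -1 else ""
        for lo, hi in self._DAY_EDGES:
            if lo <= d <= hi:
                label = f"{lo}-{hi} days"
                return label if sign == "+" else f"-{label}"
        years = d // 365
        if years >= 10:
            return f"{sign}10+ years"
        return f"{sign}{years} years"

    def labels(self) -> list[str]:
        out = ["0-1 days"]
        for lo, hi in self._DAY_EDGES[1:]:
            out += [f"{lo}-{hi} days", f"-{lo}-{hi} days"]
        for y in range(1, 10):
            out += [f"+{y} years", f"-{y} years"]
        out += ["+10+ years", "-10+ years"]
        return out

    def _check_total(self) -> None:
        # exhaustive over a generous range; the mapping is periodic beyond it
        for d in range(-5000, 5001):
            label = self.bin_for(d)
            if not label:
                raise AssertionError(f"delta {d} has no bin")


DEFAULT_BIN_TABLE = DeltaBinTable()
DEFAULT_BIN_TABLE._check_total()


def segment_and_tokenize(note) -> list[Sentence]:
    """Split a note's text into offset-preserving sentences and tokens.

    Total function: whitespace-only text yields no sentences, and
    concatenating the sentence slices plus inter-sentence gaps always
    reconstructs the original text.
    """
    text = note.text
    sentences: list[Sentence] = []
    cursor = 0
    pieces: list[Span] = []
    for m in _BOUNDARY_RE.finditer(text):
        pieces.append((cursor, m.start()))
        cursor = m.end()
    pieces.append((cursor, len(text)))

    idx = 0
    for start, end in pieces:
        raw = text[start:end]
        # trim whitespace but keep offsets honest
        lstrip = len(raw) - len(raw.lstrip())
        rstrip = len(raw) - len(raw.rstrip())
        s, e = start + lstrip, end - rstrip
        if s >= e:
            continue
        tokens = tuple(
            (m.group(0), (s + m.start(), s + m.end()))
            for m in _TOKEN_RE.finditer(text[s:e])
        )
        sentences.append(Sentence(note.note_id, idx, (s, e), tokens))
        idx += 1
    return sentences


_HEADER_LINE_RE = re.compile(r"^[ \t]*([A-Za-z][A-Za-z /&'-]{2,60}):", re.MULTILINE)


def load_section_lexicon(path=None) -> dict[str, str]:
    """Map lower-cased header surface forms to canonical section names."""
    if path is None:
        source = _ilres.files("implantwatch.resources").joinpath("section_headers.csv")
        raw = source.read_text()
    else:
        raw = open(path).read()
    lex: dict[str, str] = {}
    for row in csv.DictReader(raw.splitlines()):
        lex[row["surface"].strip().lower()] = row["canonical"].strip()
    return lex


def detect_sections(note, header_lexicon: dict[str, str] | None = None) -> list[SectionSpan]:
    """Partition the note into section spans keyed by canonical header.

    Text before the first recognized header is section "body"; headers not
    in the lexicon do not open a new section (they stay inside the
    enclosing one).
    """
    if header_lexicon is None:
        header_lexicon = load_section_lexicon()
    text = note.text
    cuts: list[tuple[int, str]] = []
    for m in _HEADER_LINE_RE.finditer(text):
        surface = m.group(1).strip().lower()
        if surface in header_lexicon:
            cuts.append((m.start(), header_lexicon[surface]))
    spans: list[SectionSpan] = []
    if not cuts or cuts[0][0] > 0:
        first = cuts[0][0] if cuts else len(text)
        spans.append(SectionSpan(note.note_id, "body", (0, first)))
    for i, (start, canon) in enumerate(cuts):
        end = cuts[i + 1][0] if i + 1 < len(cuts) else len(text)
        spans.append(SectionSpan(note.note_id, canon, (start, end)))
    return spans


def section_at(sections: Sequence[SectionSpan], offset: int) -> str:
    for s in sections:
        if s.char_span[0] <= offset < s.char_span[1]:
            return s.canonical_header
    return "body"


_MONTHS = {
    m.lower(): i + 1
    for i, m in enumerate(
        ["January", "February", "March", "April", "May", "June", "July",
         "August", "September", "October", "November", "December"]
    )
}
_DATE_PATTERNS = [
    # M/D/YYYY and M-D-YYYY (4-digit years only; 2-digit years are ambiguous)
    re.compile(r"\b(\d{1,2})([/-])(\d{1,2})\2(\d{4})\b"),
    re.compile(r"\b(\d{4})-(\d{2})-(\d{2})\b"),
    re.compile(
        r"\b(" + "|".join(m.capitalize() for m in _MONTHS) + r")\s+(\d{1,2}),?\s+(\d{4})\b"
    ),
]


def normalize_dates(note, bin_table: DeltaBinTable = DEFAULT_BIN_TABLE) -> list[DateMention]:
    """Find unambiguous date mentions and bin them relative to note creation.

    Recognized dialects: M/D/YYYY, M-D-YYYY, "Month D, YYYY", YYYY-MM-DD.
    Strings that do not resolve to a real calendar date are skipped.
    """
    created = note.created.date() if isinstance(note.created, dt.datetime) else note.created
    mentions: list[DateMention] = []
    seen: set[Span] = set()
    for pat in _DATE_PATTERNS:
        for m in pat.finditer(note.text):
            span = (m.start(), m.end())
            if any(s < span[1] and span[0] < e for s, e in seen):
                continue
            g = m.groups()
            try:
                if pat is _DATE_PATTERNS[0]:
                    date = dt.date(int(g[3]), int(g[0]), int(g[2]))
                elif pat is _DATE_PATTERNS[1]:
                    date = dt.date(int(g[0]), int(g[1]), int(g[2]))
                else:
                    date = dt.date(int(g[2]), _MONTHS[g[0].lower()], int(g[1]))
            except ValueError:
                continue
            delta = (date - created).days
            mentions.append(DateMention(span, date, bin_table.bin_for(delta)))
            seen.add(span)
    mentions.sort(key=lambda d: d.char_span)
    return mentions


def load_trigger_table(path=None) -> list[TriggerRule]:
    if path is None:
        raw = _ilres.files("implantwatch.resources").joinpath("triggers.csv").read_text()
    else:
        raw = open(path).read()
    rules = []
    for row in csv.DictReader(raw.splitlines()):
        rules.append(
            TriggerRule(
                row["phrase"].strip().lower(),
                row["kind"].strip(),
                row["direction"].strip(),
                int(row["scope"]),
            )
        )
    return rules


def _match_trigger(tokens: Sequence[str], start: int, phrase_tokens: Sequence[str]) -> bool:
    if start + len(phrase_tokens) > len(tokens):
        return False
    return all(
        tokens[start + k].lower() == phrase_tokens[k] for k in range(len(phrase_tokens))
    )


def detect_modifiers(
    sentence: Sentence,
    sections: Sequence[SectionSpan] = (),
    trigger_table: Sequence[TriggerRule] | None = None,
) -> list[ModifierSpan]:
    """NegEx/ConText-style scope detection within one sentence.

    Scopes extend ``max_scope`` tokens in the trigger's direction, truncated
    at the sentence boundary or at a terminator trigger ("but", "however",
    ";"). Any sentence inside a past_medical_history section additionally
    yields a historical modifier covering the whole section. Output order is
    deterministic and independent of trigger-table row order.
    """
    if trigger_table is None:
        trigger_table = load_trigger_table()
    toks = sentence.token_texts
    spans = sentence.tokens
    n = len(toks)
    terminator_at = [False] * n
    for rule in trigger_table:
        if rule.kind != "terminator":
            continue
        pt = rule.phrase.split()
        for i in range(n):
            if _match_trigger(toks, i, pt):
                terminator_at[i] = True

    out: list[ModifierSpan] = []
    # longest phrase first so "no evidence of" beats "no"
    ordered = sorted(trigger_table, key=lambda r: (-len(r.phrase.split()), r.phrase, r.kind))
    claimed: list[tuple[int, int]] = []  # token index ranges already used as triggers
    for rule in ordered:
        if rule.kind == "terminator":
            continue
        pt = rule.phrase.split()
        for i in range(n):
            if not _match_trigger(toks, i, pt):
                continue
            if any(i < ce and i + len(pt) > cs for cs, ce in claimed):
                continue
            claimed.append((i, i + len(pt)))
            tok_ranges = []
            if rule.direction in ("forward", "bidirectional"):
                j = i + len(pt)
                end = min(n, j + rule.max_scope)
                for k in range(j, end):
                    if terminator_at[k]:
                        end = k
                        break
                if j < end:
                    tok_ranges.append((j, end))
            if rule.direction in ("backward", "bidirectional"):
                j = i
                start = max(0, j - rule.max_scope)
                for k in range(j - 1, start - 1, -1):
                    if terminator_at[k]:
                        start = k + 1
                        break
                if start < j:
                    tok_ranges.append((start, j))
            for ts, te in tok_ranges:
                scope = (spans[ts][1][0], spans[te - 1][1][1])
                out.append(ModifierSpan(rule.kind, rule.phrase, scope))

    for sec in sections:
        if sec.canonical_header == "past_medical_history":
            s, e = sec.char_span
            if s < sentence.char_span[1] and sentence.char_span[0] < e:
                out.append(ModifierSpan("historical", "§past_medical_history", (s, e)))
    out.sort(key=lambda m: (m.scope, m.kind, m.trigger))
    return out
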