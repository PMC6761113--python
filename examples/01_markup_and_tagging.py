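"""Markup and dictionary tagging of a single clinical note.

Builds one note by hand, then runs sentence segmentation, section
detection, date normalization, modifier (negation/historical/
hypothetical) detection, and lexicon tagging, printing what each stage
sees.
"""

import datetime as dt

from implantwatch import entity_tagging, text_markup
from implantwatch.corpus_io import Note

TEXT = """PAST MEDICAL HISTORY:
Revision surgery of the left hip on 6/1/2001.
IMAGING:
The left acetabular cup demonstrates extreme liner wear.
No evidence of periprosthetic infection around the Depuy Pinnacle.
"""

note = Note("p1", "n1", dt.datetime(2006, 6, 1, 9, 0), TEXT, "clinical_note")
lexicon = entity_tagging.load_lexicon()
sections = text_markup.detect_sections(note)
dates = text_markup.normalize_dates(note)

print("Sections:")
for sec in sections:
    print(f"  {sec.canonical_header:24s} chars {sec.char_span}")
print("Date mentions (relative to note creation):")
for d in dates:
    print(f"  {note.text[slice(*d.char_span)]!r} -> {d.resolved_date} bin {d.delta_bin!r}")

print("Sentences, modifiers, and tagged entities:")
for sent in text_markup.segment_and_tokenize(note):
    mods = text_markup.detect_modifiers(sent, sections)
    entities = entity_tagging.tag_entities(sent, lexicon, mods)
    if not entities:
        continue
    print(f"  sentence {sent.index}: {note.text[slice(*sent.char_span)]!r}")
    for e in entities:
        flags = ",".join(sorted(e.modifiers)) or "present"
        print(f"    {e.entity_type:13s} {e.text!r:38s} [{flags}]")

# The revision mention sits in Past Medical History (historical, not a
# current event); the liner-wear mention is a present-positive finding;
# the infection mention is negated. Only the present-positive mention
# should survive into the event stream.
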