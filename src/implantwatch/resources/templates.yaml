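# Sentence templates for the synthetic EHR generator. Slots in braces are
# filled with lexicon surface forms; spans of the filled slots are recorded
# as gold annotations. "positive" variants are present-positive relations;
# the other variants are gold-negative. Some positive templates deliberately
# avoid the cue words and short entity gaps that the shipped labeling
# functions key on, so heuristic coverage of true relations is incomplete
# (as with real clinical language).
pain_anatomy:
  positive:
    - "Patient reports {pain} in the {anatomy} on exam."
    - "Exam demonstrates {pain} over the {anatomy}."
    - "{anatomy} {pain} noted at the visit."
    - "She reports {pain} of the {anatomy} today."
    - "He complains of {pain} localized to the {anatomy} region."
    - "Persistent {pain} which involves most of the {anatomy} continues."
  negated:
    - "No {pain} in the {anatomy} today."
    - "Patient denies {pain} of the {anatomy}."
    - "The {anatomy} is without {pain} or swelling."
  historical:
    - "History of {pain} in the {anatomy} years ago."
    - "Prior {pain} of the {anatomy} resolved."
  hypothetical:
    - "Return if {pain} in the {anatomy} develops."
    - "She may develop {pain} near the {anatomy}."
implant_complication:
  positive:
    - "Imaging demonstrates {complication} of the {implant} component."
    - "The {implant} shows {complication} on the current films."
    - "{complication} of the {implant} noted today."
    - "There is {complication} in the region of the {implant} component."
    - "Ongoing {complication} seen at the margin of the {implant} shell."
  negated:
    - "No evidence of {complication} around the {implant}."
    - "The {implant} is intact without {complication}."
    - "Negative for {complication} of the {implant}."
  historical:
    - "History of {complication} after the {implant} was placed."
    - "Prior {complication} of the {implant} treated elsewhere."
    - "{complication} of the {implant} was treated on {old_date}."
  hypothetical:
    - "If {complication} of the {implant} occurs, we will reassess."
    - "Watch for {complication} near the {implant}."
filler:
  - "Vital signs are stable."
  - "The wound is healing well."
  - "Patient ambulating with a walker."
  - "Follow up in six weeks."
  - "Range of motion is improving."
operative:
  - "A {ace_surface} acetabular shell and a {fem_surface} femoral stem were implanted."
  - "The {ace_surface} cup was seated and the {fem_surface} stem placed."
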