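# Methods

This note documents the models and procedures implemented in
`implantwatch`, the assumptions behind them, the defaults and why they
were chosen, and what the synthetic-data experiments do and do not show.

## Text markup

Sentence segmentation and tokenization are rule-based. Tokens are
alphanumeric runs glued by internal `-`, `/`, `'` so device vocabulary
("metal-on-metal", "M/L", "Ranawat/Burstein") survives as single tokens —
a requirement for dictionary matching, and the reason a statistical
tokenizer is deliberately not used. Sentences break on terminal
punctuation, blank lines, and header lines; a header line (e.g. `PAST
MEDICAL HISTORY:`) always ends a sentence so that the word "history" in a
header can never open a historical-modifier scope over following text.

Sections partition the note: a shipped, editable lexicon of ~35 common
header surfaces maps to canonical sections (past_medical_history,
history_of_present_illness, assessment_plan, operative_findings, imaging,
medications, body). Unknown headers do not open sections; text before the
first known header is "body".

Date mentions in four unambiguous dialects (M/D/YYYY, M-D-YYYY,
"Month D, YYYY", YYYY-MM-DD) are resolved and binned by signed distance
from the note's creation time. The bin table is: "0–1 days" (|Δ| ≤ 1),
then signed day bins 2–7, 8–30, 31–182, 183–365, then signed whole-year
bins ±1…±9, capped at "±10+ years". Two-digit years are skipped as
ambiguous. The table is checked at import time to be a total,
non-overlapping partition of the signed day line. Day-scale granularity
near the note and year-scale granularity far from it reflects how
clinicians reference time; nothing downstream is sensitive to the exact
cut points.

Modifier detection is a compact NegEx/ConText: trigger phrases (negated /
hypothetical / historical) scope 6 tokens in their direction by default,
truncated at sentence ends and at terminators ("but", "however", ";").
Six tokens is the classic NegEx window. Sentences inside a
past_medical_history section additionally receive a historical modifier
spanning the section — the one scope allowed to cross sentence
boundaries. Detection is deterministic and invariant to trigger-table row
order (longest phrase wins; overlapping triggers cannot double-fire).

## Entity tagging and implant systems

Tagging is longest-match-wins, left-to-right, case-insensitive over token
sequences, so returned mentions never overlap and "hip pain" beats "hip"
at the same offset. The bundled lexicon covers the Zimmer Biomet
(Trilogy, Continuum, RingLoc, Ranawat/Burstein acetabular; VerSys,
M/L Taper, Taperloc femoral; Longevity liner) and Depuy (Pinnacle,
Duraloc acetabular; AML, Corail, Summit, Endurance femoral) families plus
~50 complication/anatomy/pain surfaces; it is a starter dictionary, and
production use is expected to extend it with institution-specific CSVs.
"Zimmer" and "Zimmer Biomet" alias to one manufacturer.

A patient's implant system is composed from operative-report entities:
exactly one distinct acetabular and one distinct femoral model yields a
system label ("Depuy Pinnacle + AML"); anything else is flagged
`incomplete` or `multiple` and excluded from single-implant analyses.
Laterality is not resolved; restricting to single-implant patients (as
all outcome analyses do by default) sidesteps attribution of events to a
specific hip.

## Weak supervision

Candidates are the per-sentence Cartesian product of the two entity
types of a relation — (pain, anatomy) and (complication, implant). The
label model treats labeling functions as conditionally independent noisy
voters on a latent y ∈ {−1, +1} with fixed class prior p (default 0.5):
LF j votes with propensity β_j and, conditional on voting, matches y with
accuracy α_j. β_j has a closed-form MLE (its vote rate); α is fitted by
EM (tolerance 1e-6, ≤500 iterations), initialised at 0.7 to break the
label-flip symmetry and clipped to [0.51, 0.99]. The marginal
log-likelihood is asserted non-decreasing at every step. Posteriors are
exact under the model; all-abstain rows receive the prior. LF
correlations are not modelled.

One subtlety worth recording: the posterior is monotone in the vote
margin (#TRUE − #FALSE), while the soft majority vote scores by the
fraction of cast votes. The two rank candidates identically only among
rows casting the same number of votes; across different abstain patterns
they can legitimately disagree.

Discriminative training uses only *covered* candidates (at least one
non-abstain vote). An uncovered candidate's posterior is the bare prior,
which carries no signal; including such rows teaches the model to park
their sentence shapes at the prior and blunts exactly the generalisation
weak supervision is meant to buy.

## Relation classifiers

Training instances are the sentence's tokens wrapped in inline markup:
`<a>…</a>` and `<b>…</b>` entity boundaries, a `<sec:…>` tag, `<bin:…>`
date tags, and `<mod:…>` modifier tags. The noise-aware loss is the
expected cross-entropy under the soft label.

* `bag_of_ngrams` (default): logistic regression over uni/bi-grams. The
  soft-label loss is realised exactly by duplicating each example into a
  positive copy weighted y and a negative copy weighted 1−y. L-BFGS makes
  it deterministic; L2 strength is 1e-4·n in sklearn's C parameterisation.
* `bilstm_attention`: single-layer BiLSTM (default hidden 16) with
  additive attention and sigmoid output, in NumPy with hand-written
  backpropagation (validated against finite differences in the test
  suite) and Adam. Embeddings are randomly initialised; pre-trained
  vectors may be passed in. It exists as the sequence-model option; the
  n-gram model is the default because it trains in seconds on a CPU and
  the two expose identical train/predict/checkpoint contracts.

Splits are by document, never by candidate, to prevent sentence leakage.
Decision threshold is 0.5 with score ≥ threshold counting positive.

## Events and merging

Only present-positive mentions become events, dated at the note's
creation date — the pipeline's definition of an event being
"contemporaneous" with its documentation. Repeated text mentions of the
same complication subclass within the merge window collapse to one event
(an event, not a mention, is the unit); pain mentions never collapse,
because their frequency is the analysed quantity. Coded and text events
of the same kind for one patient merge when within 60 days of each
other, keeping the earlier date and both provenances; pairing is greedy
chronological with deterministic tie-breaks. The 60-day window bounds
merging so that genuinely distinct revisions years apart are never
fused; it is configurable.

Registry comparison canonicalizes both sides to manufacturer/model and
classifies each (patient, surgery, component) slot as agreement,
conflict, missing_in_system, or missing_in_registry; proportions sum
to 1 and swapping the inputs swaps the two missingness categories.

## Outcome models

* **Cox proportional hazards** (lifelines, Efron ties, configurable to
  Breslow) on time from primary replacement to first event, with
  categorical covariates dummy-coded against explicit reference levels
  (default reference system: the most frequent). A log-rank test across
  implant-system strata is reported alongside. Patients without the
  outcome are censored at end of follow-up.
* **Negative binomial** (statsmodels NB2, MLE dispersion) on first-year
  pain-mention counts with the system interaction, demographics, prior-
  year pain count, and follow-up. For each candidate frequency cutoff,
  systems with fewer patients collapse to "other"; the cutoff minimising
  AIC wins (asserted, not assumed).
* **Welch t-test** of pain burden, revised vs unrevised. "Controlling for
  follow-up" has two defensible readings, both implemented:
  `fixed_window` (default) compares raw counts within a common fixed
  window, controlling follow-up by construction; `rate_per_year` divides
  by follow-up years.
* **Charlson index**: accepted as a precomputed integer and categorized
  0/1/2/≥3; an optional helper computes it from ICD-9 codes with a
  compact Quan-style prefix map and the standard severity hierarchy.

## Synthetic EHR

The generator is a pure function of (config, seed). Defaults describe a
plausible hip-replacement service: implant systems drawn from a
12-system frequency table with Trilogy + VerSys most common (30%);
~5–6% revision incidence under a 0.012/person-year baseline hazard and
follow-up uniform on 1–9.6 years (mean ≈ 5.3); first-year hip-pain
mentions negative binomial with mean 3.23 and size 1.5; 45% of planted
relation mentions present-positive with 25/20/10% negated / historical /
hypothetical. Notes are assembled from a YAML template resource so users
can extend surface variety without touching the generator; gold spans
are recorded at construction time and verified to substring-match their
note text. Some positive templates deliberately avoid the labeling
functions' cue words and short entity gaps, so heuristic coverage of
true relations is incomplete — the property that gives weak supervision
something to improve on, as in real clinical language.

What passing tests show: the pipeline's machinery — offsets, scoping,
candidate generation, EM denoising, noise-aware training, merging, and
the statistical recovery of planted hazard ratios and rate ratios — is
correct under the generator's assumptions. What they do not show:
robustness to real clinical style (abbreviation soup, copy-forward,
mis-spellings, template-free narrative), vocabulary beyond the bundled
lexicon, coreference, or laterality. Extraction metrics on the synthetic
corpus are upper bounds, not estimates, of real-world performance.

## Problem sizes and determinism

Test and example runs use 30–150 synthetic patients (≈300–2000 candidate
relations) for pipeline checks and n = 2000–3000 simulated patients ×
20 seeds for Cox/NB recovery — sizes at which the estimators' confidence
intervals are informative while a full run stays interactive on one CPU.
Every stochastic step takes an explicit seed; identical configs produce
byte-identical corpora and bit-identical model scores.

## Known limitations

No learned NER (dictionary recall bounds implant coverage); no LF
dependency modelling; no transformer architectures; no propensity-score
matching, frailty, or competing-risks survival models; no laterality or
coreference resolution; the bundled Charlson map is a compact subset of
a full Quan implementation.
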