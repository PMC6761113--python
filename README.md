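# implantwatch

Post-market surveillance of implantable medical devices from electronic
health records. Much of the evidence that an implant is failing — reports
of pain, loosening, wear, infection, or an upcoming revision — lives in
free-text clinical notes rather than billing codes. `implantwatch` turns a
corpus of clinical notes plus structured records into timestamped,
implant-attributed outcome events **without hand-labeled training data**,
then models how implant systems differ in revision-free survivorship and
post-implant pain burden. It is aimed at clinical informatics and device
epidemiology groups who have notes and codes but no annotation budget.

## What it does

1. **Cohort construction** (`corpus_io`): selects hip-replacement patients
   from ICD-9 procedure code 81.51 and CPT 27130/27132, with coded
   revisions from ICD-9 81.53 and 00.70–00.73 and CPT 27134/27137/27138.
2. **Text markup** (`text_markup`): rule-based sentence segmentation and
   tokenization, section-header detection, normalization of date mentions
   to relative time-delta bins ("0–1 days", "−5 years"), and
   NegEx/ConText-style negated / hypothetical / historical scopes.
3. **Entity tagging** (`entity_tagging`): dictionary tagging of implants
   (canonicalized to manufacturer/model, e.g. "Zimmer VerSys" → Zimmer
   Biomet VerSys, femoral), complications in six subclasses (revision,
   component wear, mechanical failure, particle disease, radiographic
   abnormality, infection), anatomy, and pain; composition of each
   patient's implant system (acetabular + femoral pair).
4. **Weak supervision** (`weak_supervision`): candidate relations are the
   per-sentence Cartesian product of (pain, anatomy) or (complication,
   implant) mentions. A library of labeling functions votes
   {FALSE, ABSTAIN, TRUE} on each candidate; an unsupervised generative
   model estimates each function's accuracy α_j and propensity β_j by EM
   and emits the posterior P(y = +1 | votes) as a probabilistic label.
5. **Relation classification** (`relation_classifier`): a discriminative
   model trained with the noise-aware expected cross-entropy
   Σᵢ yᵢ(−log ŷᵢ) + (1−yᵢ)(−log(1−ŷᵢ)) on soft labels yᵢ. Architectures:
   `bag_of_ngrams` (logistic over markup n-grams; fast default) and
   `bilstm_attention` (bidirectional LSTM with additive attention,
   implemented in NumPy with manual backpropagation).
6. **Events** (`events`): present-positive mentions become events dated at
   the note timestamp; text and coded events of the same kind merge within
   a 60-day window (earlier date wins); pain mentions are counted in
   windows around surgery; extracted implants are audited against a
   registry snapshot (agreement / conflict / missingness).
7. **Outcome models** (`outcomes_stats`): Cox proportional hazards on time
   to first event with Efron ties and a log-rank test across systems;
   negative binomial regression of first-year pain-mention counts with the
   femoral×acetabular system interaction, rare systems collapsed to
   "other" at the AIC-minimizing frequency cutoff; Welch t-test of pain
   burden in revised vs unrevised patients; Charlson index categorization
   (0 / 1 / 2 / ≥3 → none / low / moderate / high).
8. **Synthetic EHR** (`synthetic_ehr`): a generator of templated notes with
   planted gold entities/relations (including negated, historical, and
   hypothetical variants), coded records, demographics, registry
   snapshots, and survival/count outcomes — every stage is testable with
   no access to protected health data.

## Worked example

`examples/03_train_and_evaluate.py` generates a 120-patient synthetic
corpus, weakly labels its candidate relations, trains the classifier on
the probabilistic labels only, and scores both the classifier and the
rule-based soft-majority-vote (SMV) baseline on held-out documents:

```
held-out candidates: 365 (304 true positives)
model                         P      R     F1
soft majority vote         98.2   73.4   84.0
weakly supervised          98.7  100.0   99.3
improvement over SMV:  recall +36.2%  F1 +18.2%
```

The SMV baseline only fires where a labeling function fires, so its
recall is capped by heuristic coverage; the classifier generalizes past
the trigger vocabulary (it learns, e.g., that the *absence* of negation
and history markers signals a present-positive mention) and recovers the
uncovered true relations at almost no precision cost. The other examples
walk through markup and tagging (`01`), label-model fitting (`02`), event
merging plus the Cox/NB/t-test analyses (`04`), and the registry audit
(`05`); each prints a short explanation with its numbers.

A thin CLI mirrors the main steps:

```bash
implantwatch simulate --n-patients 100 --seed 7 --out synth/
implantwatch cohort --notes synth/notes.jsonl --codes synth/coded.csv --out cohort.csv
implantwatch label --notes synth/notes.jsonl --out labels.jsonl
implantwatch analyze --rows rows.csv --model cox --outcome revision
```

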