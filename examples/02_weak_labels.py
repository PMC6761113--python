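"""Data programming on the synthetic EHR: labeling functions, the
generative label model, and probabilistic labels.

Generates a synthetic corpus with planted ground truth, applies the
default labeling-function library, fits the accuracy/propensity label
model by EM (unsupervised), and compares the resulting posteriors with
the soft majority vote.
"""

import numpy as np

from implantwatch import pipeline, synthetic_ehr, weak_supervision as ws

config = synthetic_ehr.SimConfig(n_patients=80, seed=7)
corpus, gt = synthetic_ehr.simulate_corpus(config)
candidates = pipeline.corpus_candidates(corpus)
gold = {r.key: r for r in gt.relations}
truth = np.array(
    [gold[(c.note_id, c.entity_a.char_span, c.entity_b.char_span)].is_positive
     for c in candidates]
)

lfs = ws.default_lfs("implant_complication") + [
    lf for lf in ws.default_lfs("pain_anatomy") if lf.task == "pain_anatomy"
]
L = ws.apply_lfs(candidates, lfs)
params = ws.fit_label_model(L)

print(f"{len(candidates)} candidates, {L.shape[1]} labeling functions")
print("Estimated LF accuracies (EM, no labels seen):")
for name, a, b in zip(L.lf_names, params.alpha, params.beta):
    print(f"  {name:24s} accuracy {a:.2f}  propensity {b:.2f}")

marginals = np.array([m.probability for m in ws.predict_marginals(L, params)])
smv = np.array([s for s, _ in ws.soft_majority_vote(L)])
covered = ws.coverage_mask(L)
print(f"coverage: {covered.mean():.0%} of candidates received at least one vote")
print(f"mean posterior on true positives:  {marginals[truth].mean():.3f}")
print(f"mean posterior on true negatives:  {marginals[~truth].mean():.3f}")

# A high-accuracy LF (e.g. the negation detector) is weighted up by the
# label model; posteriors separate the planted present-positive relations
# from negated/historical/hypothetical ones without any hand labels.
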