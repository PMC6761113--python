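"""Data programming: candidate relations, labeling functions, the
generative label model, and probabilistic labels.

The generative model treats labeling functions (LFs) as conditionally
independent noisy voters on a latent binary label y in {-1, +1}: LF j
votes with propensity beta_j and, when it votes, agrees with y with
accuracy alpha_j. Fitting is unsupervised expectation-maximisation over
the observed vote matrix; the posterior P(y=+1 | votes) becomes the
probabilistic training label for the discriminative classifier. The soft
majority vote of the same LFs is the rule-based baseline.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .entity_tagging import Entity
from .text_markup import ModifierSpan, Sentence

__all__ = [
    "CandidateRelation",
    "LabelingFunction",
    "LabelMatrix",
    "LabelModelParams",
    "ProbabilisticLabel",
    "LabelModelConfig",
    "generate_candidates",
    "apply_lfs",
    "fit_label_model",
    "predict_marginals",
    "soft_majority_vote",
    "default_lfs",
]

log = logging.getLogger(__name__)

RELATION_SIGNATURES = {
    "pain_anatomy": ("pain", "anatomy"),
    "implant_complication": ("complication", "implant"),
}


@dataclass(frozen=True)
class CandidateRelation:
    """A typed entity pair within one sentence, with its markup context.

    entity_a is the pain/complication mention, entity_b the
    anatomy/implant mention (relation signature order).
    """

    candidate_id: str
    relation_type: str
    entity_a: Entity
    entity_b: Entity
    note_id: str
    patient_id: str
    sentence: Sentence
    section: str = "body"
    date_bins: tuple[str, ...] = ()
    modifiers: tuple[ModifierSpan, ...] = ()

    @property
    def pair_modifiers(self) -> frozenset[str]:
        return self.entity_a.modifiers | self.entity_b.modifiers

    def token_distance(self) -> int:
        """Tokens strictly between the two entity spans."""
        lo = min(self.entity_a.char_span[1], self.entity_b.char_span[1])
        hi = max(self.entity_a.char_span[0], self.entity_b.char_span[0])
        return sum(
            1 for _, (s, e) in self.sentence.tokens if s >= lo and e <= hi
        )


def generate_candidates(
    entities: Sequence[Entity],
    relation_type: str,
    sentence: Sentence,
    patient_id: str,
    section: str = "body",
    date_bins: Sequence[str] = (),
    modifiers: Sequence[ModifierSpan] = (),
) -> list[CandidateRelation]:
    """Cartesian product of the relation's two entity types in a sentence."""
    type_a, type_b = RELATION_SIGNATURES[relation_type]
    a_entities = [e for e in entities if e.entity_type == type_a]
    b_entities = [e for e in entities if e.entity_type == type_b]
    out = []
    for a in a_entities:
        for b in b_entities:
            cid = (
                f"{sentence.note_id}:{sentence.index}:"
                f"{a.char_span[0]}-{a.char_span[1]}:{b.char_span[0]}-{b.char_span[1]}"
            )
            out.append(
                CandidateRelation(
                    cid,
                    relation_type,
                    a,
                    b,
                    sentence.note_id,
                    patient_id,
                    sentence,
                    section,
                    tuple(date_bins),
                    tuple(modifiers),
                )
            )
    return out


@dataclass(frozen=True)
class LabelingFunction:
    """A pure heuristic mapping a candidate to a vote in {-1, 0, +1}."""

    name: str
    fn: Callable[[CandidateRelation], int]
    task: str = "shared"

    def __call__(self, cand: CandidateRelation) -> int:
        return self.fn(cand)


@dataclass
class LabelMatrix:
    """Votes in {-1, 0, +1}: rows are candidates, columns are LFs."""

    votes: np.ndarray  # (n_candidates, n_lfs) int8
    lf_names: tuple[str, ...]

    def __post_init__(self):
        self.votes = np.asarray(self.votes, dtype=np.int8)
        if not np.isin(self.votes, (-1, 0, 1)).all():
            raise ValueError("votes must lie in {-1, 0, +1}")
        if self.votes.ndim != 2 or self.votes.shape[1] != len(self.lf_names):
            raise ValueError("vote matrix shape does not match LF names")

    @property
    def shape(self):
        return self.votes.shape

    def save(self, mtx_path, names_path) -> None:
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        mmwrite(str(mtx_path), csr_matrix(self.votes))
        with open(names_path, "w") as fh:
            json.dump(list(self.lf_names), fh)

    @classmethod
    def load(cls, mtx_path, names_path) -> "LabelMatrix":
        from scipy.io import mmread

        votes = np.asarray(mmread(str(mtx_path)).todense(), dtype=np.int8)
        with open(names_path) as fh:
            names = tuple(json.load(fh))
        return cls(votes, names)


def apply_lfs(
    candidates: Sequence[CandidateRelation], lfs: Sequence[LabelingFunction]
) -> LabelMatrix:
    """Evaluate every LF on every candidate; LF exceptions become abstains
    with a logged warning."""
    votes = np.zeros((len(candidates), len(lfs)), dtype=np.int8)
    for j, lf in enumerate(lfs):
        for i, cand in enumerate(candidates):
            try:
                v = int(lf(cand))
            except Exception as exc:  # noqa: BLE001 - LF bugs must not kill labeling
                log.warning("LF %s raised on candidate %s: %s", lf.name, cand.candidate_id, exc)
                v = 0
            if v not in (-1, 0, 1):
                raise ValueError(f"LF {lf.name} returned {v}, not a vote")
            votes[i, j] = v
    return LabelMatrix(votes, tuple(lf.name for lf in lfs))


@dataclass
class LabelModelParams:
    alpha: np.ndarray  # per-LF accuracy, clipped to (0.5, 1)
    beta: np.ndarray  # per-LF propensity in (0, 1]
    prior: float  # P(y = +1)
    log_likelihood_path: list[float] = field(default_factory=list)


@dataclass
class LabelModelConfig:
    prior: float = 0.5
    tol: float = 1e-6
    max_iter: int = 500
    alpha_init: float = 0.7
    alpha_bounds: tuple[float, float] = (0.51, 0.99)
    seed: int = 0


@dataclass(frozen=True)
class ProbabilisticLabel:
    candidate_id: str
    probability: float


def _row_posteriors(L: np.ndarray, alpha: np.ndarray, prior: float) -> np.ndarray:
    """Exact posterior P(y=+1 | votes) per row; abstains contribute nothing."""
    pos = (L == 1).astype(float)
    neg = (L == -1).astype(float)
    log_a = np.log(alpha)
    log_na = np.log1p(-alpha)
    ll_pos = pos @ log_a + neg @ log_na  # log P(votes | y=+1), up to beta terms
    ll_neg = pos @ log_na + neg @ log_a
    m = np.maximum(ll_pos, ll_neg)
    num = prior * np.exp(ll_pos - m)
    den = num + (1 - prior) * np.exp(ll_neg - m)
    return num / den


def _marginal_ll(L: np.ndarray, alpha: np.ndarray, beta: np.ndarray, prior: float) -> float:
    pos = (L == 1).astype(float)
    neg = (L == -1).astype(float)
    obs = pos + neg
    log_a, log_na = np.log(alpha), np.log1p(-alpha)
    ll_pos = pos @ log_a + neg @ log_na
    ll_neg = pos @ log_na + neg @ log_a
    beta_term = obs @ np.log(beta) + (1 - obs) @ np.log1p(-np.minimum(beta, 1 - 1e-12))
    m = np.maximum(ll_pos, ll_neg)
    mix = m + np.log(prior * np.exp(ll_pos - m) + (1 - prior) * np.exp(ll_neg - m))
    return float(np.sum(mix + beta_term))


def fit_label_model(
    L: LabelMatrix, config: LabelModelConfig | None = None
) -> LabelModelParams:
    """Fit per-LF accuracies and propensities by EM with a fixed class prior.

    Propensity beta_j has the closed-form MLE (fraction of non-abstain
    votes). Accuracies start at ``alpha_init`` (breaking the label-flip
    symmetry toward "LFs are better than chance") and are clipped to
    ``alpha_bounds`` every M-step. The marginal log-likelihood is asserted
    non-decreasing across iterations.
    """
    cfg = config or LabelModelConfig()
    V = L.votes.astype(np.int64)
    if V.size == 0 or not np.any(V != 0):
        raise ValueError("label matrix has no votes: model unfittable")
    n, m = V.shape
    obs = V != 0
    beta = np.clip(obs.mean(axis=0), 1e-6, 1.0)
    lo, hi = cfg.alpha_bounds
    alpha = np.full(m, cfg.alpha_init, dtype=float)
    prior = cfg.prior

    ll_path: list[float] = []
    prev = -np.inf
    for _ in range(cfg.max_iter):
        q = _row_posteriors(V, alpha, prior)  # E-step
        pos, neg = (V == 1), (V == -1)
        agree = pos.T @ q + neg.T @ (1 - q)  # expected agreements per LF
        total = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            alpha = np.where(total > 0, agree / np.maximum(total, 1), cfg.alpha_init)
        alpha = np.clip(alpha, lo, hi)
        ll = _marginal_ll(V, alpha, beta, prior)
        if ll_path and ll < ll_path[-1] - 1e-8:
            raise AssertionError("EM log-likelihood decreased")
        ll_path.append(ll)
        if ll - prev < cfg.tol:
            break
        prev = ll
    return LabelModelParams(alpha, beta, prior, ll_path)


def predict_marginals(
    L: LabelMatrix,
    params: LabelModelParams,
    candidates: Sequence[CandidateRelation] | None = None,
) -> list[ProbabilisticLabel]:
    """Posterior P(y=+1 | votes) per candidate; all-abstain rows get the prior."""
    probs = _row_posteriors(L.votes.astype(np.int64), params.alpha, params.prior)
    ids = (
        [c.candidate_id for c in candidates]
        if candidates is not None
        else [str(i) for i in range(L.votes.shape[0])]
    )
    return [ProbabilisticLabel(cid, float(p)) for cid, p in zip(ids, probs)]


def coverage_mask(L: LabelMatrix) -> np.ndarray:
    """Boolean mask of candidates with at least one non-abstain vote.

    Discriminative training conventionally uses only covered candidates:
    an all-abstain row carries no supervision signal (its posterior is the
    bare prior), and training on it only teaches the model to park that
    sentence shape at the prior.
    """
    return (L.votes != 0).any(axis=1)


def soft_majority_vote(
    L: LabelMatrix, threshold: float = 0.5
) -> list[tuple[float, str]]:
    """Fraction of non-abstain votes that are positive, with a decision.

    All-abstain rows are decided negative (abstain-as-negative), the
    convention that makes SMV a high-precision, low-recall baseline.
    """
    V = L.votes
    pos = (V == 1).sum(axis=1)
    nonabstain = (V != 0).sum(axis=1)
    out = []
    for p, na in zip(pos, nonabstain):
        if na == 0:
            out.append((0.0, "negative"))
        else:
            score = p / na
            out.append((float(score), "positive" if score >= threshold else "negative"))
    return out


# ---------------------------------------------------------------------------
# Shipped LF library: representative of the families used for implant
# surveillance (section-, modifier-, distance-, trigger-, and date-based).
# ---------------------------------------------------------------------------

_NEGATIVE_SECTIONS = ("past_medical_history",)
_POSITIVE_CUES = ("demonstrates", "shows", "reports", "noted", "exam")
_HEDGE_CUES = ("doubt", "unlikely", "versus")


def default_lfs(relation_type: str, max_pair_distance: int = 12) -> list[LabelingFunction]:
    """The default labeling-function set for one relation task."""

    def lf_section_history(c: CandidateRelation) -> int:
        return -1 if c.section in _NEGATIVE_SECTIONS else 0

    def lf_negated(c: CandidateRelation) -> int:
        return -1 if "negated" in c.pair_modifiers else 0

    def lf_hypothetical(c: CandidateRelation) -> int:
        return -1 if "hypothetical" in c.pair_modifiers else 0

    def lf_historical(c: CandidateRelation) -> int:
        return -1 if "historical" in c.pair_modifiers else 0

    def lf_far_apart(c: CandidateRelation) -> int:
        return -1 if c.token_distance() > max_pair_distance else 0

    def lf_adjacent(c: CandidateRelation) -> int:
        if c.token_distance() <= 2 and not c.pair_modifiers:
            return 1
        return 0

    def lf_positive_cue(c: CandidateRelation) -> int:
        toks = {t.lower() for t in c.sentence.token_texts}
        if toks & set(_POSITIVE_CUES) and not c.pair_modifiers:
            return 1
        return 0

    def lf_hedge_cue(c: CandidateRelation) -> int:
        toks = {t.lower() for t in c.sentence.token_texts}
        return -1 if toks & set(_HEDGE_CUES) else 0

    def lf_old_date(c: CandidateRelation) -> int:
        return -1 if any(b.startswith("-") and "year" in b for b in c.date_bins) else 0

    lfs = [
        LabelingFunction("lf_section_history", lf_section_history),
        LabelingFunction("lf_negated", lf_negated),
        LabelingFunction("lf_hypothetical", lf_hypothetical),
        LabelingFunction("lf_historical", lf_historical),
        LabelingFunction("lf_far_apart", lf_far_apart),
        LabelingFunction("lf_adjacent", lf_adjacent),
        LabelingFunction("lf_positive_cue", lf_positive_cue),
        LabelingFunction("lf_hedge_cue", lf_hedge_cue),
        LabelingFunction("lf_old_date", lf_old_date),
    ]

    if relation_type == "implant_complication":

        def lf_imaging_section(c: CandidateRelation) -> int:
            if c.section in ("imaging", "operative_findings") and not c.pair_modifiers:
                return 1
            return 0

        lfs.append(LabelingFunction("lf_imaging_section", lf_imaging_section, relation_type))
    elif relation_type == "pain_anatomy":

        def lf_pain_precedes_anatomy(c: CandidateRelation) -> int:
            # "hip pain": anatomy immediately before the pain token
            if 0 <= c.entity_a.char_span[0] - c.entity_b.char_span[1] <= 1:
                return 1 if not c.pair_modifiers else 0
            return 0

        lfs.append(
            LabelingFunction("lf_pain_precedes_anatomy", lf_pain_precedes_anatomy, relation_type)
        )
    return lfs
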