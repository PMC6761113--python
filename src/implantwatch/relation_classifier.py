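"""Discriminative relation classifiers trained on probabilistic labels.

Two interchangeable architectures share one train/predict contract:

* ``bag_of_ngrams`` — logistic regression over uni/bi-grams of the markup
  token stream. The noise-aware expected cross-entropy
  ``sum_i y_i (-log yhat_i) + (1 - y_i)(-log(1 - yhat_i))`` with soft
  ``y_i`` is realised exactly by duplicating each example into a
  positive and a negative copy weighted ``y_i`` and ``1 - y_i``. Fast and
  deterministic; the default for desk-scale work.
* ``bilstm_attention`` — a single-layer bidirectional LSTM with additive
  attention and a sigmoid output, implemented in NumPy with manual
  backpropagation and Adam. Embeddings are randomly initialised by
  default; pre-trained vectors can be supplied.

Training instances are the candidate's sentence tokens wrapped in inline
markup: entity boundary tags, a section tag, date-bin tags, and modifier
tags, so document-level context is available to the model as plain
symbols.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np

from .weak_supervision import CandidateRelation

__all__ = [
    "TrainingExample",
    "ModelConfig",
    "Prediction",
    "candidate_to_tokens",
    "make_training_examples",
    "train_noise_aware",
    "predict",
    "learning_curve",
    "save_model",
    "load_model",
]

UNK = "<unk>"


def expected_cross_entropy(soft_label: float, score: float) -> float:
    """Noise-aware per-example loss: CE of the prediction against a soft
    label (ln 2 when both are 0.5)."""
    s = min(max(score, 1e-12), 1 - 1e-12)
    return float(-(soft_label * np.log(s) + (1 - soft_label) * np.log(1 - s)))


@dataclass(frozen=True)
class TrainingExample:
    tokens: tuple[str, ...]
    soft_label: float
    candidate_id: str = ""
    note_id: str = ""

    def __post_init__(self):
        if not np.isfinite(self.soft_label):
            raise ValueError("soft label must be finite")


@dataclass
class ModelConfig:
    architecture: str = "bag_of_ngrams"  # or "bilstm_attention"
    embedding_dim: int = 32
    hidden_dim: int = 16
    epochs: int = 10
    learning_rate: float = 0.01
    seed: int = 13
    threshold: float = 0.5
    l2: float = 1e-4
    batch_size: int = 16

    def __post_init__(self):
        if self.architecture not in ("bag_of_ngrams", "bilstm_attention"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        if min(self.embedding_dim, self.hidden_dim, self.epochs) <= 0:
            raise ValueError("dimensions and epochs must be positive")


@dataclass(frozen=True)
class Prediction:
    candidate_id: str
    score: float
    decision: str  # score >= threshold -> positive


def candidate_to_tokens(cand: CandidateRelation) -> tuple[str, ...]:
    """Markup token stream for one candidate.

    Sentence tokens lower-cased, with <a>...</a> around the pain or
    complication mention and <b>...</b> around the anatomy or implant
    mention, preceded by section, date-bin, and modifier tags.
    """
    prefix = [f"<sec:{cand.section}>"]
    prefix += [f"<bin:{b}>" for b in cand.date_bins]
    prefix += sorted(f"<mod:{m}>" for m in cand.pair_modifiers)
    a_span, b_span = cand.entity_a.char_span, cand.entity_b.char_span
    body: list[str] = []
    for text, (s, e) in cand.sentence.tokens:
        if s == a_span[0]:
            body.append("<a>")
        if s == b_span[0]:
            body.append("<b>")
        body.append(text.lower())
        if e == a_span[1]:
            body.append("</a>")
        if e == b_span[1]:
            body.append("</b>")
    return tuple(prefix + body)


def make_training_examples(
    candidates: Sequence[CandidateRelation], soft_labels: Sequence[float]
) -> list[TrainingExample]:
    return [
        TrainingExample(candidate_to_tokens(c), float(p), c.candidate_id, c.note_id)
        for c, p in zip(candidates, soft_labels)
    ]


# ---------------------------------------------------------------------------
# bag-of-ngrams
# ---------------------------------------------------------------------------


def _ngrams(tokens: Sequence[str]) -> list[str]:
    grams = list(tokens)
    grams += [f"{a}__{b}" for a, b in zip(tokens, tokens[1:])]
    return grams


class BagOfNgramsModel:
    def __init__(self, config: ModelConfig):
        self.config = config
        self.vocab: dict[str, int] = {}
        self.clf = None

    def _vectorize(self, examples: Iterable[Sequence[str]], fit: bool):
        from scipy.sparse import csr_matrix

        rows, cols, data = [], [], []
        n = 0
        for i, toks in enumerate(examples):
            n = i + 1
            seen: dict[int, int] = {}
            for g in _ngrams(toks):
                j = self.vocab.get(g)
                if j is None:
                    if not fit:
                        continue
                    j = self.vocab[g] = len(self.vocab)
                seen[j] = seen.get(j, 0) + 1
            for j, c in seen.items():
                rows.append(i)
                cols.append(j)
                data.append(c)
        return csr_matrix(
            (data, (rows, cols)), shape=(n, max(len(self.vocab), 1)), dtype=float
        )

    def fit(self, examples: Sequence[TrainingExample]) -> "BagOfNgramsModel":
        from scipy.sparse import vstack
        from sklearn.linear_model import LogisticRegression

        X = self._vectorize([e.tokens for e in examples], fit=True)
        p = np.array([e.soft_label for e in examples])
        # noise-aware expected CE == weighted hard-label CE on duplicated rows
        Xd = vstack([X, X])
        yd = np.concatenate([np.ones(len(p)), np.zeros(len(p))])
        wd = np.concatenate([p, 1 - p])
        keep = wd > 1e-12
        self.clf = LogisticRegression(
            C=1.0 / max(self.config.l2 * len(examples), 1e-12),
            solver="lbfgs",
            max_iter=2000,
            random_state=self.config.seed,
        )
        self.clf.fit(Xd[keep], yd[keep], sample_weight=wd[keep])
        return self

    def score(self, token_streams: Sequence[Sequence[str]]) -> np.ndarray:
        X = self._vectorize(token_streams, fit=False)
        if X.shape[0] == 0:
            return np.zeros(0)
        return self.clf.predict_proba(X)[:, 1]


# ---------------------------------------------------------------------------
# BiLSTM with additive attention (NumPy, manual backprop)
# ---------------------------------------------------------------------------


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


class BiLSTMAttentionModel:
    """Single-layer BiLSTM + additive attention + sigmoid output."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.vocab: dict[str, int] = {UNK: 0}
        self.params: dict[str, np.ndarray] = {}

    # -- parameter setup ----------------------------------------------------
    def _init_params(self, rng: np.random.Generator, pretrained=None):
        d, h = self.config.embedding_dim, self.config.hidden_dim
        V = len(self.vocab)

        def glorot(*shape):
            lim = np.sqrt(6.0 / sum(shape))
            return rng.uniform(-lim, lim, size=shape)

        P = {
            "E": rng.normal(0, 0.1, size=(V, d)),
            "v_a": glorot(2 * h),
            "W_a": glorot(2 * h, 2 * h),
            "b_a": np.zeros(2 * h),
            "w_o": glorot(2 * h),
            "b_o": np.zeros(1),
        }
        for direction in ("f", "b"):
            P[f"W_{direction}"] = glorot(4 * h, d + h)
            P[f"bias_{direction}"] = np.zeros(4 * h)
            # forget-gate bias 1.0: standard stabilisation
            P[f"bias_{direction}"][h : 2 * h] = 1.0
        if pretrained:
            for tok, vec in pretrained.items():
                if tok in self.vocab and len(vec) == d:
                    P["E"][self.vocab[tok]] = vec
        self.params = P

    # -- forward ------------------------------------------------------------
    def _lstm_forward(self, xs: np.ndarray, W: np.ndarray, b: np.ndarray):
        h_dim = self.config.hidden_dim
        T = xs.shape[0]
        hs = np.zeros((T, h_dim))
        cache = []
        h = np.zeros(h_dim)
        c = np.zeros(h_dim)
        for t in range(T):
            z = W @ np.concatenate([xs[t], h]) + b
            i = _sigmoid(z[:h_dim])
            f = _sigmoid(z[h_dim : 2 * h_dim])
            g = np.tanh(z[2 * h_dim : 3 * h_dim])
            o = _sigmoid(z[3 * h_dim :])
            c_new = f * c + i * g
            h_new = o * np.tanh(c_new)
            cache.append((xs[t], h, c, i, f, g, o, c_new))
            h, c = h_new, c_new
            hs[t] = h
        return hs, cache

    def _forward(self, idxs: np.ndarray):
        P = self.params
        xs = P["E"][idxs]
        hs_f, cache_f = self._lstm_forward(xs, P["W_f"], P["bias_f"])
        hs_b_rev, cache_b = self._lstm_forward(xs[::-1], P["W_b"], P["bias_b"])
        hs_b = hs_b_rev[::-1]
        H = np.concatenate([hs_f, hs_b], axis=1)  # (T, 2h)
        pre = H @ P["W_a"].T + P["b_a"]
        tanh_pre = np.tanh(pre)
        u = tanh_pre @ P["v_a"]
        u = u - u.max()
        a = np.exp(u) / np.exp(u).sum()
        context = a @ H
        logit = float(P["w_o"] @ context + P["b_o"][0])
        yhat = _sigmoid(np.array(logit))
        cache = (idxs, xs, cache_f, cache_b, H, tanh_pre, a, context)
        return float(yhat), cache

    # -- backward -----------------------------------------------------------
    def _lstm_backward(self, dhs: np.ndarray, cache, W: np.ndarray):
        h_dim = self.config.hidden_dim
        T = len(cache)
        d_in = W.shape[1] - h_dim
        dW = np.zeros_like(W)
        db = np.zeros(4 * h_dim)
        dxs = np.zeros((T, d_in))
        dh_next = np.zeros(h_dim)
        dc_next = np.zeros(h_dim)
        for t in range(T - 1, -1, -1):
            x, h_prev, c_prev, i, f, g, o, c_new = cache[t]
            dh = dhs[t] + dh_next
            tanh_c = np.tanh(c_new)
            do = dh * tanh_c
            dc = dh * o * (1 - tanh_c**2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g**2),
                    do * o * (1 - o),
                ]
            )
            inp = np.concatenate([x, h_prev])
            dW += np.outer(dz, inp)
            db += dz
            dinp = W.T @ dz
            dxs[t] = dinp[:d_in]
            dh_next = dinp[d_in:]
        return dW, db, dxs

    def _backward(self, cache, dlogit: float):
        P = self.params
        h_dim = self.config.hidden_dim
        idxs, xs, cache_f, cache_b, H, tanh_pre, a, context = cache
        g = {k: np.zeros_like(v) for k, v in P.items()}
        g["w_o"] = dlogit * context
        g["b_o"] = np.array([dlogit])
        dcontext = dlogit * P["w_o"]
        dH = np.outer(a, dcontext)
        da = H @ dcontext
        du = a * (da - float(a @ da))
        dtanh_pre = np.outer(du, P["v_a"]) * (1 - tanh_pre**2)
        g["v_a"] = tanh_pre.T @ du
        g["W_a"] = dtanh_pre.T @ H
        g["b_a"] = dtanh_pre.sum(axis=0)
        dH += dtanh_pre @ P["W_a"]
        dhs_f = dH[:, :h_dim]
        dhs_b = dH[:, h_dim:]
        dW_f, db_f, dxs_f = self._lstm_backward(dhs_f, cache_f, P["W_f"])
        dW_b, db_b, dxs_b_rev = self._lstm_backward(dhs_b[::-1], cache_b, P["W_b"])
        g["W_f"], g["bias_f"] = dW_f, db_f
        g["W_b"], g["bias_b"] = dW_b, db_b
        dxs = dxs_f + dxs_b_rev[::-1]
        np.add.at(g["E"], idxs, dxs)
        return g

    # -- training -----------------------------------------------------------
    def _encode(self, tokens: Sequence[str], grow: bool) -> np.ndarray:
        out = []
        for t in tokens:
            j = self.vocab.get(t)
            if j is None:
                if grow:
                    j = self.vocab[t] = len(self.vocab)
                else:
                    j = self.vocab[UNK]
            out.append(j)
        return np.asarray(out or [self.vocab[UNK]], dtype=int)

    def fit(self, examples: Sequence[TrainingExample], pretrained=None) -> "BiLSTMAttentionModel":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        seqs = [self._encode(e.tokens, grow=True) for e in examples]
        labels = np.array([e.soft_label for e in examples])
        self._init_params(rng, pretrained)
        m_t = {k: np.zeros_like(v) for k, v in self.params.items()}
        v_t = {k: np.zeros_like(v) for k, v in self.params.items()}
        step = 0
        b1, b2, eps = 0.9, 0.999, 1e-8
        for _epoch in range(cfg.epochs):
            order = rng.permutation(len(seqs))
            for start in range(0, len(seqs), cfg.batch_size):
                batch = order[start : start + cfg.batch_size]
                grads = {k: np.zeros_like(v) for k, v in self.params.items()}
                for i in batch:
                    yhat, cache = self._forward(seqs[i])
                    dlogit = (yhat - labels[i]) / len(batch)
                    for k, v in self._backward(cache, dlogit).items():
                        grads[k] += v
                step += 1
                for k in self.params:
                    gk = grads[k] + cfg.l2 * self.params[k]
                    m_t[k] = b1 * m_t[k] + (1 - b1) * gk
                    v_t[k] = b2 * v_t[k] + (1 - b2) * gk**2
                    mhat = m_t[k] / (1 - b1**step)
                    vhat = v_t[k] / (1 - b2**step)
                    self.params[k] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
        return self

    def score(self, token_streams: Sequence[Sequence[str]]) -> np.ndarray:
        return np.array(
            [self._forward(self._encode(toks, grow=False))[0] for toks in token_streams]
        )

    def loss(self, tokens: Sequence[str], soft_label: float) -> float:
        """Expected cross-entropy of one example (used for gradient checks)."""
        yhat, _ = self._forward(self._encode(tokens, grow=False))
        return expected_cross_entropy(soft_label, yhat)


# ---------------------------------------------------------------------------
# shared contract
# ---------------------------------------------------------------------------


def train_noise_aware(examples: Sequence[TrainingExample], config: ModelConfig | None = None):
    """Train the configured architecture on soft labels.

    Seeded and reproducible for a fixed config; raises on an empty
    training set.
    """
    if not examples:
        raise ValueError("empty training set")
    cfg = config or ModelConfig()
    model = (
        BagOfNgramsModel(cfg)
        if cfg.architecture == "bag_of_ngrams"
        else BiLSTMAttentionModel(cfg)
    )
    return model.fit(examples)


def predict(model, candidates: Sequence[CandidateRelation]) -> list[Prediction]:
    """Score candidates; decision is positive iff score >= threshold."""
    streams = [candidate_to_tokens(c) for c in candidates]
    scores = model.score(streams) if candidates else np.zeros(0)
    thr = model.config.threshold
    return [
        Prediction(c.candidate_id, float(s), "positive" if s >= thr else "negative")
        for c, s in zip(candidates, scores)
    ]


def predict_examples(model, examples: Sequence[TrainingExample]) -> list[Prediction]:
    """Score pre-built token streams (for evaluation against gold labels)."""
    scores = model.score([e.tokens for e in examples]) if examples else np.zeros(0)
    thr = model.config.threshold
    return [
        Prediction(e.candidate_id, float(s), "positive" if s >= thr else "negative")
        for e, s in zip(examples, scores)
    ]


def learning_curve(
    pool: Sequence[TrainingExample],
    sizes: Sequence[int],
    test_examples: Sequence[TrainingExample],
    test_truth: Sequence[int],
    config: ModelConfig | None = None,
):
    """AUPRC on a fixed test split as a function of training-pool size.

    Sizes are subsampled from the pool with the config seed; duplicated
    sizes are deduplicated with a warning; a size of 0 or larger than the
    pool is an error.
    """
    from .evaluation import pr_curve_auprc

    cfg = config or ModelConfig()
    uniq: list[int] = []
    for s in sizes:
        if s in uniq:
            warnings.warn(f"duplicate training size {s} ignored", stacklevel=2)
            continue
        uniq.append(s)
    rows = []
    rng = np.random.default_rng(cfg.seed)
    for size in uniq:
        if size <= 0 or size > len(pool):
            raise ValueError(f"training size {size} out of range (pool {len(pool)})")
        idx = rng.choice(len(pool), size=size, replace=False)
        model = train_noise_aware([pool[i] for i in idx], cfg)
        scores = model.score([e.tokens for e in test_examples])
        _, auprc = pr_curve_auprc(scores, test_truth)
        rows.append((size, auprc))
    return rows


def save_model(model, path) -> None:
    """Single-archive checkpoint: config + vocab JSON alongside weights."""
    meta = {"config": asdict(model.config), "vocab": model.vocab,
            "kind": type(model).__name__}
    if isinstance(model, BiLSTMAttentionModel):
        np.savez(path, meta=json.dumps(meta), **model.params)
    else:
        np.savez(
            path,
            meta=json.dumps(meta),
            coef=model.clf.coef_,
            intercept=model.clf.intercept_,
        )


def load_model(path):
    archive = np.load(path, allow_pickle=False)
    meta = json.loads(str(archive["meta"]))
    cfg = ModelConfig(**meta["config"])
    if meta["kind"] == "BiLSTMAttentionModel":
        model = BiLSTMAttentionModel(cfg)
        model.vocab = {k: int(v) for k, v in meta["vocab"].items()}
        model.params = {k: archive[k] for k in archive.files if k != "meta"}
        return model
    from sklearn.linear_model import LogisticRegression

    model = BagOfNgramsModel(cfg)
    model.vocab = {k: int(v) for k, v in meta["vocab"].items()}
    clf = LogisticRegression()
    clf.coef_ = archive["coef"]
    clf.intercept_ = archive["intercept"]
    clf.classes_ = np.array([0.0, 1.0])
    model.clf = clf
    return model
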