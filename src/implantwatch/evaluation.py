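"""Extraction-quality metrics and annotation agreement.

Reporting follows the conventions of surveillance-extraction tables:
percent scale, one decimal. Matching of predicted to gold mentions is
exact-span by default (identical offsets and types), with an overlap mode
for looser scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "prf",
    "match_mentions",
    "pr_curve_auprc",
    "fleiss_kappa",
    "relative_improvement",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


def prf(counts: ConfusionCounts) -> tuple[float, float, float, dict]:
    """Precision, recall, F1 on the percent scale, one decimal.

    Degenerate denominators (no predicted positives / no gold positives)
    report the undefined metric as 0.0 and set a flag instead of raising.
    """
    flags = {}
    if counts.tp + counts.fp > 0:
        p = counts.tp / (counts.tp + counts.fp)
    else:
        p, flags["precision_undefined"] = 0.0, True
    if counts.tp + counts.fn > 0:
        r = counts.tp / (counts.tp + counts.fn)
    else:
        r, flags["recall_undefined"] = 0.0, True
    f1 = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    return round(100 * p, 1), round(100 * r, 1), round(100 * f1, 1), flags


def match_mentions(
    predicted: Sequence[tuple],
    gold: Sequence[tuple],
    mode: str = "exact",
) -> ConfusionCounts:
    """Count tp/fp/fn between predicted and gold mention keys.

    Items are hashable keys, typically (note_id, span, type). ``exact``
    requires identical keys; ``overlap`` treats keys as
    (note_id, (start, end), type) and matches on any span overlap with
    equal note and type.
    """
    if mode == "exact":
        pset, gset = set(predicted), set(gold)
        tp = len(pset & gset)
        return ConfusionCounts(tp, len(pset) - tp, len(gset) - tp)
    if mode != "overlap":
        raise ValueError(f"unknown matching mode {mode!r}")
    gold_left = list(gold)
    tp = 0
    for p in predicted:
        for g in gold_left:
            if (
                p[0] == g[0]
                and p[2] == g[2]
                and p[1][0] < g[1][1]
                and g[1][0] < p[1][1]
            ):
                tp += 1
                gold_left.remove(g)
                break
    return ConfusionCounts(tp, len(predicted) - tp, len(gold) - tp)


def pr_curve_auprc(
    scores: Sequence[float], truth: Sequence[int]
) -> tuple[list[tuple[float, float]], float]:
    """Precision-recall curve and average precision (AUPRC).

    AUPRC is the step-wise integral sum_t P(t) * dR(t) over decision
    thresholds t taken at the distinct scores in descending order. Tied
    scores cannot be separated by any threshold, so they enter the curve
    as one group (the sort itself is stable on input order, making the
    returned curve deterministic). Requires at least one positive and one
    negative label.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    if truth.size == 0 or truth.min() == truth.max():
        raise ValueError("truth must contain both classes")
    order = np.argsort(-scores, kind="stable")
    y = truth[order]
    s = scores[order]
    n_pos = int(y.sum())
    # indices where a threshold can actually cut (end of each tie group)
    cut = np.nonzero(np.diff(s))[0]
    ends = np.concatenate([cut, [len(s) - 1]])
    tp = np.cumsum(y)[ends]
    k = ends + 1
    precision = tp / k
    recall = tp / n_pos
    curve = list(zip(recall.tolist(), precision.tolist()))
    d_recall = np.diff(np.concatenate([[0.0], recall]))
    auprc = float(np.sum(precision * d_recall))
    return curve, auprc


def fleiss_kappa(table) -> float:
    """Fleiss' kappa for a (items x categories) count table.

    Each row sums to the (constant) number of annotators. Observed
    agreement is the mean per-item pairwise agreement; chance agreement is
    the sum of squared category marginals. Invariant to item and category
    order. Raises if fewer than 2 categories are actually used.
    """
    T = np.asarray(table, dtype=float)
    if T.ndim != 2 or T.shape[0] < 2:
        raise ValueError("need a 2-D table with >= 2 items")
    n = T.sum(axis=1)
    if not np.all(n == n[0]) or n[0] < 2:
        raise ValueError("each item needs the same number (>= 2) of annotators")
    if int((T.sum(axis=0) > 0).sum()) < 2:
        raise ValueError("kappa undefined: fewer than 2 categories used")
    n = float(n[0])
    N = T.shape[0]
    p_j = T.sum(axis=0) / (N * n)
    P_i = (np.sum(T * (T - 1), axis=1)) / (n * (n - 1))
    P_bar = float(P_i.mean())
    P_e = float(np.sum(p_j**2))
    if P_e == 1.0:
        return 1.0
    return (P_bar - P_e) / (1 - P_e)


def relative_improvement(metric_a: float, metric_b: float) -> float:
    """Signed percent change of ``metric_a`` over baseline ``metric_b``,
    one decimal (e.g. F1 70.2 over baseline 45.6 -> +53.9)."""
    if metric_b <= 0:
        raise ValueError("baseline must be positive")
    return round(100.0 * (metric_a - metric_b) / metric_b, 1)
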