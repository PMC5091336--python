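"""Instance-level (CEMP) and passage-level (CPD) evaluation metrics.

CEMP scores exact-span chemical mention recognition with micro-averaged
precision, recall and F-score (percentages). CPD scores each title or
abstract passage as a binary "contains a chemical mention" decision with
sensitivity, specificity, accuracy and the Matthews correlation
coefficient.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from nerchem.corpus_io import Document, Mention
from nerchem.label_codec import compose_class


@dataclass(frozen=True)
class CempResult:
    true_positives: int
    false_positives: int
    false_negatives: int
    precision: float  # percent
    recall: float  # percent
    f_score: float  # percent

    def report(self) -> str:
        return (
            f"CEMP  TP={self.true_positives} FP={self.false_positives} "
            f"FN={self.false_negatives}  P={self.precision:.3f} "
            f"R={self.recall:.3f} F={self.f_score:.3f}"
        )


@dataclass(frozen=True)
class CpdResult:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float  # percent
    specificity: float  # percent
    accuracy: float  # percent
    mcc: float  # in [-1, 1]

    def report(self) -> str:
        return (
            f"CPD   TP={self.tp} FP={self.fp} TN={self.tn} FN={self.fn}  "
            f"Sens={self.sensitivity:.3f} Spec={self.specificity:.3f} "
            f"Acc={self.accuracy:.3f} MCC={self.mcc:.5f}"
        )


def _pct(num: float, den: float) -> float:
    return 100.0 * num / den if den else 0.0


def f_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (all on the percent scale)."""
    if precision < 0 or recall < 0:
        raise ValueError("precision and recall must be non-negative")
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def match_mentions(
    gold: Sequence[Mention], pred: Sequence[Mention], class_sensitive: bool = False
) -> tuple[int, int, int]:
    """One-to-one exact-span matching within a single document.

    A prediction is a true positive iff an unconsumed gold mention has the
    identical (passage, start, end) — and identical composed class when
    ``class_sensitive``. Duplicate predictions of one gold span yield one
    TP and one FP.
    """

    def key(m: Mention):
        base = (m.passage, m.start, m.end)
        if not class_sensitive:
            return base
        cls = m.composed_class or compose_class(m.raw_class)
        return base + (cls,)

    gold_counts = Counter(key(m) for m in gold)
    tp = 0
    for m in pred:
        k = key(m)
        if gold_counts.get(k, 0) > 0:
            gold_counts[k] -= 1
            tp += 1
    fp = len(pred) - tp
    fn = len(gold) - tp
    return tp, fp, fn


def cemp_from_counts(tp: int, fp: int, fn: int) -> CempResult:
    p = _pct(tp, tp + fp)
    r = _pct(tp, tp + fn)
    return CempResult(tp, fp, fn, precision=p, recall=r, f_score=f_score(p, r))


def cemp_evaluate(
    gold_docs: Sequence[Document],
    pred_docs: Sequence[Document],
    class_sensitive: bool = False,
) -> CempResult:
    """Micro-averaged CEMP over a corpus: counts are pooled over all
    documents before precision/recall are computed."""
    pred_by_id = {d.doc_id: d for d in pred_docs}
    if set(pred_by_id) != {d.doc_id for d in gold_docs}:
        raise ValueError("gold and predicted document sets differ")
    tp = fp = fn = 0
    for g in gold_docs:
        p = pred_by_id[g.doc_id]
        a, b, c = match_mentions(g.gold_mentions, p.predicted_mentions, class_sensitive)
        tp, fp, fn = tp + a, fp + b, fn + c
    return cemp_from_counts(tp, fp, fn)


def mcc_from_counts(tp: float, fp: float, tn: float, fn: float) -> float:
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom


def cpd_evaluate(
    gold_docs: Sequence[Document], pred_docs: Sequence[Document]
) -> CpdResult:
    """Passage-level detection: each title and each abstract is one binary
    instance, positive iff it contains at least one mention."""
    pred_by_id = {d.doc_id: d for d in pred_docs}
    if set(pred_by_id) != {d.doc_id for d in gold_docs}:
        raise ValueError("gold and predicted document sets differ")
    tp = fp = tn = fn = 0
    for g in gold_docs:
        p = pred_by_id[g.doc_id]
        for passage in ("T", "A"):
            has_gold = any(m.passage == passage for m in g.gold_mentions)
            has_pred = any(m.passage == passage for m in p.predicted_mentions)
            if has_gold and has_pred:
                tp += 1
            elif has_gold:
                fn += 1
            elif has_pred:
                fp += 1
            else:
                tn += 1
    total = tp + fp + tn + fn
    return CpdResult(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=_pct(tp, tp + fn),
        specificity=_pct(tn, tn + fp),
        accuracy=_pct(tp + tn, total),
        mcc=mcc_from_counts(tp, fp, tn, fn),
    )


def rate_consistency(
    sensitivity: float, specificity: float, accuracy: float
) -> tuple[float, dict[str, float]]:
    """Recover the positive-passage fraction and the normalized confusion
    matrix implied by (sensitivity, specificity, accuracy) percentages.

    With positive fraction p, accuracy = p*sens + (1-p)*spec, so
    p = (acc - spec) / (sens - spec). Useful for checking reported metric
    triples against each other; inconsistent triples (p outside [0, 1])
    raise.
    """
    if sensitivity == specificity:
        raise ValueError("sensitivity == specificity: positive fraction undetermined")
    p = (accuracy - specificity) / (sensitivity - specificity)
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"inconsistent rates: implied positive fraction {p:.4f}")
    s, sp = sensitivity / 100.0, specificity / 100.0
    matrix = {
        "TP": p * s,
        "FN": p * (1.0 - s),
        "TN": (1.0 - p) * sp,
        "FP": (1.0 - p) * (1.0 - sp),
    }
    return p, matrix


def mcc_from_rates(sensitivity: float, specificity: float, accuracy: float) -> float:
    """MCC implied by a (sens, spec, acc) percentage triple."""
    _, m = rate_consistency(sensitivity, specificity, accuracy)
    return mcc_from_counts(m["TP"], m["FP"], m["TN"], m["FN"])
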