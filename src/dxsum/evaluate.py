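"""Metrics and threshold calibration for extractive summaries.

Character-level metrics (ROC/AUROC, binary F1) score the per-character
selection probabilities pooled over a labeled set; the operating threshold
is the F1 maximizer over all distinct cleaned probabilities observed on a
validation set.  Word-level quality is measured with ROUGE-1/2 (clipped
n-gram overlap) and ROUGE-L (longest common subsequence) F1 between the
extracted summary and the label-derived reference summary, after lowering
case and stripping punctuation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from sklearn import metrics as _skm

from .summarize import cleanup, extract_summary, predict_probabilities, threshold_select
from .tokenizer import segment_units


@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray  # descending
    tpr: np.ndarray
    fpr: np.ndarray
    auroc: float


@dataclass(frozen=True)
class ScoreTriple:
    precision: float
    recall: float
    f1: float


def _f1(p: float, r: float) -> float:
    return 0.0 if p + r == 0 else 2 * p * r / (p + r)


def roc_auc(scores, labels) -> RocCurve:
    """ROC curve and AUROC (ties between classes count one half)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if labels.min() == labels.max():
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = _skm.roc_curve(labels, scores)
    return RocCurve(thresholds=thr, tpr=tpr, fpr=fpr,
                    auroc=float(_skm.roc_auc_score(labels, scores)))


def f1_binary(pred_mask, true_mask) -> ScoreTriple:
    """Character-level precision/recall/F1 with the 0/0 -> 0 convention."""
    pred = np.asarray([int(c) for c in pred_mask] if isinstance(pred_mask, str)
                      else pred_mask, dtype=np.int64)
    true = np.asarray([int(c) for c in true_mask] if isinstance(true_mask, str)
                      else true_mask, dtype=np.int64)
    if pred.size != true.size:
        raise ValueError("masks must have equal length")
    tp = int(((pred == 1) & (true == 1)).sum())
    fp = int(((pred == 1) & (true == 0)).sum())
    fn = int(((pred == 0) & (true == 1)).sum())
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    return ScoreTriple(p, r, _f1(p, r))


def best_f1_threshold(scores, labels) -> tuple[float, float]:
    """(threshold, F1) maximizing F1 over all distinct scores.

    Candidate thresholds are the distinct score values (selection uses >=,
    so each distinct value yields a distinct predicted set); ties in F1 are
    broken toward the larger threshold.  O(n log n).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if labels.min() == labels.max():
        raise ValueError("threshold calibration needs both classes present")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    npos = int(y.sum())
    tp_cum = np.cumsum(y)
    npred = np.arange(1, s.size + 1)
    # last index of each distinct score group = the predicted set for >= s
    is_boundary = np.empty(s.size, dtype=bool)
    is_boundary[:-1] = s[:-1] != s[1:]
    is_boundary[-1] = True
    idx = np.flatnonzero(is_boundary)
    f1 = 2.0 * tp_cum[idx] / (npred[idx] + npos)
    best = int(np.argmax(f1))  # first occurrence = largest threshold
    return float(s[idx[best]]), float(f1[best])


def choose_threshold(model, validation_set) -> float:
    """Calibrate the selection threshold on a labeled validation set.

    Pools cleaned per-character probabilities over the whole set and
    returns the F1-maximizing threshold.
    """
    scores, labels = _pooled_scores(model, validation_set)
    if len(scores) == 0:
        raise ValueError("validation set is empty or has no characters")
    threshold, _ = best_f1_threshold(scores, labels)
    return threshold


def _ngrams(words: list[str], n: int) -> Counter:
    return Counter(tuple(words[i:i + n]) for i in range(len(words) - n + 1))


def rouge_n(candidate_words: list[str], reference_words: list[str],
            n: int) -> ScoreTriple:
    """Clipped n-gram overlap precision/recall/F1."""
    if n < 1:
        raise ValueError("n must be >= 1")
    cand = _ngrams(candidate_words, n)
    ref = _ngrams(reference_words, n)
    n_cand = sum(cand.values())
    n_ref = sum(ref.values())
    if n_cand == 0 or n_ref == 0:
        return ScoreTriple(0.0, 0.0, 0.0)
    overlap = sum(min(c, ref[g]) for g, c in cand.items())
    p = overlap / n_cand
    r = overlap / n_ref
    return ScoreTriple(p, r, _f1(p, r))


def lcs_length(a: list[str], b: list[str]) -> int:
    """Longest-common-subsequence length by dynamic programming."""
    if not a or not b:
        return 0
    prev = np.zeros(len(b) + 1, dtype=np.int64)
    for x in a:
        cur = prev.copy()
        for j, y in enumerate(b, start=1):
            cur[j] = prev[j - 1] + 1 if x == y else max(cur[j - 1], prev[j])
        prev = cur
    return int(prev[-1])


def rouge_l(candidate_words: list[str], reference_words: list[str]) -> ScoreTriple:
    """LCS-based precision/recall/F1 over words."""
    if not candidate_words or not reference_words:
        return ScoreTriple(0.0, 0.0, 0.0)
    lcs = lcs_length(candidate_words, reference_words)
    p = lcs / len(candidate_words)
    r = lcs / len(reference_words)
    return ScoreTriple(p, r, _f1(p, r))


_PUNCT_STRIP = {c: " " for c in r"""!"#$%&'()*+,-./:;<=>?@[\]^_`{|}~°±×÷§"""}


def tokenize_for_rouge(text: str) -> list[str]:
    """Lowercase, strip punctuation, split on whitespace."""
    return text.lower().translate(str.maketrans(_PUNCT_STRIP)).split()


def _cleaned_per_record(model, records) -> list[np.ndarray]:
    """Cleaned per-character probabilities for each non-empty record."""
    predict = model if callable(model) else None
    cleans = []
    for rec in records:
        if rec.label is None:
            raise ValueError("evaluation records must be labeled")
        if not rec.text:
            continue
        raw = predict(rec.text) if predict else predict_probabilities(model, rec.text)
        cleans.append(cleanup(np.asarray(raw, dtype=np.float64),
                              segment_units(rec.text)))
    return cleans


def _pooled_scores(model, records) -> tuple[np.ndarray, np.ndarray]:
    """Cleaned probabilities and labels pooled over all characters."""
    cleans = _cleaned_per_record(model, records)
    labels = [np.array([int(c) for c in rec.label], dtype=np.int64)
              for rec in records if rec.text and rec.label is not None]
    if not cleans:
        return np.zeros(0), np.zeros(0, dtype=np.int64)
    return np.concatenate(cleans), np.concatenate(labels)


def evaluate_model(model, test_set, threshold: float) -> dict:
    """Pooled character AUROC plus per-record ROUGE-1/2/L of the summaries.

    ``model`` is a fitted network (or checkpoint path handled by
    predict_probabilities) or any callable text -> per-character
    probabilities.  The reference summary of each record is the extraction
    induced by its true label mask.
    """
    test_set = list(test_set)
    if not test_set:
        raise ValueError("test set is empty")
    cleans = _cleaned_per_record(model, test_set)
    labels = [np.array([int(c) for c in rec.label], dtype=np.int64)
              for rec in test_set if rec.text]
    curve = roc_auc(np.concatenate(cleans), np.concatenate(labels))
    per_record = []
    for rec, clean in zip([r for r in test_set if r.text], cleans):
        mask = threshold_select(clean, threshold)
        cand = tokenize_for_rouge(extract_summary(rec.text, mask))
        ref = tokenize_for_rouge(extract_summary(rec.text, rec.label))
        per_record.append({
            "rouge1": rouge_n(cand, ref, 1).f1,
            "rouge2": rouge_n(cand, ref, 2).f1,
            "rougeL": rouge_l(cand, ref).f1,
        })
    return {
        "auroc": curve.auroc,
        "threshold": threshold,
        "n_records": len(per_record),
        "rouge1_f1": float(np.mean([r["rouge1"] for r in per_record])),
        "rouge2_f1": float(np.mean([r["rouge2"] for r in per_record])),
        "rougeL_f1": float(np.mean([r["rougeL"] for r in per_record])),
        "per_record": per_record,
    }
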