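"""Weighted token-overlap scoring of M gold answers against N model answers.

Classic SQuAD-style token F1 compares one gold answer with one model
answer.  Once questions may carry several gold answers and a model may
return several spans, partial credit needs an M-to-N matching rule:

* anchoring on each gold answer g, pick the model answer m* sharing the
  most tokens with it; the shared token count accrues to the weighted
  true positives (wTP) and g's unmatched tokens to the weighted false
  negatives (wFN);
* anchoring on each model answer m, pick the gold answer g* sharing the
  most tokens; m's unmatched tokens accrue to the weighted false
  positives (wFP).

Pooling wTP/wFN/wFP over a question set gives micro precision
P = wTP/(wTP+wFP), recall R = wTP/(wTP+wFN), and F1 = 2PR/(P+R).

Unanswerable questions must contribute to the pooled counts, so
abstention is scored with a one-token sentinel: correct abstention adds
one true positive token; answering a question with no gold answer adds
one false negative plus every produced token as false positives.

Tokenization follows the SQuAD evaluation convention: lowercase, strip
punctuation, drop the articles a/an/the, split on whitespace.
"""

from __future__ import annotations

import re
import string
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

_PUNCT = set(string.punctuation)
_ARTICLES = re.compile(r"\b(a|an|the)\b")


def normalize_tokens(text: str) -> list[str]:
    """Lowercase, strip punctuation characters, drop articles, split."""
    lowered = text.lower()
    no_punct = "".join(ch for ch in lowered if ch not in _PUNCT)
    no_articles = _ARTICLES.sub(" ", no_punct)
    return no_articles.split()


@dataclass
class EvalCounts:
    wTP: float = 0.0
    wFN: float = 0.0
    wFP: float = 0.0

    def __iadd__(self, other: "EvalCounts") -> "EvalCounts":
        self.wTP += other.wTP
        self.wFN += other.wFN
        self.wFP += other.wFP
        return self

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(self.wTP + other.wTP, self.wFN + other.wFN, self.wFP + other.wFP)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.wTP, self.wFN, self.wFP)


def _coerce(answers: Iterable) -> list[tuple[str, int]]:
    out = []
    for a in answers:
        if isinstance(a, tuple):
            text, start = a
        elif isinstance(a, dict):
            text, start = a["text"], a["answer_start"]
        else:
            text, start = a.text, a.answer_start
        out.append((str(text), int(start)))
    return out


def _dedupe(answers: list[tuple[str, int]]) -> list[tuple[str, int]]:
    # dedupe by normalized token string, keeping the smallest offset
    best: dict[tuple[str, ...], tuple[str, int]] = {}
    for text, start in sorted(answers, key=lambda a: a[1]):
        key = tuple(normalize_tokens(text))
        best.setdefault(key, (text, start))
    return sorted(best.values(), key=lambda a: a[1])


def _overlap(c1: Counter, c2: Counter) -> int:
    return sum((c1 & c2).values())


def score_question(
    gold_answers: Iterable, model_answers: Iterable, dedupe: bool = True
) -> EvalCounts:
    """Weighted TP/FN/FP for one question.

    Answers are (text, answer_start) pairs (or any objects with ``.text``
    and ``.answer_start``); an empty set encodes abstention/unanswerable.
    Ties in the most-overlapping-tokens argmax break toward the answer
    with the smaller original offset.
    """
    gold = _coerce(gold_answers)
    model = _coerce(model_answers)
    if dedupe:
        gold, model = _dedupe(gold), _dedupe(model)

    counts = EvalCounts()
    gold_toks = [(Counter(normalize_tokens(t)), s) for t, s in gold]
    model_toks = [(Counter(normalize_tokens(t)), s) for t, s in model]

    if not gold_toks and not model_toks:
        counts.wTP += 1.0  # sentinel token: correct abstention
        return counts
    if not gold_toks:
        counts.wFN += 1.0  # missed the abstention sentinel
        counts.wFP += sum(sum(c.values()) for c, _ in model_toks)
        return counts
    if not model_toks:
        counts.wFN += sum(sum(c.values()) for c, _ in gold_toks)
        return counts

    for g, _ in gold_toks:
        best = max(model_toks, key=lambda m: (_overlap(g, m[0]), -m[1]))
        shared = _overlap(g, best[0])
        counts.wTP += shared
        counts.wFN += sum(g.values()) - shared
    for m, _ in model_toks:
        best = max(gold_toks, key=lambda g: (_overlap(m, g[0]), -g[1]))
        counts.wFP += sum(m.values()) - _overlap(m, best[0])
    return counts


# ---------------------------------------------------------------------------
# Aggregation


@dataclass
class QuestionRecord:
    counts: EvalCounts
    is_impossible: bool
    n_answers: int
    n_drugs: int


@dataclass
class SliceMetrics:
    precision: float
    recall: float
    f1: float
    n_questions: int
    counts: EvalCounts


@dataclass
class EvalReport:
    precision: float
    recall: float
    f1: float
    counts: EvalCounts
    slices: dict[str, SliceMetrics] = field(default_factory=dict)


def _metrics(counts: EvalCounts) -> tuple[float, float, float]:
    p = counts.wTP / (counts.wTP + counts.wFP) if counts.wTP + counts.wFP > 0 else 0.0
    r = counts.wTP / (counts.wTP + counts.wFN) if counts.wTP + counts.wFN > 0 else 0.0
    f1 = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return p, r, f1


_SLICE_PREDICATES = {
    "full": lambda q: True,
    "unanswerable": lambda q: q.is_impossible,
    "single_answer": lambda q: not q.is_impossible and q.n_answers == 1,
    "multi_answer": lambda q: not q.is_impossible and q.n_answers >= 2,
    "single_drug": lambda q: not q.is_impossible and q.n_drugs == 1,
    "multi_drug": lambda q: not q.is_impossible and q.n_drugs >= 2,
}


def aggregate(records: Sequence[QuestionRecord]) -> EvalReport:
    """Micro-pooled precision/recall/F1 for the full set and each slice
    (unanswerable, single/multi-answer, single/multi-drug); empty slices
    are absent from the report, not reported as zero."""
    slices: dict[str, SliceMetrics] = {}
    for name, pred in _SLICE_PREDICATES.items():
        members = [q for q in records if pred(q)]
        if not members:
            continue
        pooled = EvalCounts()
        for q in members:
            pooled += q.counts
        p, r, f1 = _metrics(pooled)
        slices[name] = SliceMetrics(p, r, f1, len(members), pooled)
    full = slices.get("full", SliceMetrics(0.0, 0.0, 0.0, 0, EvalCounts()))
    return EvalReport(full.precision, full.recall, full.f1, full.counts, slices)


def macro_f1(records: Sequence[QuestionRecord]) -> float:
    """Mean of per-question F1 (available for sensitivity analysis; the
    primary report micro-pools counts)."""
    if not records:
        return 0.0
    return sum(_metrics(q.counts)[2] for q in records) / len(records)


# ---------------------------------------------------------------------------
# Independent oracle


def brute_force_oracle(
    gold_answers: Iterable, model_answers: Iterable, dedupe: bool = True
) -> EvalCounts:
    """Recompute :func:`score_question` by exhaustive enumeration.

    Builds the full pairwise overlap matrix with a sorted-list two-pointer
    token matcher (no Counter arithmetic) and walks every anchor choice
    explicitly.  Capped at 6 answers per side.
    """
    gold = _coerce(gold_answers)
    model = _coerce(model_answers)
    if dedupe:
        gold, model = _dedupe(gold), _dedupe(model)
    if len(gold) > 6 or len(model) > 6:
        raise ValueError("oracle capped at 6 answers per side")

    def toks(text: str) -> list[str]:
        return sorted(normalize_tokens(text))

    def shared(t1: list[str], t2: list[str]) -> int:
        i = j = n = 0
        while i < len(t1) and j < len(t2):
            if t1[i] == t2[j]:
                n += 1
                i += 1
                j += 1
            elif t1[i] < t2[j]:
                i += 1
            else:
                j += 1
        return n

    counts = EvalCounts()
    if not gold and not model:
        return EvalCounts(wTP=1.0)
    if not gold:
        return EvalCounts(wFN=1.0, wFP=float(sum(len(toks(t)) for t, _ in model)))
    if not model:
        return EvalCounts(wFN=float(sum(len(toks(t)) for t, _ in gold)))

    matrix = [[shared(toks(gt), toks(mt)) for mt, _ in model] for gt, _ in gold]
    for gi, (gt, _) in enumerate(gold):
        best_j, best_val = None, -1
        for mj in range(len(model)):
            val = matrix[gi][mj]
            if val > best_val or (val == best_val and model[mj][1] < model[best_j][1]):
                best_j, best_val = mj, val
        counts.wTP += best_val
        counts.wFN += len(toks(gt)) - best_val
    for mj, (mt, _) in enumerate(model):
        best_i, best_val = None, -1
        for gi in range(len(gold)):
            val = matrix[gi][mj]
            if val > best_val or (val == best_val and gold[gi][1] < gold[best_i][1]):
                best_i, best_val = gi, val
        counts.wFP += len(toks(mt)) - best_val
    return counts
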