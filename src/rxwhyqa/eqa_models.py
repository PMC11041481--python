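"""Single-answer extractive-QA model contract, plus two implementations.

The masking driver only needs one behavior from a model: given a
question, the drug name(s) it asks about, and a (possibly masked)
context, either return the single best answer span with a confidence
score, or refrain.  That contract is deliberately minimal so that a
rule-based system, a scripted test double, or a transformer fine-tuned
elsewhere can all sit behind it.

Provided here:

* :class:`PatternBaseline` — a rule-based answerer built on the four
  contextual trigger families seen around drug-reason pairs ("started
  on", "prn", "given for", "managed with").  The drug anchor comes from
  the question's ``_mname`` payload rather than re-parsing the question.
* :class:`ScriptedMock` — replays a script exactly, for testing the
  masking loop; it fails loudly on any unscripted call.
* :func:`calibrate_no_answer_threshold` — picks the refrain threshold
  maximizing F1 on a development set.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Protocol, Sequence, runtime_checkable

from rxwhyqa.qa_builder import QAEntry, Document


class _Refrain:
    """Sentinel: the model declines to answer."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover
        return "REFRAIN"


REFRAIN = _Refrain()


@dataclass(frozen=True)
class ModelAnswer:
    text: str
    answer_start: int
    score: float


@runtime_checkable
class Answerer(Protocol):
    def answer(
        self,
        question: str,
        drug_names: Sequence[str],
        context: str,
        no_answer_threshold: float = 0.0,
        qa_id: str | None = None,
    ) -> ModelAnswer | _Refrain: ...


class ContractViolation(RuntimeError):
    """An answerer returned a span that does not verify against its context."""


def verify_model_answer(context: str, answer: ModelAnswer) -> None:
    got = context[answer.answer_start : answer.answer_start + len(answer.text)]
    if got != answer.text:
        raise ContractViolation(
            f"answer text {answer.text!r} != context slice {got!r} at {answer.answer_start}"
        )


def load_stopwords() -> frozenset[str]:
    raw = resources.files("rxwhyqa.data").joinpath("stopwords.txt").read_text("utf-8")
    return frozenset(w.strip().lower() for w in raw.splitlines() if w.strip())


# ---------------------------------------------------------------------------
# Pattern baseline

_WORD = re.compile(r"\S+")

# Capture templates mirroring the four trigger families.  {drug} is the
# escaped drug name; the reason slot is a lazy 1-6 token capture.  The
# bare "for" in the prn family admits the elliptical form of
# "as needed for" ("morphine for pain").
# doubled braces survive str.format when the drug name is substituted
_ANS = r"(?P<ans>\w[\w/-]*(?:[^\S\n]\w[\w/-]*){{0,5}}?)"
_CAPTURE_TEMPLATES: list[tuple[str, int, str]] = [
    (
        "reason_started_on_drug",
        25,
        _ANS
        + r"\s+(?:was\s+|were\s+|being\s+)?"
        r"(?:received|started|restarted|required|maintained|continued?)"
        r"(?:\s+on)?\s+(?:\S+\s+){{0,3}}?{drug}\b",
    ),
    (
        "drug_prn_reason",
        18,
        r"{drug}\b\W*(?:\S+\s+){{0,12}}?(?:prn|as\s+needed\s+for|for)\s+" + _ANS + r"\b",
    ),
    (
        "drug_given_for_reason",
        14,
        r"{drug}\b\W*(?:\S+\s+){{0,12}}?(?:was\s+)?(?:attempted|given|dosing|taking)"
        r"\s+for\s+(?:any\s+)?(?:(?:possible|likely|presumed)\s+)?" + _ANS + r"\b",
    ),
    (
        "reason_managed_with_drug",
        13,
        _ANS
        + r"\s+(?:was\s+|were\s+)?"
        r"(?:managed|treated|improved|recommended|downtrended|resolved|reversed|needed)"
        r"\s+with\s+(?:\S+\s+){{0,3}}?{drug}\b",
    ),
]


@dataclass
class PatternBaseline:
    """Rule-based answerer over the contextual trigger families.

    For each drug name it scans the sentences containing that name,
    applies the family capture patterns, trims the captured reason span
    of leading/trailing stopwords, punctuation, and mask characters, and
    scores each surviving candidate with the family's priority weight.
    The highest-scoring candidate wins; ties break toward the earliest
    offset.  It refrains when no candidate survives or the best score
    falls below the no-answer threshold.
    """

    mask_char: str = "_"
    max_answer_tokens: int = 6
    stopwords: frozenset[str] = field(default_factory=load_stopwords)

    def _candidates(self, drug: str, context: str) -> list[ModelAnswer]:
        from rxwhyqa.corpus_stats import split_sentences

        out: dict[tuple[int, str], float] = {}
        for sent_start, sent_end in split_sentences(context):
            sentence = context[sent_start:sent_end]
            if drug.lower() not in sentence.lower():
                continue
            for _pid, weight, template in _CAPTURE_TEMPLATES:
                rx = re.compile(template.format(drug=re.escape(drug)), re.IGNORECASE)
                for m in rx.finditer(sentence):
                    span = self._trim(sentence, m.start("ans"), m.end("ans"))
                    if span is None:
                        continue
                    a, b = span
                    key = (sent_start + a, sentence[a:b])
                    out[key] = max(out.get(key, 0.0), float(weight))
        return [ModelAnswer(text=t, answer_start=o, score=s) for (o, t), s in out.items()]

    def _trim(self, sentence: str, a: int, b: int) -> tuple[int, int] | None:
        tokens = [(m.start() + a, m.end() + a, m.group()) for m in _WORD.finditer(sentence[a:b])]
        strip = lambda w: w.strip(".,;:!?()[]\"'")  # noqa: E731
        while tokens and (
            strip(tokens[0][2]).lower() in self.stopwords
            or not strip(tokens[0][2])
            or set(strip(tokens[0][2])) == {self.mask_char}
        ):
            tokens.pop(0)
        while tokens and (
            strip(tokens[-1][2]).lower() in self.stopwords
            or not strip(tokens[-1][2])
            or set(strip(tokens[-1][2])) == {self.mask_char}
        ):
            tokens.pop()
        if not tokens:
            return None
        start, end = tokens[0][0], tokens[-1][1]
        while end > start and sentence[end - 1] in ".,;:!?()[]\"'":
            end -= 1
        text = sentence[start:end]
        if not text or set(text) <= {self.mask_char, " "}:
            return None
        return start, end

    def answer(
        self,
        question: str,
        drug_names: Sequence[str],
        context: str,
        no_answer_threshold: float = 0.0,
        qa_id: str | None = None,
    ) -> ModelAnswer | _Refrain:
        if not drug_names:
            raise ValueError("drug_names must be nonempty")
        candidates: list[ModelAnswer] = []
        for drug in drug_names:
            candidates.extend(self._candidates(drug, context))
        if not candidates:
            return REFRAIN
        best = max(candidates, key=lambda c: (c.score, -c.answer_start))
        if best.score < no_answer_threshold:
            return REFRAIN
        return best


# ---------------------------------------------------------------------------
# Scripted mock


class ScriptError(KeyError):
    """The mock was driven outside its script."""


class ScriptedMock:
    """Replays a per-question script of answers; round index is implicit.

    ``script`` maps qa_id to a list of steps, one per call in order; each
    step is ``None`` (refrain), an answer string located case-insensitively
    in the current context, or a ``{"text", "answer_start"}`` mapping
    verified against the current context.  Any unscripted qa_id, extra
    call, or unlocatable answer raises :class:`ScriptError`.
    """

    def __init__(self, script: Mapping[str, Sequence]):
        self.script = {k: list(v) for k, v in script.items()}
        self.calls: dict[str, int] = {}

    def answer(
        self,
        question: str,
        drug_names: Sequence[str],
        context: str,
        no_answer_threshold: float = 0.0,
        qa_id: str | None = None,
    ) -> ModelAnswer | _Refrain:
        if qa_id is None or qa_id not in self.script:
            raise ScriptError(f"unscripted question {qa_id!r}")
        i = self.calls.get(qa_id, 0)
        self.calls[qa_id] = i + 1
        steps = self.script[qa_id]
        if i >= len(steps):
            raise ScriptError(f"{qa_id}: call {i} beyond scripted {len(steps)} steps")
        step = steps[i]
        if step is None:
            return REFRAIN
        if isinstance(step, str):
            pos = context.lower().find(step.lower())
            if pos < 0:
                raise ScriptError(f"{qa_id}: scripted answer {step!r} absent from context")
            return ModelAnswer(text=context[pos : pos + len(step)], answer_start=pos, score=1.0)
        answer = ModelAnswer(
            text=step["text"], answer_start=step["answer_start"], score=float(step.get("score", 1.0))
        )
        verify_model_answer(context, answer)
        return answer


def scripted_mock(script: Mapping[str, Sequence]) -> ScriptedMock:
    return ScriptedMock(script)


# ---------------------------------------------------------------------------
# No-answer threshold calibration


def calibrate_no_answer_threshold(
    answerer: Answerer,
    dev_entries: Sequence[QAEntry],
    documents: Iterable[Document],
    grid: Sequence[float],
) -> float:
    """Grid value maximizing single-round (no masking) micro F1 on the dev
    set; ties break toward the larger (more conservative) threshold.

    Exploits contract determinism: the answerer runs once per question
    with an unreachable low threshold, and each grid value is applied to
    the recorded best score.
    """
    from rxwhyqa import mn_eval

    if not grid:
        raise ValueError("threshold grid is empty")
    docs = {d.doc_id: d for d in documents}
    raw: list[tuple[QAEntry, ModelAnswer | _Refrain]] = []
    for e in dev_entries:
        got = answerer.answer(
            e.question, e.drug_names, docs[e.doc_id].text,
            no_answer_threshold=float("-inf"), qa_id=e.qa_id,
        )
        if isinstance(got, ModelAnswer):
            verify_model_answer(docs[e.doc_id].text, got)
        raw.append((e, got))

    best_t, best_f1 = None, -1.0
    for t in sorted(grid):
        records = []
        for e, got in raw:
            model = (
                [(got.text, got.answer_start)]
                if isinstance(got, ModelAnswer) and got.score >= t
                else []
            )
            gold = [(a.text, a.answer_start) for a in e.answers]
            records.append(
                mn_eval.QuestionRecord(
                    counts=mn_eval.score_question(gold, model),
                    is_impossible=e.is_impossible,
                    n_answers=len(e.distinct_answer_strings),
                    n_drugs=len(e.drug_names),
                )
            )
        f1 = mn_eval.aggregate(records).f1
        if f1 >= best_f1:  # >= so ties move toward larger thresholds
            best_t, best_f1 = t, f1
    return best_t
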