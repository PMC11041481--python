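"""Incremental answer masking: make a single-answer model yield many answers.

The loop is the three-step heuristic: (1) let the model extract its
usual top answer; (2) replace every case-insensitive occurrence of that
answer in the question's working copy of the note with underscores of
identical length; (3) run the model again on the masked text, repeating
until a full round produces no new answer anywhere (or a safety cap).

Masking is per question: one document serves many questions, and
masking a shared copy would corrupt other questions' evidence.  Because
the mask preserves length, offsets found in the masked context are valid
coordinates in the original text, and recorded answers are reported in
original-text coordinates.

Novelty is judged on lowercased, whitespace-collapsed strings.  Answers
consisting only of mask characters (a model "clinging" to the masked
span) are excluded from the record but terminate that question's loop,
preventing infinite cycling; a flag keeps them for replication studies.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from rxwhyqa.eqa_models import (
    Answerer,
    ContractViolation,
    ModelAnswer,
    REFRAIN,
    verify_model_answer,
)
from rxwhyqa.qa_builder import Document, QAEntry

logger = logging.getLogger(__name__)

_WS = re.compile(r"\s+")


@dataclass
class MaskingConfig:
    max_rounds: int = 10
    mask_char: str = "_"
    no_answer_threshold: float = 0.0
    keep_mask_only_answers: bool = False

    def __post_init__(self):
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")
        if len(self.mask_char) != 1:
            raise ValueError("mask_char must be a single character")


def mask_answer(context: str, answer_text: str, mask_char: str = "_") -> str:
    """Replace every case-insensitive, non-overlapping (left-to-right)
    occurrence of *answer_text* with mask characters of identical length.

    An answer consisting only of mask characters is a no-op (returned
    unchanged and logged) — masking it again would never change the text.
    """
    if not answer_text:
        raise ValueError("answer_text must be nonempty")
    if set(answer_text) <= {mask_char}:
        logger.info("mask_answer: answer is mask-only, context unchanged")
        return context
    haystack = context.lower()
    needle = answer_text.lower()
    out = []
    pos = 0
    while True:
        hit = haystack.find(needle, pos)
        if hit < 0:
            out.append(context[pos:])
            break
        out.append(context[pos:hit])
        out.append(mask_char * len(answer_text))
        pos = hit + len(answer_text)
    return "".join(out)


@dataclass
class QuestionState:
    qa_id: str
    original: str
    context: str
    answers: list[tuple[str, int]] = field(default_factory=list)
    frozen: bool = False
    freeze_reason: str | None = None

    def recorded_keys(self) -> set[str]:
        return {_WS.sub(" ", t.lower()).strip() for t, _ in self.answers}


@dataclass
class RoundStat:
    round_index: int
    novel_answers: int
    newly_masked_chars: int


@dataclass
class RunState:
    rounds: list[RoundStat] = field(default_factory=list)
    cap_hit: bool = False
    states: dict[str, QuestionState] = field(default_factory=dict)


@dataclass
class MaskingResult:
    answers: dict[str, list[tuple[str, int]]]
    state: RunState


def extract_multi_answers(
    answerer: Answerer,
    entries: Sequence[QAEntry],
    documents: Iterable[Document],
    config: MaskingConfig | None = None,
) -> MaskingResult:
    """Drive *answerer* through the incremental-masking loop.

    Returns every question's ordered answers in original-text
    coordinates; a question where the model never answered maps to an
    empty list (the explicit no-answer marker).  Raises
    :class:`~rxwhyqa.eqa_models.ContractViolation` naming the qa_id and
    round when the answerer returns a span that does not verify against
    the masked context it was given.
    """
    config = config or MaskingConfig()
    docs = {d.doc_id: d for d in documents}
    run = RunState()
    for e in entries:
        text = docs[e.doc_id].text
        run.states[e.qa_id] = QuestionState(qa_id=e.qa_id, original=text, context=text)

    for round_index in range(config.max_rounds):
        novel = 0
        masked_chars = 0
        for e in entries:
            state = run.states[e.qa_id]
            if state.frozen:
                continue
            got = answerer.answer(
                e.question,
                e.drug_names,
                state.context,
                no_answer_threshold=config.no_answer_threshold,
                qa_id=e.qa_id,
            )
            if got is REFRAIN:
                state.frozen = True
                state.freeze_reason = "refrain"
                continue
            assert isinstance(got, ModelAnswer)
            try:
                verify_model_answer(state.context, got)
            except ContractViolation as exc:
                raise ContractViolation(f"{e.qa_id} round {round_index}: {exc}") from exc
            key = _WS.sub(" ", got.text.lower()).strip()
            mask_only = not key.replace(config.mask_char, "").strip()
            if mask_only:
                if config.keep_mask_only_answers:
                    state.answers.append((got.text, got.answer_start))
                state.frozen = True
                state.freeze_reason = "mask_only"
                continue
            if key in state.recorded_keys():
                state.frozen = True
                state.freeze_reason = "repeat"
                continue
            state.answers.append((got.text, got.answer_start))
            new_context = mask_answer(state.context, got.text, config.mask_char)
            masked_chars += sum(
                1 for old, new in zip(state.context, new_context) if old != new
            )
            state.context = new_context
            novel += 1
        run.rounds.append(RoundStat(round_index, novel, masked_chars))
        if novel == 0:
            break
    else:
        # loop exhausted max_rounds with the last round still productive
        if run.rounds and run.rounds[-1].novel_answers > 0:
            run.cap_hit = True

    answers = {qa_id: list(s.answers) for qa_id, s in run.states.items()}
    return MaskingResult(answers=answers, state=run)


@dataclass
class TerminationCertificate:
    rounds: list[RoundStat]
    cap_hit: bool
    ok: bool
    total_masked_chars: int


def termination_certificate(run: MaskingResult | RunState) -> TerminationCertificate:
    """Machine-checked termination argument for a completed run.

    Every continuing round must have masked at least one new character;
    since masking is monotone and length-preserving, the number of rounds
    is then bounded by the context length.  A run stopped by the round
    cap is flagged rather than failed.
    """
    state = run.state if isinstance(run, MaskingResult) else run
    continuing = state.rounds[:-1] if state.rounds else []
    ok = all(r.newly_masked_chars > 0 for r in continuing)
    if state.rounds and state.rounds[-1].novel_answers > 0 and not state.cap_hit:
        ok = False  # a productive final round is only legal at the cap
    return TerminationCertificate(
        rounds=list(state.rounds),
        cap_hit=state.cap_hit,
        ok=ok,
        total_masked_chars=sum(r.newly_masked_chars for r in state.rounds),
    )
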