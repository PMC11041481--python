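"""Group drug->reason relations and emit SQuAD-2.0-style QA entries.

Five relation categories drive the conversion:

================  =============================================
1 drug, 0 reason  unanswerable entry (``is_impossible: true``)
1 drug, 1 reason  plain 1-to-1 entry
1 drug, N reasons one entry listing all N reasons as answers
N drugs, 1 reason N split 1-to-1 entries and/or one combined
                  multidrug entry ("Why were A, B, and C ...")
M drugs, N reasons split 1-to-N entries and/or one combined
                  multidrug multi-answer entry
================  =============================================

Drug identity is the lowercased surface string; nothing stronger (no
brand/generic merging) because that would require a drug lexicon.
Duplicate answer strings at distinct character offsets are deliberately
retained: a reason like "pain" annotated at three places yields three
answer spans so models can learn positional nuance.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping, Sequence

from rxwhyqa.annotation_io import (
    AnnotationSet,
    ConceptMention,
    ConceptType,
    Document,
)


class Category(str, Enum):
    ONE_DRUG_NO_REASON = "ONE_DRUG_NO_REASON"
    ONE_TO_ONE = "ONE_TO_ONE"
    ONE_TO_N = "ONE_TO_N"
    N_TO_ONE = "N_TO_ONE"
    M_TO_N = "M_TO_N"


@dataclass(frozen=True)
class QuestionGroup:
    doc_id: str
    drug_terms: tuple[str, ...]
    drug_mentions: tuple[ConceptMention, ...]
    reason_mentions: tuple[ConceptMention, ...]
    category: Category

    @property
    def distinct_reason_strings(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for m in self.reason_mentions:
            seen.setdefault(m.surface_text.lower(), None)
        return tuple(seen)


@dataclass(frozen=True)
class AnswerSpan:
    text: str
    answer_start: int


@dataclass(frozen=True)
class QAEntry:
    qa_id: str
    doc_id: str
    question: str
    drug_names: tuple[str, ...]
    is_impossible: bool
    answers: tuple[AnswerSpan, ...]
    category: Category | None = None

    @property
    def distinct_answer_strings(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for a in self.answers:
            seen.setdefault(a.text.lower(), None)
        return tuple(seen)


# ---------------------------------------------------------------------------
# Question templates


@dataclass(frozen=True)
class QuestionTemplate:
    singular: str
    plural: str


def load_templates(path=None) -> list[QuestionTemplate]:
    """Load question templates (singular TAB plural per line, '#' comments).

    With no path, the packaged default file (the two canonical forms as a
    single template) is used.
    """
    if path is None:
        raw = resources.files("rxwhyqa.data").joinpath("templates.txt").read_text("utf-8")
    else:
        from pathlib import Path

        raw = Path(path).read_text(encoding="utf-8")
    templates = []
    for line in raw.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        singular, _, plural = line.partition("\t")
        templates.append(QuestionTemplate(singular.strip(), (plural or singular).strip()))
    if not templates:
        raise ValueError("template file contains no templates")
    return templates


def _join_terms(terms: Sequence[str]) -> str:
    if len(terms) == 1:
        return terms[0]
    if len(terms) == 2:
        return f"{terms[0]} and {terms[1]}"
    return ", ".join(terms[:-1]) + f", and {terms[-1]}"


def render_question(
    drug_terms: Sequence[str], templates: Sequence[QuestionTemplate] | None = None
) -> list[str]:
    """Render one question string per template (canonical template first).

    One drug uses the singular form; two or more use the plural form with
    an "A, B, and C" conjunction (two terms drop the comma).
    """
    if not drug_terms:
        raise ValueError("drug_terms must be nonempty")
    templates = list(templates) if templates is not None else load_templates()
    joined = _join_terms(list(drug_terms))
    out = []
    for t in templates:
        pattern = t.singular if len(drug_terms) == 1 else t.plural
        out.append(pattern.format(drugs=joined))
    return out


# ---------------------------------------------------------------------------
# Grouping


def _single_drug_category(n_distinct_reasons: int) -> Category:
    if n_distinct_reasons == 0:
        return Category.ONE_DRUG_NO_REASON
    if n_distinct_reasons == 1:
        return Category.ONE_TO_ONE
    return Category.ONE_TO_N


def group_relations(ann: AnnotationSet) -> list[QuestionGroup]:
    """Build single-drug and multidrug question groups for one document.

    Each distinct normalized drug string yields one single-drug group
    collecting every reason mention related to any mention of that drug.
    Additionally, every maximal set of >= 2 drug terms whose distinct
    reason-string sets are identical and nonempty yields one multidrug
    group (N_TO_ONE for a single shared reason string, M_TO_N otherwise).
    """
    by_id = {m.mention_id: m for m in ann.mentions}
    # term -> ordered drug mentions
    drug_mentions: dict[str, list[ConceptMention]] = {}
    for m in ann.mentions:
        if m.concept_type == ConceptType.DRUG:
            drug_mentions.setdefault(m.surface_text.lower(), []).append(m)
    # term -> ordered reason mentions (dedup by mention id, keep offset order)
    reasons_for_term: dict[str, dict[str, ConceptMention]] = {t: {} for t in drug_mentions}
    for rel in ann.relations:
        drug = by_id[rel.drug_mention]
        reason = by_id[rel.reason_mention]
        reasons_for_term[drug.surface_text.lower()][reason.mention_id] = reason

    # order terms by first mention offset for stable output
    ordered_terms = sorted(drug_mentions, key=lambda t: drug_mentions[t][0].start)

    groups: list[QuestionGroup] = []
    for term in ordered_terms:
        reasons = sorted(reasons_for_term[term].values(), key=lambda m: (m.start, m.end))
        distinct = {m.surface_text.lower() for m in reasons}
        groups.append(
            QuestionGroup(
                doc_id=ann.document.doc_id,
                drug_terms=(term,),
                drug_mentions=tuple(drug_mentions[term]),
                reason_mentions=tuple(reasons),
                category=_single_drug_category(len(distinct)),
            )
        )

    # multidrug groups: partition terms by their distinct reason-string set
    by_reason_set: dict[tuple[str, ...], list[str]] = {}
    for term in ordered_terms:
        key = tuple(sorted({m.surface_text.lower() for m in reasons_for_term[term].values()}))
        if key:
            by_reason_set.setdefault(key, []).append(term)
    for key, terms in by_reason_set.items():
        if len(terms) < 2:
            continue
        mentions = tuple(m for t in terms for m in drug_mentions[t])
        merged: dict[str, ConceptMention] = {}
        for t in terms:
            merged.update(reasons_for_term[t])
        reasons = tuple(sorted(merged.values(), key=lambda m: (m.start, m.end)))
        groups.append(
            QuestionGroup(
                doc_id=ann.document.doc_id,
                drug_terms=tuple(terms),
                drug_mentions=mentions,
                reason_mentions=reasons,
                category=Category.N_TO_ONE if len(key) == 1 else Category.M_TO_N,
            )
        )
    return groups


# ---------------------------------------------------------------------------
# Entry construction


@dataclass
class BuildConfig:
    """Configuration for QA-entry emission.

    multidrug_mode:
        ``"both"`` (default) emits the split single-drug entries AND the
        combined multidrug entry; ``"split_only"`` suppresses combined
        multidrug entries; ``"combined_only"`` suppresses the single-drug
        entries of drugs that belong to a multidrug group.
    """

    multidrug_mode: str = "both"
    templates: Sequence[QuestionTemplate] | None = None

    def __post_init__(self):
        if self.multidrug_mode not in ("both", "split_only", "combined_only"):
            raise ValueError(f"unknown multidrug_mode {self.multidrug_mode!r}")

    def resolved_templates(self) -> list[QuestionTemplate]:
        return list(self.templates) if self.templates is not None else load_templates()


def _answer_spans(group: QuestionGroup, text: str) -> tuple[AnswerSpan, ...]:
    # SQuAD answers must be contiguous: a discontinuous reason mention is
    # flattened to its longest fragment (remaining fragments are dropped).
    spans = []
    for m in group.reason_mentions:
        a, b = m.longest_fragment()
        spans.append(AnswerSpan(text=text[a:b], answer_start=a))
    return tuple(spans)


def build_qa_entries(ann: AnnotationSet, config: BuildConfig | None = None) -> list[QAEntry]:
    """Convert a document's relation groups into SQuAD-style QA entries."""
    config = config or BuildConfig()
    templates = config.resolved_templates()
    groups = group_relations(ann)

    multidrug_members: set[str] = set()
    if config.multidrug_mode == "combined_only":
        for g in groups:
            if len(g.drug_terms) > 1:
                multidrug_members.update(g.drug_terms)

    entries: list[QAEntry] = []
    for g in groups:
        if len(g.drug_terms) > 1 and config.multidrug_mode == "split_only":
            continue
        if (
            len(g.drug_terms) == 1
            and config.multidrug_mode == "combined_only"
            and g.drug_terms[0] in multidrug_members
        ):
            continue
        answers = _answer_spans(g, ann.document.text)
        questions = render_question(g.drug_terms, templates)
        for t_index, question in enumerate(questions):
            qa_id = f"{g.doc_id}::{'+'.join(g.drug_terms)}::t{t_index}"
            entries.append(
                QAEntry(
                    qa_id=qa_id,
                    doc_id=g.doc_id,
                    question=question,
                    drug_names=g.drug_terms,
                    is_impossible=not answers,
                    answers=answers,
                    category=g.category,
                )
            )
    return entries


# ---------------------------------------------------------------------------
# SQuAD 2.0 I/O


def write_squad(
    entries: Iterable[QAEntry],
    documents: Iterable[Document],
    out=None,
    version: str = "v2.0",
) -> str:
    """Serialize entries into a SQuAD-2.0-style JSON string (and file).

    Every ``answer_start`` is verified against its context before
    writing; a mismatch aborts naming the offending qa_id.  Key order is
    fixed, so identical inputs give byte-identical output.
    """
    docs = {d.doc_id: d for d in documents}
    per_doc: dict[str, list[QAEntry]] = {d: [] for d in docs}
    for e in entries:
        if e.doc_id not in docs:
            raise KeyError(f"entry {e.qa_id} references unknown document {e.doc_id}")
        per_doc[e.doc_id].append(e)

    data = []
    for doc_id, doc in docs.items():
        qas = []
        for e in per_doc[doc_id]:
            for a in e.answers:
                if doc.text[a.answer_start : a.answer_start + len(a.text)] != a.text:
                    raise ValueError(
                        f"{e.qa_id}: answer {a.text!r} does not match context at {a.answer_start}"
                    )
            qas.append(
                {
                    "id": e.qa_id,
                    "question": e.question,
                    "_mname": list(e.drug_names),
                    "answers": [
                        {"text": a.text, "answer_start": a.answer_start} for a in e.answers
                    ],
                    "is_impossible": e.is_impossible,
                }
            )
        data.append(
            {"title": doc_id, "paragraphs": [{"context": doc.text, "qas": qas}]}
        )
    payload = {"version": version, "data": data}
    blob = json.dumps(payload, ensure_ascii=False, indent=1)
    if out is not None:
        from pathlib import Path

        Path(out).write_text(blob, encoding="utf-8")
    return blob


def read_squad(source) -> tuple[list[Document], list[QAEntry]]:
    """Read a SQuAD-2.0-style file (path, file object, or JSON string)."""
    from pathlib import Path

    if isinstance(source, Path):
        text = source.read_text(encoding="utf-8")
    elif isinstance(source, str):
        # a JSON blob starts with '{'; anything else is a path
        text = source if source.lstrip().startswith("{") else Path(source).read_text(encoding="utf-8")
    else:
        text = source.read()
    payload = json.loads(text)
    documents: list[Document] = []
    entries: list[QAEntry] = []
    for article in payload["data"]:
        for para in article["paragraphs"]:
            doc = Document(doc_id=article["title"], text=para["context"])
            documents.append(doc)
            for qa in para["qas"]:
                mname = qa.get("_mname", [])
                drug_names = tuple(mname) if isinstance(mname, list) else (mname,)
                entries.append(
                    QAEntry(
                        qa_id=qa["id"],
                        doc_id=doc.doc_id,
                        question=qa["question"],
                        drug_names=drug_names,
                        is_impossible=qa.get("is_impossible", False),
                        answers=tuple(
                            AnswerSpan(a["text"], a["answer_start"]) for a in qa["answers"]
                        ),
                    )
                )
    return documents, entries


# ---------------------------------------------------------------------------
# Document-level splitting


def largest_remainder_sizes(total: int, ratios: Sequence[float]) -> list[int]:
    """Apportion *total* into integer cells proportional to *ratios*.

    Floors of the exact quotas first; leftover units go to the cells with
    the largest fractional remainders, earlier cells winning ties.
    """
    if any(r < 0 for r in ratios) or sum(ratios) <= 0:
        raise ValueError("ratios must be nonnegative and sum to a positive value")
    norm = [r / sum(ratios) for r in ratios]
    quotas = [total * r for r in norm]
    sizes = [math.floor(q) for q in quotas]
    leftover = total - sum(sizes)
    order = sorted(range(len(ratios)), key=lambda i: (-(quotas[i] - sizes[i]), i))
    for i in order[:leftover]:
        sizes[i] += 1
    return sizes


def split_documents(
    doc_ids: Sequence[str], ratios: Sequence[float] = (5, 2, 3), seed: int = 0
) -> tuple[list[str], ...]:
    """Partition document ids into train/dev/test by the given ratios.

    Sizes follow largest-remainder apportionment; identical seeds give
    identical partitions.  No document lands in two splits.
    """
    nonzero = sum(1 for r in ratios if r > 0)
    if len(doc_ids) < nonzero:
        raise ValueError(f"{len(doc_ids)} documents cannot fill {nonzero} nonempty splits")
    sizes = largest_remainder_sizes(len(doc_ids), ratios)
    shuffled = list(doc_ids)
    random.Random(seed).shuffle(shuffled)
    splits = []
    start = 0
    for size in sizes:
        splits.append(shuffled[start : start + size])
        start += size
    return tuple(splits)
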