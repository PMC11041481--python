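"""Read, validate, and write clinical notes with standoff drug/reason annotations.

The on-disk carrier is the BRAT standoff dialect used by clinical
relation-extraction challenges: per document a plain-text note
(``<id>.txt``) and an annotation file (``<id>.ann``) whose ``T`` lines
carry typed character-offset mentions (possibly discontinuous) and whose
``R`` lines carry binary relations between them.  Only ``Drug`` and
``Reason`` mentions and the drug->reason relations between them are kept;
everything else (dosage, route, ADE annotations, notes...) is counted and
ignored.

Offsets are 0-based, half-open, counted in unicode characters.  Line
endings are normalized to ``"\\n"`` before any offset is interpreted,
since mixed ``"\\r\\n"`` endings silently shift character-indexed
annotations.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)


class ConceptType(str, Enum):
    DRUG = "Drug"
    REASON = "Reason"


class StandoffParseError(ValueError):
    """Raised for a malformed standoff line; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


class AnnotationValidationError(ValueError):
    """Raised when annotations do not resolve against the document."""


@dataclass(frozen=True)
class Document:
    doc_id: str
    text: str


@dataclass(frozen=True)
class ConceptMention:
    mention_id: str
    concept_type: ConceptType
    fragments: tuple[tuple[int, int], ...]
    surface_text: str

    @property
    def start(self) -> int:
        return self.fragments[0][0]

    @property
    def end(self) -> int:
        return self.fragments[-1][1]

    def longest_fragment(self) -> tuple[int, int]:
        """Longest contiguous fragment; earliest wins ties."""
        return max(self.fragments, key=lambda f: (f[1] - f[0], -f[0]))


@dataclass(frozen=True)
class DrugReasonRelation:
    relation_id: str
    drug_mention: str
    reason_mention: str


@dataclass
class AnnotationSet:
    document: Document
    mentions: list[ConceptMention] = field(default_factory=list)
    relations: list[DrugReasonRelation] = field(default_factory=list)

    def mention_by_id(self, mention_id: str) -> ConceptMention:
        for m in self.mentions:
            if m.mention_id == mention_id:
                return m
        raise KeyError(mention_id)

    def mentions_of_type(self, concept_type: ConceptType) -> list[ConceptMention]:
        return [m for m in self.mentions if m.concept_type == concept_type]


@dataclass(frozen=True)
class Violation:
    offending_id: str
    rule: str
    detail: str


_WS = re.compile(r"\s+")


def _normalize_newlines(text: str) -> str:
    return text.replace("\r\n", "\n").replace("\r", "\n")


def _joined_surface(text: str, fragments: Sequence[tuple[int, int]]) -> str:
    return " ".join(text[a:b] for a, b in fragments)


_T_LINE = re.compile(r"^(T[^\t]+)\t([^\t ]+) ([0-9 ;]+)\t?(.*)$")
_R_LINE = re.compile(r"^(R[^\t]+)\t(\S+) Arg1:(\S+) Arg2:(\S+)\s*$")


def read_brat_standoff(doc_text: str, ann_text: str, doc_id: str = "doc") -> AnnotationSet:
    """Parse note text plus standoff annotation text into an :class:`AnnotationSet`.

    Keeps exactly the Drug and Reason mentions and the relations whose two
    endpoints are one Drug and one Reason (either argument order); all
    other annotation lines are ignored with a logged count.  Discontinuous
    spans are preserved as multiple fragments.

    Raises :class:`StandoffParseError` on a malformed line and
    :class:`AnnotationValidationError` when offsets fall outside the
    document or a relation references a missing mention.
    """
    text = _normalize_newlines(doc_text)
    mentions: dict[str, ConceptMention] = {}
    relations: list[DrugReasonRelation] = []
    ignored = 0

    pending_relations: list[tuple[int, str, str, str]] = []
    for lineno, raw in enumerate(_normalize_newlines(ann_text).split("\n"), start=1):
        line = raw.rstrip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("T"):
            m = _T_LINE.match(line)
            if m is None:
                raise StandoffParseError(lineno, f"malformed mention line: {line!r}")
            tid, ttype, offsets, surface = m.groups()
            if ttype not in (ConceptType.DRUG.value, ConceptType.REASON.value):
                ignored += 1
                continue
            fragments = []
            try:
                for frag in offsets.split(";"):
                    a, b = frag.split()
                    fragments.append((int(a), int(b)))
            except ValueError as exc:
                raise StandoffParseError(lineno, f"bad offsets {offsets!r}") from exc
            for a, b in fragments:
                if not (0 <= a < b <= len(text)):
                    raise AnnotationValidationError(
                        f"{tid}: fragment ({a}, {b}) outside document of length {len(text)}"
                    )
            fragments.sort()
            sliced = _joined_surface(text, fragments)
            if surface and _WS.sub(" ", surface.strip()) != _WS.sub(" ", sliced.strip()):
                logger.warning(
                    "%s %s: surface text %r disagrees with offsets (document reads %r); "
                    "keeping the document slice",
                    doc_id,
                    tid,
                    surface,
                    sliced,
                )
            mentions[tid] = ConceptMention(
                mention_id=tid,
                concept_type=ConceptType(ttype),
                fragments=tuple(fragments),
                surface_text=sliced,
            )
        elif line.startswith("R"):
            m = _R_LINE.match(line)
            if m is None:
                raise StandoffParseError(lineno, f"malformed relation line: {line!r}")
            rid, _rtype, arg1, arg2 = m.groups()
            pending_relations.append((lineno, rid, arg1, arg2))
        else:
            ignored += 1

    for lineno, rid, arg1, arg2 in pending_relations:
        m1, m2 = mentions.get(arg1), mentions.get(arg2)
        if m1 is None or m2 is None:
            # Both endpoints must be Drug/Reason mentions we kept; a relation
            # over ignored types (e.g. Strength-Drug) is itself ignored, but a
            # drug-reason relation naming an unknown T id is a data error.
            missing = arg1 if m1 is None else arg2
            if missing.startswith("T"):
                ignored += 1
                continue
            raise AnnotationValidationError(f"relation {rid} references missing mention {missing}")
        types = {m1.concept_type, m2.concept_type}
        if types != {ConceptType.DRUG, ConceptType.REASON}:
            ignored += 1
            continue
        drug, reason = (m1, m2) if m1.concept_type == ConceptType.DRUG else (m2, m1)
        relations.append(
            DrugReasonRelation(relation_id=rid, drug_mention=drug.mention_id, reason_mention=reason.mention_id)
        )

    if ignored:
        logger.info("%s: ignored %d non-drug/reason annotation lines", doc_id, ignored)

    ordered = sorted(mentions.values(), key=lambda m: (m.start, m.end, m.mention_id))
    return AnnotationSet(document=Document(doc_id=doc_id, text=text), mentions=ordered, relations=relations)


def write_brat_standoff(ann: AnnotationSet) -> tuple[str, str]:
    """Serialize an :class:`AnnotationSet` back to ``(doc_text, ann_text)``.

    ``read_brat_standoff(*write_brat_standoff(ann))`` reproduces *ann* up
    to identifier renaming; output is byte-stable across calls.
    """
    violations = validate_annotation_set(ann)
    if violations:
        raise AnnotationValidationError(
            "; ".join(f"{v.offending_id}: {v.rule}" for v in violations)
        )
    lines = []
    id_map: dict[str, str] = {}
    for i, m in enumerate(ann.mentions, start=1):
        new_id = f"T{i}"
        id_map[m.mention_id] = new_id
        offsets = ";".join(f"{a} {b}" for a, b in m.fragments)
        lines.append(f"{new_id}\t{m.concept_type.value} {offsets}\t{m.surface_text}")
    for i, r in enumerate(ann.relations, start=1):
        lines.append(
            f"R{i}\tReason-Drug Arg1:{id_map[r.drug_mention]} Arg2:{id_map[r.reason_mention]}"
        )
    ann_text = "\n".join(lines) + ("\n" if lines else "")
    return ann.document.text, ann_text


def validate_annotation_set(ann: AnnotationSet) -> list[Violation]:
    """Check every structural invariant; violations are returned, not raised."""
    out: list[Violation] = []
    text = ann.document.text
    if not ann.document.doc_id:
        out.append(Violation("<document>", "doc-id-nonempty", "document id is empty"))
    if ann.mentions and not text:
        out.append(Violation(ann.document.doc_id, "text-nonempty", "annotated document has empty text"))

    seen_m: set[str] = set()
    by_id: dict[str, ConceptMention] = {}
    for m in ann.mentions:
        if m.mention_id in seen_m:
            out.append(Violation(m.mention_id, "mention-id-unique", "duplicate mention id"))
        seen_m.add(m.mention_id)
        by_id[m.mention_id] = m
        prev_end = -1
        for a, b in m.fragments:
            if not (0 <= a < b <= len(text)):
                out.append(Violation(m.mention_id, "fragment-in-bounds", f"fragment ({a}, {b})"))
            elif a < prev_end:
                out.append(Violation(m.mention_id, "fragments-sorted-disjoint", f"fragment ({a}, {b})"))
            prev_end = max(prev_end, b)
        expected = _joined_surface(text, m.fragments)
        if m.surface_text != expected:
            if _WS.sub(" ", m.surface_text) == _WS.sub(" ", expected):
                logger.warning(
                    "%s: surface text differs from slice only in whitespace", m.mention_id
                )
            else:
                out.append(
                    Violation(
                        m.mention_id,
                        "surface-matches-offsets",
                        f"surface {m.surface_text!r} != slice {expected!r}",
                    )
                )

    seen_r: set[str] = set()
    for r in ann.relations:
        if r.relation_id in seen_r:
            out.append(Violation(r.relation_id, "relation-id-unique", "duplicate relation id"))
        seen_r.add(r.relation_id)
        drug = by_id.get(r.drug_mention)
        reason = by_id.get(r.reason_mention)
        if drug is None:
            out.append(Violation(r.relation_id, "relation-resolves", f"missing drug mention {r.drug_mention}"))
        elif drug.concept_type != ConceptType.DRUG:
            out.append(Violation(r.relation_id, "relation-arg-types", f"{r.drug_mention} is not a Drug"))
        if reason is None:
            out.append(
                Violation(r.relation_id, "relation-resolves", f"missing reason mention {r.reason_mention}")
            )
        elif reason.concept_type != ConceptType.REASON:
            out.append(Violation(r.relation_id, "relation-arg-types", f"{r.reason_mention} is not a Reason"))
    return out


def read_corpus_dir(notes_dir, ann_dir=None) -> list[AnnotationSet]:
    """Load every ``<id>.txt`` / ``<id>.ann`` pair under a directory.

    ``ann_dir`` defaults to ``notes_dir``.  A note without a sibling
    ``.ann`` file gets an empty annotation set.
    """
    from pathlib import Path

    notes_dir = Path(notes_dir)
    ann_dir = Path(ann_dir) if ann_dir is not None else notes_dir
    sets = []
    for txt in sorted(notes_dir.glob("*.txt")):
        ann_path = ann_dir / (txt.stem + ".ann")
        ann_text = ann_path.read_text(encoding="utf-8") if ann_path.exists() else ""
        sets.append(
            read_brat_standoff(txt.read_text(encoding="utf-8"), ann_text, doc_id=txt.stem)
        )
    return sets


def write_corpus_dir(sets: Iterable[AnnotationSet], out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ann in sets:
        doc_text, ann_text = write_brat_standoff(ann)
        (out / f"{ann.document.doc_id}.txt").write_text(doc_text, encoding="utf-8")
        (out / f"{ann.document.doc_id}.ann").write_text(ann_text, encoding="utf-8")
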