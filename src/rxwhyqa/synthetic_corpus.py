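"""Seeded generator of synthetic notes with planted drug-reason structure.

The real source corpus of drug->reason relation annotations sits behind
a data-use agreement, so tests and demos run on synthetic notes whose
ground truth is known by construction.  Each generated document carries
one planted question group from the five relation categories
(unanswerable, 1-to-1, 1-to-N, N-to-1, M-to-N).  Every planted relation
is realized by one of the four contextual trigger families ("started
on", "prn", "given for", "managed with") with a drawn sentence gap:
gap 0 puts drug and reason in the same trigger sentence; gap k puts an
anaphoric reason statement k sentences away from the drug sentence.

A manifest records the planted truth (categories, distinct reasons,
answer-mention counts, sentence distances, expected entry totals) so the
QA builder and corpus statistics can be checked against it exactly.

No clinical realism is attempted beyond what the patterns need; all
randomness flows through one explicit generator object, so a fixed seed
reproduces the corpus byte for byte.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from typing import Sequence

from rxwhyqa.annotation_io import (
    AnnotationSet,
    ConceptMention,
    ConceptType,
    Document,
    DrugReasonRelation,
)
from rxwhyqa.qa_builder import Category

DEFAULT_DRUGS = (
    "coumadin",
    "vancomycin",
    "lasix",
    "acetaminophen",
    "senna",
    "oxycodone",
    "morphine",
    "metoprolol",
    "amlodipine",
    "aspirin",
)
DEFAULT_REASONS = (
    "pain",
    "constipation",
    "fever",
    "afib",
    "sob",
    "wheeze",
    "hypertension",
    "nausea",
    "agitation",
    "insomnia",
)

PATTERN_FAMILIES = (
    "reason_started_on_drug",
    "drug_prn_reason",
    "drug_given_for_reason",
    "reason_managed_with_drug",
)

_FILLERS = (
    "vital signs stable overnight.",
    "tolerating a regular diet.",
    "ambulating without assistance.",
    "follow up in two weeks.",
)

# distractors mention a drug name but carry no reason trigger
_DISTRACTOR = "{drug} 10 mg daily."


@dataclass
class GeneratorConfig:
    category_counts: dict[Category, int] = field(
        default_factory=lambda: {
            Category.ONE_DRUG_NO_REASON: 10,
            Category.ONE_TO_ONE: 20,
            Category.ONE_TO_N: 5,
            Category.N_TO_ONE: 3,
            Category.M_TO_N: 2,
        }
    )
    drug_lexicon: tuple[str, ...] = DEFAULT_DRUGS
    reason_lexicon: tuple[str, ...] = DEFAULT_REASONS
    distance_histogram: dict[int, float] = field(
        default_factory=lambda: {0: 0.72, 1: 0.18, 2: 0.06, 3: 0.04}
    )
    duplicate_answer_rate: float = 0.25
    pattern_mix: dict[str, float] = field(
        default_factory=lambda: {f: w for f, w in zip(PATTERN_FAMILIES, (25, 18, 14, 13))}
    )
    distractor_rate: float = 0.3
    n_reasons_range: tuple[int, int] = (2, 3)
    n_drugs_range: tuple[int, int] = (2, 3)
    seed: int = 0

    def validate(self) -> None:
        overlap = set(self.drug_lexicon) & set(self.reason_lexicon)
        if overlap:
            raise ValueError(f"lexicons must be disjoint; shared terms: {sorted(overlap)}")
        if any(n < 0 for n in self.category_counts.values()):
            raise ValueError("category counts must be nonnegative")
        if not self.category_counts or sum(self.category_counts.values()) == 0:
            raise ValueError("at least one category count must be positive")
        if abs(sum(self.distance_histogram.values()) - 1.0) > 1e-9:
            raise ValueError("distance histogram must sum to 1")
        if any(g < 0 for g in self.distance_histogram):
            raise ValueError("sentence gaps must be nonnegative")
        unknown = set(self.pattern_mix) - set(PATTERN_FAMILIES)
        if unknown or sum(self.pattern_mix.values()) <= 0:
            raise ValueError(f"bad pattern mix (unknown families {sorted(unknown)})")
        if not 0 <= self.duplicate_answer_rate <= 1 or not 0 <= self.distractor_rate <= 1:
            raise ValueError("rates must lie in [0, 1]")
        answerable = sum(
            n for c, n in self.category_counts.items() if c != Category.ONE_DRUG_NO_REASON
        )
        if self.duplicate_answer_rate > 0 and answerable == 0:
            raise ValueError(
                "duplicate_answer_rate > 0 is impossible without answerable groups"
            )
        needed = max(self.n_drugs_range[1], 1)
        if len(self.drug_lexicon) < needed or len(self.reason_lexicon) < max(
            self.n_reasons_range[1], 1
        ):
            raise ValueError("lexicons too small for the configured group sizes")


@dataclass
class DocPlan:
    doc_id: str
    category: Category
    drug_terms: tuple[str, ...]
    reason_strings: tuple[str, ...]  # distinct, in planting order
    n_answer_mentions: int
    expected_distance: int | None  # None for unanswerable


@dataclass
class Manifest:
    docs: list[DocPlan]
    n_templates: int = 1

    @property
    def category_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for d in self.docs:
            out[d.category.value] = out.get(d.category.value, 0) + 1
        return out

    @property
    def unique_answer_hist(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for d in self.docs:
            if d.category == Category.ONE_DRUG_NO_REASON:
                continue
            k = len(d.reason_strings)
            bucket = "4+" if k >= 4 else str(k)
            out[bucket] = out.get(bucket, 0) + 1
        return out

    @property
    def distance_hist(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for d in self.docs:
            if d.expected_distance is not None:
                out[d.expected_distance] = out.get(d.expected_distance, 0) + 1
        return out

    def expected_entry_total(self, multidrug_mode: str = "combined_only") -> int:
        """Entries build_qa_entries emits per mode (one group per document)."""
        total = 0
        for d in self.docs:
            k = len(d.drug_terms)
            if k == 1:
                total += 1
            elif multidrug_mode == "combined_only":
                total += 1
            elif multidrug_mode == "split_only":
                total += k
            else:  # both
                total += k + 1
        return total * self.n_templates

    def to_json(self) -> str:
        payload = {
            "docs": [
                {**asdict(d), "category": d.category.value} for d in self.docs
            ],
            "n_templates": self.n_templates,
            "category_counts": self.category_counts,
            "unique_answer_hist": self.unique_answer_hist,
            "distance_hist": {str(k): v for k, v in sorted(self.distance_hist.items())},
        }
        return json.dumps(payload, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Sentence realizers: (template, drug slot, reason slot) with offsets


def _family_sentence(family: str, drug: str, reason: str) -> tuple[str, int, int]:
    """Gap-0 sentence realizing one trigger family; returns the sentence
    and the character offsets of the drug and reason terms within it."""
    if family == "reason_started_on_drug":
        s = f"{reason} being maintained on {drug}."
        return s, s.index(drug), 0
    if family == "drug_prn_reason":
        s = f"{drug} prn {reason}."
        return s, 0, s.index(reason)
    if family == "drug_given_for_reason":
        s = f"{drug} was given for {reason}."
        return s, 0, s.index(reason)
    if family == "reason_managed_with_drug":
        s = f"{reason} was managed with {drug}."
        return s, s.index(drug), 0
    raise ValueError(f"unknown pattern family {family!r}")


def _multi_drug_sentence(family: str, drugs: Sequence[str], reason: str) -> tuple[str, list[int], int]:
    joined = " and ".join(drugs)
    if family in ("reason_started_on_drug",):
        s = f"{reason} required {joined}."
    else:
        s = f"{reason} was managed with {joined}."
    offsets = []
    pos = s.index(joined)
    for d in drugs:
        offsets.append(s.index(d, pos))
        pos = offsets[-1] + len(d)
    return s, offsets, 0


class _DocBuilder:
    def __init__(self, doc_id: str):
        self.doc_id = doc_id
        self.sentences: list[str] = []
        self.mentions: list[ConceptMention] = []
        self.relations: list[DrugReasonRelation] = []
        self._m = 0
        self._r = 0

    def _offset(self) -> int:
        return sum(len(s) + 1 for s in self.sentences)  # sentences joined by "\n"

    def add_sentence(self, sentence: str) -> int:
        start = self._offset()
        self.sentences.append(sentence)
        return start

    def add_mention(self, ctype: ConceptType, start: int, text: str) -> ConceptMention:
        self._m += 1
        m = ConceptMention(
            mention_id=f"T{self._m}",
            concept_type=ctype,
            fragments=((start, start + len(text)),),
            surface_text=text,
        )
        self.mentions.append(m)
        return m

    def relate(self, drug: ConceptMention, reason: ConceptMention) -> None:
        self._r += 1
        self.relations.append(
            DrugReasonRelation(f"R{self._r}", drug.mention_id, reason.mention_id)
        )

    def build(self) -> AnnotationSet:
        text = "\n".join(self.sentences) + "\n"
        return AnnotationSet(
            document=Document(self.doc_id, text),
            mentions=sorted(self.mentions, key=lambda m: m.start),
            relations=list(self.relations),
        )


def _draw(rng: random.Random, weights: dict) -> object:
    keys = sorted(weights, key=str)
    total = sum(weights[k] for k in keys)
    x = rng.random() * total
    acc = 0.0
    for k in keys:
        acc += weights[k]
        if x <= acc:
            return k
    return keys[-1]


def _plant_relation(
    b: _DocBuilder,
    drug: str,
    reason: str,
    family: str,
    gap: int,
) -> None:
    """Realize one drug->reason relation with the given sentence gap."""
    if gap == 0:
        s, d_off, r_off = _family_sentence(family, drug, reason)
        start = b.add_sentence(s)
        dm = b.add_mention(ConceptType.DRUG, start + d_off, drug)
        rm = b.add_mention(ConceptType.REASON, start + r_off, reason)
    else:
        s = f"patient reports {reason}."
        start = b.add_sentence(s)
        rm = b.add_mention(ConceptType.REASON, start + s.index(reason), reason)
        for i in range(gap - 1):
            b.add_sentence(_FILLERS[i % len(_FILLERS)])
        s2 = f"{drug} dose unchanged."
        start2 = b.add_sentence(s2)
        dm = b.add_mention(ConceptType.DRUG, start2, drug)
    b.relate(dm, rm)


def generate_corpus(
    config: GeneratorConfig | None = None,
) -> tuple[list[Document], list[AnnotationSet], Manifest]:
    """Generate documents, annotation sets, and the ground-truth manifest.

    One planted question group per document; identical config (including
    seed) reproduces the corpus byte for byte.
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = random.Random(config.seed)

    plans: list[Category] = []
    for cat in (
        Category.ONE_DRUG_NO_REASON,
        Category.ONE_TO_ONE,
        Category.ONE_TO_N,
        Category.N_TO_ONE,
        Category.M_TO_N,
    ):
        plans.extend([cat] * config.category_counts.get(cat, 0))

    docs: list[Document] = []
    ann_sets: list[AnnotationSet] = []
    manifest_docs: list[DocPlan] = []

    for i, cat in enumerate(plans):
        doc_id = f"synth-{i:04d}"
        b = _DocBuilder(doc_id)
        if rng.random() < config.distractor_rate:
            b.add_sentence(_DISTRACTOR.format(drug=rng.choice(config.drug_lexicon)))

        if cat == Category.ONE_DRUG_NO_REASON:
            drug = rng.choice(config.drug_lexicon)
            s = f"{drug} 15 mg po qhs."
            start = b.add_sentence(s)
            b.add_mention(ConceptType.DRUG, start, drug)
            plan = DocPlan(doc_id, cat, (drug,), (), 0, None)

        elif cat == Category.ONE_TO_ONE:
            drug = rng.choice(config.drug_lexicon)
            reason = rng.choice(config.reason_lexicon)
            family = _draw(rng, config.pattern_mix)
            gap = _draw(rng, config.distance_histogram)
            _plant_relation(b, drug, reason, family, gap)
            n_mentions = 1
            # duplicates only in the gap-0 regime so the appended restatement
            # cannot shrink the planted sentence distance
            if gap == 0 and rng.random() < config.duplicate_answer_rate:
                s = f"{reason} noted again overnight."
                start = b.add_sentence(s)
                rm = b.add_mention(ConceptType.REASON, start, reason)
                dm = next(m for m in b.mentions if m.concept_type == ConceptType.DRUG)
                b.relate(dm, rm)
                n_mentions = 2
            plan = DocPlan(doc_id, cat, (drug,), (reason,), n_mentions, gap)

        elif cat == Category.ONE_TO_N:
            drug = rng.choice(config.drug_lexicon)
            n = rng.randint(*config.n_reasons_range)
            reasons = tuple(rng.sample(config.reason_lexicon, n))
            for reason in reasons:
                family = _draw(rng, config.pattern_mix)
                _plant_relation(b, drug, reason, family, 0)
            plan = DocPlan(doc_id, cat, (drug,), reasons, n, 0)

        elif cat == Category.N_TO_ONE:
            k = rng.randint(*config.n_drugs_range)
            drugs = tuple(rng.sample(config.drug_lexicon, k))
            reason = rng.choice(config.reason_lexicon)
            gap = _draw(rng, config.distance_histogram)
            if gap == 0:
                s, d_offs, r_off = _multi_drug_sentence("reason_started_on_drug", drugs, reason)
                start = b.add_sentence(s)
                rm = b.add_mention(ConceptType.REASON, start + r_off, reason)
                for d, off in zip(drugs, d_offs):
                    dm = b.add_mention(ConceptType.DRUG, start + off, d)
                    b.relate(dm, rm)
            else:
                s = f"patient reports {reason}."
                start = b.add_sentence(s)
                rm = b.add_mention(ConceptType.REASON, start + s.index(reason), reason)
                for j in range(gap - 1):
                    b.add_sentence(_FILLERS[j % len(_FILLERS)])
                joined = " and ".join(drugs)
                s2 = f"{joined} doses unchanged."
                start2 = b.add_sentence(s2)
                pos = 0
                for d in drugs:
                    off = s2.index(d, pos)
                    dm = b.add_mention(ConceptType.DRUG, start2 + off, d)
                    b.relate(dm, rm)
                    pos = off + len(d)
            plan = DocPlan(doc_id, cat, drugs, (reason,), 1, gap)

        else:  # M_TO_N
            k = rng.randint(*config.n_drugs_range)
            n = rng.randint(*config.n_reasons_range)
            drugs = tuple(rng.sample(config.drug_lexicon, k))
            reasons = tuple(rng.sample(config.reason_lexicon, n))
            for reason in reasons:
                s, d_offs, r_off = _multi_drug_sentence("reason_managed_with_drug", drugs, reason)
                start = b.add_sentence(s)
                rm = b.add_mention(ConceptType.REASON, start + r_off, reason)
                for d, off in zip(drugs, d_offs):
                    dm = b.add_mention(ConceptType.DRUG, start + off, d)
                    b.relate(dm, rm)
            plan = DocPlan(doc_id, cat, drugs, reasons, n, 0)

        ann = b.build()
        docs.append(ann.document)
        ann_sets.append(ann)
        manifest_docs.append(plan)

    return docs, ann_sets, Manifest(docs=manifest_docs)


def pattern_pure_config(
    n_one_to_one: int = 20, n_unanswerable: int = 0, seed: int = 0
) -> GeneratorConfig:
    """Canonical test regime where the pattern baseline is exact by
    construction: all sentence gaps 0, single-token reasons, one relation
    per document, no duplicate answers, no distractors."""
    return GeneratorConfig(
        category_counts={
            Category.ONE_DRUG_NO_REASON: n_unanswerable,
            Category.ONE_TO_ONE: n_one_to_one,
            Category.ONE_TO_N: 0,
            Category.N_TO_ONE: 0,
            Category.M_TO_N: 0,
        },
        distance_histogram={0: 1.0},
        duplicate_answer_rate=0.0,
        distractor_rate=0.0,
        seed=seed,
    )


def write_corpus(config: GeneratorConfig, out_dir) -> Manifest:
    """Generate and write ``<id>.txt`` / ``<id>.ann`` pairs plus
    ``manifest.json`` under *out_dir*."""
    from pathlib import Path

    from rxwhyqa.annotation_io import write_corpus_dir

    _docs, ann_sets, manifest = generate_corpus(config)
    out = Path(out_dir)
    write_corpus_dir(ann_sets, out)
    (out / "manifest.json").write_text(manifest.to_json(), encoding="utf-8")
    return manifest
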