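"""Corpus analytics for drug-reason QA datasets.

Covers the descriptive statistics a dataset release reports: the
unique-answer-count distribution of answerable questions, ranked drug and
drug-reason pair frequencies, the sentence distance between a question's
drug anchor and its answer term, matching of the four common contextual
trigger patterns observed around drug-reason pairs (the "prn" /
"as needed for" / "managed with" / "started on" families), and a simple
on-label screen of drug-reason pairs against a drug->indication lookup
table (case-folded exact string match); pairs missing from the table are
candidate off-label uses for human review.
"""

from __future__ import annotations

import bisect
import logging
import math
import re
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Iterable, Mapping, Sequence

from rxwhyqa.annotation_io import AnnotationSet
from rxwhyqa.qa_builder import QAEntry, QuestionGroup

logger = logging.getLogger(__name__)

Span = tuple[int, int]
SentenceSplitter = Callable[[str], list[Span]]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (so 2.5 -> 3, not 2)."""
    factor = 10**ndigits
    scaled = x * factor
    rounded = math.floor(scaled + 0.5) if scaled >= 0 else math.ceil(scaled - 0.5)
    return rounded / factor if ndigits else int(rounded)


# ---------------------------------------------------------------------------
# Sentence splitting

_BOUNDARY = re.compile(r"[.?!]+(?=\s+[A-Z0-9])|\n")


def split_sentences(text: str) -> list[Span]:
    """Rule-based sentence spans: break on newline and on ``[.?!]`` followed
    by whitespace and an uppercase/numeric character.  Pluggable — any
    callable returning (start, end) spans can replace it."""
    spans: list[Span] = []
    start = 0
    for m in _BOUNDARY.finditer(text):
        end = m.end() if m.group() != "\n" else m.start()
        if text[start:end].strip():
            spans.append((start, end))
        start = m.end()
    if text[start:].strip():
        spans.append((start, len(text)))
    return spans


def sentence_index(spans: Sequence[Span], offset: int) -> int:
    """Index of the sentence containing *offset* (whitespace between
    sentences belongs to the following one)."""
    if not spans:
        return 0
    starts = [s for s, _ in spans]
    i = bisect.bisect_right(starts, offset) - 1
    if i < 0:
        return 0
    if offset >= spans[i][1] and i + 1 < len(spans):
        return i + 1
    return i


# ---------------------------------------------------------------------------
# Answer-count distribution and term frequencies


def answer_count_distribution(entries: Iterable[QAEntry]) -> dict[str, tuple[int, int]]:
    """Distribution of distinct (lowercased) answer strings per answerable
    question, bucketed 1 / 2 / 3 / 4+; values are (n, integer percent)."""
    counts: Counter[str] = Counter()
    total = 0
    for e in entries:
        if e.is_impossible:
            continue
        total += 1
        k = len(e.distinct_answer_strings)
        counts["4+" if k >= 4 else str(k)] += 1
    out = {}
    for bucket in ("1", "2", "3", "4+"):
        if counts[bucket]:
            out[bucket] = (counts[bucket], distribution_percents(counts)[bucket])
    return out


def distribution_percents(counts: Mapping[str, int]) -> dict[str, int]:
    """Integer percents (half-away-from-zero) of a bucket->n histogram."""
    total = sum(counts.values())
    if total == 0:
        return {k: 0 for k in counts}
    return {k: round_half_away(100 * n / total) for k, n in counts.items()}


@dataclass
class TermFrequencies:
    answerable_drugs: list[tuple[str, int]]
    unanswerable_drugs: list[tuple[str, int]]
    pairs: list[tuple[tuple[str, str], int]]


def term_frequencies(entries: Iterable[QAEntry]) -> TermFrequencies:
    """Ranked lowercased drug frequencies (answerable vs unanswerable
    disjointly) and drug-reason pair frequencies, counted in QA entries."""
    answerable: Counter[str] = Counter()
    unanswerable: Counter[str] = Counter()
    pairs: Counter[tuple[str, str]] = Counter()
    for e in entries:
        target = unanswerable if e.is_impossible else answerable
        for drug in {d.lower() for d in e.drug_names}:
            target[drug] += 1
            for reason in e.distinct_answer_strings:
                pairs[(drug, reason)] += 1

    def ranked(c: Counter) -> list:
        return sorted(c.items(), key=lambda kv: (-kv[1], kv[0]))

    return TermFrequencies(ranked(answerable), ranked(unanswerable), ranked(pairs))


# ---------------------------------------------------------------------------
# Sentence distance


@dataclass(frozen=True)
class DistanceRecord:
    qa_id: str
    distance: int


def sentence_distance(
    ann: AnnotationSet,
    group: QuestionGroup,
    splitter: SentenceSplitter = split_sentences,
) -> DistanceRecord:
    """Shortest sentence distance between any drug mention and any reason
    mention of the group (0 = same sentence).  A mention sits in the
    sentence containing its first fragment's start offset."""
    if not group.reason_mentions:
        raise ValueError(f"group {group.doc_id}::{'+'.join(group.drug_terms)} is unanswerable")
    spans = splitter(ann.document.text)
    drug_idx = {sentence_index(spans, m.start) for m in group.drug_mentions}
    reason_idx = {sentence_index(spans, m.start) for m in group.reason_mentions}
    best = min(abs(d - r) for d in drug_idx for r in reason_idx)
    return DistanceRecord(qa_id=f"{group.doc_id}::{'+'.join(group.drug_terms)}", distance=best)


def distance_histogram(
    pairs: Iterable[tuple[AnnotationSet, QuestionGroup]],
    splitter: SentenceSplitter = split_sentences,
) -> Counter:
    """Histogram of shortest sentence distances over answerable groups."""
    hist: Counter[int] = Counter()
    for ann, group in pairs:
        if group.reason_mentions:
            hist[sentence_distance(ann, group, splitter).distance] += 1
    return hist


# ---------------------------------------------------------------------------
# Contextual trigger patterns

DEFAULT_GAP_LIMIT = 12  # max intervening words per ellipsis


@dataclass(frozen=True)
class ContextPattern:
    """One trigger-pattern family around a drug-reason pair.

    The template holds ``{drug}`` and ``{reason}`` slots plus a ``{gap}``
    word bound for each ellipsis; ``weight`` reflects how often the family
    was observed and doubles as the pattern-baseline confidence score.
    """

    pattern_id: str
    direction: str  # "REASON_FIRST" | "DRUG_FIRST"
    template: str
    weight: int
    gap: int = DEFAULT_GAP_LIMIT

    def compile(self, drug_text: str, reason_text: str) -> re.Pattern:
        pattern = self.template.format(
            drug=f"(?P<drug>{re.escape(drug_text)})",
            reason=f"(?P<reason>{re.escape(reason_text)})",
            gap=self.gap,
        )
        return re.compile(pattern, re.IGNORECASE)


def default_context_patterns(gap: int = DEFAULT_GAP_LIMIT) -> list[ContextPattern]:
    """The four trigger families, in observed-frequency (priority) order:

    1. Reason ... (being)? [received|started|restarted|required|maintained|
       continue(d)?] (on)? Drug
    2. Drug ... [prn | (as needed for)?] Reason
    3. Drug ... (was)? [attempted|given|dosing|taking] for (any)?
       [possible|likely|presumed]? Reason
    4. Reason ... (was)? [managed|treated|improved|recommended|downtrended|
       resolved|reversed|needed] with Drug
    """
    return [
        ContextPattern(
            "reason_started_on_drug",
            "REASON_FIRST",
            r"{reason}\W+(?:\S+\s+){{0,{gap}}}?(?:being\s+)?"
            r"(?:received|started|restarted|required|maintained|continued?)"
            r"(?:\s+on)?\s+{drug}",
            weight=25,
            gap=gap,
        ),
        ContextPattern(
            "drug_prn_reason",
            "DRUG_FIRST",
            r"{drug}\W+(?:\S+\s+){{0,{gap}}}?(?:(?:prn|as\s+needed\s+for)\s+)?{reason}",
            weight=18,
            gap=gap,
        ),
        ContextPattern(
            "drug_given_for_reason",
            "DRUG_FIRST",
            r"{drug}\W+(?:\S+\s+){{0,{gap}}}?(?:was\s+)?"
            r"(?:attempted|given|dosing|taking)\s+for\s+(?:any\s+)?"
            r"(?:(?:possible|likely|presumed)\s+)?{reason}",
            weight=14,
            gap=gap,
        ),
        ContextPattern(
            "reason_managed_with_drug",
            "REASON_FIRST",
            r"{reason}\W+(?:\S+\s+){{0,{gap}}}?(?:was\s+|were\s+)?"
            r"(?:managed|treated|improved|recommended|downtrended|resolved|"
            r"reversed|needed)\s+with\s+{drug}",
            weight=13,
            gap=gap,
        ),
    ]


def match_context_patterns(
    text: str,
    drug_span: Span,
    reason_span: Span,
    patterns: Sequence[ContextPattern] | None = None,
    splitter: SentenceSplitter = split_sentences,
) -> list[str]:
    """Pattern ids (in priority order) matching the given drug/reason pair.

    A pattern matches iff, within the sentence window spanning both
    mentions, its ordered elements align with the token sequence AND the
    drug/reason slots land exactly on the given spans."""
    patterns = patterns if patterns is not None else default_context_patterns()
    spans = splitter(text)
    if spans:
        i = sentence_index(spans, drug_span[0])
        j = sentence_index(spans, reason_span[0])
        w_start = spans[min(i, j)][0]
        w_end = spans[max(i, j)][1]
    else:
        w_start, w_end = 0, len(text)
    window = text[w_start:w_end]
    drug_text = text[drug_span[0] : drug_span[1]]
    reason_text = text[reason_span[0] : reason_span[1]]
    hits = []
    for p in patterns:
        rx = p.compile(drug_text, reason_text)
        for m in rx.finditer(window):
            if (
                m.start("drug") + w_start == drug_span[0]
                and m.start("reason") + w_start == reason_span[0]
            ):
                hits.append(p.pattern_id)
                break
    return hits


# ---------------------------------------------------------------------------
# On/off-label screen


@dataclass
class OffLabelResult:
    on_label: list[tuple[str, str]]
    unknown: list[tuple[str, str]]

    @property
    def pct_unknown(self) -> float:
        total = len(self.on_label) + len(self.unknown)
        if total == 0:
            return 0.0
        return round_half_away(100 * len(self.unknown) / total, ndigits=1)


def load_kb(path=None) -> set[tuple[str, str]]:
    """Load a two-column drug<TAB>indication lookup table, lowercased.

    Without a path a small packaged toy table is used; it stands in for a
    real indication knowledge base and is only meant for tests and demos.
    """
    if path is None:
        raw = resources.files("rxwhyqa.data").joinpath("toy_kb.tsv").read_text("utf-8")
    else:
        from pathlib import Path

        raw = Path(path).read_text(encoding="utf-8")
    kb = set()
    for line in raw.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        drug, _, indication = line.partition("\t")
        kb.add((drug.strip().lower(), indication.strip().lower()))
    return kb


def off_label_screen(
    pairs: Iterable[tuple[str, str]], kb: set[tuple[str, str]]
) -> OffLabelResult:
    """Partition drug-reason pairs into on-label (verbatim lowercase match
    in the lookup table) and unknown (candidate off-label, for review)."""
    if not kb:
        logger.warning("empty knowledge base: every pair will be flagged unknown")
    result = OffLabelResult(on_label=[], unknown=[])
    for drug, reason in pairs:
        key = (drug.lower(), reason.lower())
        (result.on_label if key in kb else result.unknown).append((drug, reason))
    return result


# ---------------------------------------------------------------------------
# Count-table summarization


def summarize_count_tables(
    category_totals: Mapping[str, int] | None = None,
    answer_hist: Mapping[str, int] | None = None,
    distance_hist: Mapping[int, int] | None = None,
    off_label_hits: Sequence[int] | None = None,
    off_label_sample_size: int = 100,
) -> dict:
    """Derive the release-level summary numbers from raw count tables.

    Takes the per-category entry totals, the unique-answer histogram
    (buckets "1","2","3","4+"), the sentence-distance histogram, and
    per-sample off-label hit counts; returns totals and rounded percents
    (integers half-away-from-zero; one decimal for the off-label rate).
    """
    report: dict = {}
    if category_totals is not None:
        report["total_entries"] = sum(category_totals.values())
    if answer_hist is not None:
        answerable = sum(answer_hist.values())
        multi = sum(n for k, n in answer_hist.items() if k != "1")
        report["answerable_total"] = answerable
        report["multi_answer_total"] = multi
        report["pct_single_answer"] = round_half_away(100 * answer_hist.get("1", 0) / answerable)
        report["pct_multi_answer"] = round_half_away(100 * multi / answerable)
        report["answer_hist_percents"] = distribution_percents(dict(answer_hist))
    if distance_hist is not None:
        total = sum(distance_hist.values())
        same = distance_hist.get(0, 0)
        adjacent = same + distance_hist.get(1, 0)
        report["distance_total"] = total
        report["pct_same_sentence"] = round_half_away(100 * same / total)
        report["pct_within_adjacent"] = round_half_away(100 * adjacent / total)
    if off_label_hits is not None:
        denom = len(off_label_hits) * off_label_sample_size
        report["off_label_pct"] = round_half_away(
            100 * sum(off_label_hits) / denom, ndigits=1
        )
    return report
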