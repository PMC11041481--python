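"""Answer distributions, term frequencies, distances, patterns, off-label."""

import pytest

from rxwhyqa.corpus_stats import (
    answer_count_distribution,
    default_context_patterns,
    distribution_percents,
    load_kb,
    match_context_patterns,
    off_label_screen,
    round_half_away,
    sentence_distance,
    split_sentences,
    summarize_count_tables,
    term_frequencies,
)
from rxwhyqa.qa_builder import build_qa_entries, group_relations

from conftest import make_standoff

# One exemplar sentence per trigger family, instantiated from the
# family's own template with concrete drug/reason terms.
PATTERN_EXEMPLARS = [
    ("reason_started_on_drug", "pain being maintained on coumadin.", "coumadin", "pain"),
    ("drug_prn_reason", "oxycodone prn pain.", "oxycodone", "pain"),
    (
        "drug_given_for_reason",
        "lasix was given for any possible fluid overload.",
        "lasix",
        "fluid overload",
    ),
    ("reason_managed_with_drug", "constipation was managed with senna.", "senna", "constipation"),
]


class TestRounding:
    @pytest.mark.parametrize(
        "x,expected", [(2.5, 3), (2.4, 2), (-2.5, -3), (0.5, 1), (74.9, 75)]
    )
    def test_half_away_from_zero(self, x, expected):
        assert round_half_away(x) == expected

    def test_one_decimal(self):
        assert round_half_away(20 / 3, ndigits=1) == 6.7


class TestAnswerDistribution:
    def test_published_style_counts_round_to_percents(self):
        counts = {"1": 28224, "2": 6804, "3": 1530, "4+": 954}
        assert distribution_percents(counts) == {"1": 75, "2": 18, "3": 4, "4+": 3}

    def test_all_single_answer(self, morphine_doc):
        entries = build_qa_entries(morphine_doc)
        assert answer_count_distribution(entries) == {"1": (1, 100)}

    def test_duplicates_do_not_inflate_unique_count(self):
        text = "tylenol for pain. pain again."
        ann = make_standoff(
            text,
            [("Drug", "tylenol", 0), ("Reason", "pain", 0), ("Reason", "pain", 1)],
            [(0, 1), (0, 2)],
        )
        entries = build_qa_entries(ann)
        assert answer_count_distribution(entries) == {"1": (1, 100)}

    def test_percents_sum_to_about_100(self):
        counts = {"1": 7, "2": 1, "3": 1, "4+": 1}
        assert abs(sum(distribution_percents(counts).values()) - 100) <= 1


class TestTermFrequencies:
    def test_pair_counting_and_case_folding(self):
        # mixed-case 'Coumadin'/'coumadin' merge into one key; the pair
        # frequency counts QA entries, not mention occurrences
        text = "Coumadin for afib. coumadin for afib. coumadin for afib."
        specs = [("Coumadin", 0, 0), ("coumadin", 0, 1), ("coumadin", 1, 2)]
        entries = []
        for i, (drug_text, drug_occ, afib_occ) in enumerate(specs):
            ann = make_standoff(
                text,
                [("Drug", drug_text, drug_occ), ("Reason", "afib", afib_occ)],
                [(0, 1)],
                doc_id=f"d{i}",
            )
            entries.extend(build_qa_entries(ann))
        freqs = term_frequencies(entries)
        assert freqs.pairs == [(("coumadin", "afib"), 3)]
        assert freqs.answerable_drugs == [("coumadin", 3)]

    def test_answerable_and_unanswerable_disjoint(self, morphine_doc, mirtazapine_doc):
        entries = build_qa_entries(morphine_doc) + build_qa_entries(mirtazapine_doc)
        freqs = term_frequencies(entries)
        assert freqs.answerable_drugs == [("morphine", 1)]
        assert freqs.unanswerable_drugs == [("mirtazapine", 1)]
        assert freqs.pairs == [(("morphine", "pain"), 1)]


class TestSentenceDistance:
    def test_same_sentence_is_zero(self, morphine_doc):
        (g,) = group_relations(morphine_doc)
        assert sentence_distance(morphine_doc, g).distance == 0

    def test_adjacent_sentence_is_one(self):
        text = "Vanco was continued. The wound infection improved."
        ann = make_standoff(
            text, [("Drug", "Vanco", 0), ("Reason", "wound infection", 0)], [(0, 1)]
        )
        (g,) = group_relations(ann)
        assert sentence_distance(ann, g).distance == 1

    def test_minimum_over_all_mention_pairs(self):
        # drug in sentences {0, 7}, reason in sentence {6} -> distance 1
        sentences = ["coumadin started."] + ["Filler sentence here."] * 5 + [
            "Afib noted on telemetry.",
            "Coumadin continued.",
        ]
        text = " ".join(sentences)
        ann = make_standoff(
            text,
            [("Drug", "coumadin", 0), ("Drug", "Coumadin", 0), ("Reason", "Afib", 0)],
            [(0, 2), (1, 2)],
        )
        (g,) = group_relations(ann)
        assert sentence_distance(ann, g).distance == 1

    def test_unanswerable_group_rejected(self, mirtazapine_doc):
        (g,) = group_relations(mirtazapine_doc)
        with pytest.raises(ValueError):
            sentence_distance(mirtazapine_doc, g)

    def test_distance_bounded_by_sentence_count(self):
        text = "lasix given.\nSome note text.\nEdema improving."
        assert len(split_sentences(text)) == 3
        ann = make_standoff(text, [("Drug", "lasix", 0), ("Reason", "Edema", 0)], [(0, 1)])
        (g,) = group_relations(ann)
        assert sentence_distance(ann, g).distance <= 2


class TestContextPatterns:
    @pytest.mark.parametrize("pattern_id,text,drug,reason", PATTERN_EXEMPLARS)
    def test_each_family_matches_its_exemplar(self, pattern_id, text, drug, reason):
        d = (text.index(drug), text.index(drug) + len(drug))
        r = (text.index(reason), text.index(reason) + len(reason))
        assert pattern_id in match_context_patterns(text, d, r)

    def test_all_four_families_covered(self):
        matched = set()
        for pattern_id, text, drug, reason in PATTERN_EXEMPLARS:
            d = (text.index(drug), text.index(drug) + len(drug))
            r = (text.index(reason), text.index(reason) + len(reason))
            if pattern_id in match_context_patterns(text, d, r):
                matched.add(pattern_id)
        assert matched == {p.pattern_id for p in default_context_patterns()}

    def test_drug_for_reason_family_matches_prose_sentence(self):
        text = "The patient received morphine for pain as needed"
        got = match_context_patterns(text, (21, 29), (34, 38))
        assert "drug_prn_reason" in got

    def test_far_apart_beyond_gap_limit_is_empty(self):
        filler = "word " * 40
        text = f"coumadin was continued. {filler.strip()}. More text then afib."
        d = (0, 8)
        r = (text.index("afib"), text.index("afib") + 4)
        assert match_context_patterns(text, d, r) == []

    def test_priority_order_preserved(self):
        # 'prn' family outranks 'given for' family when both match
        text = "oxycodone given for pain prn pain."
        d = (0, 9)
        r = (20, 24)
        got = match_context_patterns(text, d, r)
        assert got == sorted(
            got, key=lambda pid: [p.pattern_id for p in default_context_patterns()].index(pid)
        )


class TestOffLabelScreen:
    def test_exact_and_case_folded_match(self):
        kb = {("acetaminophen", "pain")}
        res = off_label_screen([("acetaminophen", "pain"), ("acetaminophen", "Pain")], kb)
        assert len(res.on_label) == 2 and res.unknown == []

    def test_planted_misses_yield_30_percent(self):
        kb = load_kb()
        pairs = [("acetaminophen", "pain")] * 7 + [
            ("acetaminophen", "toenail discoloration"),
            ("senna", "hiccups"),
            ("coumadin", "insomnia"),
        ]
        res = off_label_screen(pairs, kb)
        assert len(res.unknown) == 3
        assert res.pct_unknown == 30.0

    def test_empty_kb_all_unknown(self):
        res = off_label_screen([("a", "b")], set())
        assert res.on_label == [] and len(res.unknown) == 1


class TestCountTableSummaries:
    def test_distance_percents(self):
        hist = {0: 72, 1: 18, 2: 10}
        rep = summarize_count_tables(distance_hist=hist)
        assert rep["pct_same_sentence"] == 72
        assert rep["pct_within_adjacent"] == 90

    def test_off_label_mean_of_runs(self):
        rep = summarize_count_tables(off_label_hits=[7, 10, 3])
        assert rep["off_label_pct"] == 6.7
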