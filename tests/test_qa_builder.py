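"""Grouping, question rendering, entry emission, SQuAD I/O, splitting."""

import json

import pytest

from rxwhyqa.qa_builder import (
    BuildConfig,
    Category,
    QuestionTemplate,
    build_qa_entries,
    group_relations,
    largest_remainder_sizes,
    read_squad,
    render_question,
    split_documents,
    write_squad,
)
from rxwhyqa.synthetic_corpus import GeneratorConfig, generate_corpus

from conftest import make_standoff


class TestGrouping:
    def test_one_drug_one_reason(self, morphine_doc):
        (g,) = group_relations(morphine_doc)
        assert g.category == Category.ONE_TO_ONE
        assert g.drug_terms == ("morphine",)
        assert g.distinct_reason_strings == ("pain",)

    def test_one_drug_no_reason(self, mirtazapine_doc):
        (g,) = group_relations(mirtazapine_doc)
        assert g.category == Category.ONE_DRUG_NO_REASON
        assert g.reason_mentions == ()

    def test_shared_reason_yields_singles_plus_multidrug(self, multidrug_doc):
        groups = group_relations(multidrug_doc)
        singles = [g for g in groups if len(g.drug_terms) == 1]
        multi = [g for g in groups if len(g.drug_terms) > 1]
        assert [g.category for g in singles] == [Category.ONE_TO_ONE] * 3
        (m,) = multi
        assert m.category == Category.N_TO_ONE
        assert m.drug_terms == ("amlodipine", "metoprolol", "isosorbide")

    def test_one_drug_n_reasons(self, albuterol_doc):
        (g,) = group_relations(albuterol_doc)
        assert g.category == Category.ONE_TO_N
        assert g.distinct_reason_strings == ("sob", "wheeze")

    def test_m_drugs_n_reasons(self, asa_plavix_doc):
        groups = group_relations(asa_plavix_doc)
        singles = [g for g in groups if len(g.drug_terms) == 1]
        multi = [g for g in groups if len(g.drug_terms) > 1]
        assert {g.category for g in singles} == {Category.ONE_TO_N}
        (m,) = multi
        assert m.category == Category.M_TO_N
        assert m.drug_terms == ("asa", "plavix")  # lowercased, mention order
        assert len(m.distinct_reason_strings) == 2

    def test_case_variants_merge_to_one_term(self, asa_plavix_doc):
        # 'ASA' appears twice with different relations but is one drug term
        singles = [
            g for g in group_relations(asa_plavix_doc) if g.drug_terms == ("asa",)
        ]
        assert len(singles) == 1
        assert len(singles[0].drug_mentions) == 2


class TestRenderQuestion:
    @pytest.mark.parametrize(
        "terms,expected",
        [
            (["morphine"], "Why was morphine prescribed to the patient?"),
            (
                ["amlodipine", "metoprolol", "isosorbide"],
                "Why were amlodipine, metoprolol, and isosorbide prescribed to the patient?",
            ),
            (["asa", "plavix"], "Why were asa and plavix prescribed to the patient?"),
        ],
    )
    def test_canonical_forms(self, terms, expected):
        assert render_question(terms)[0] == expected

    def test_empty_terms_rejected(self):
        with pytest.raises(ValueError):
            render_question([])

    def test_paraphrase_templates_emit_one_question_each(self):
        templates = [
            QuestionTemplate(
                "Why was {drugs} prescribed to the patient?",
                "Why were {drugs} prescribed to the patient?",
            ),
            QuestionTemplate(
                "What was the reason for prescribing {drugs}?",
                "What was the reason for prescribing {drugs}?",
            ),
        ]
        got = render_question(["senna"], templates)
        assert got == [
            "Why was senna prescribed to the patient?",
            "What was the reason for prescribing senna?",
        ]


class TestBuildEntries:
    def test_answerable_entry_with_offset(self, morphine_doc):
        (e,) = build_qa_entries(morphine_doc)
        assert not e.is_impossible
        (a,) = e.answers
        assert a.text == "pain"
        assert morphine_doc.document.text[a.answer_start : a.answer_start + 4] == "pain"

    def test_unanswerable_entry(self, mirtazapine_doc):
        (e,) = build_qa_entries(mirtazapine_doc)
        assert e.is_impossible and e.answers == ()

    def test_duplicate_answer_strings_retained(self):
        text = "tylenol for pain. pain again. pain still."
        ann = make_standoff(
            text,
            [
                ("Drug", "tylenol", 0),
                ("Reason", "pain", 0),
                ("Reason", "pain", 1),
                ("Reason", "pain", 2),
            ],
            [(0, 1), (0, 2), (0, 3)],
        )
        (e,) = build_qa_entries(ann)
        assert len(e.answers) == 3
        assert e.distinct_answer_strings == ("pain",)
        assert len({a.answer_start for a in e.answers}) == 3

    def test_multidrug_modes(self, multidrug_doc):
        both = build_qa_entries(multidrug_doc, BuildConfig(multidrug_mode="both"))
        split = build_qa_entries(multidrug_doc, BuildConfig(multidrug_mode="split_only"))
        combined = build_qa_entries(
            multidrug_doc, BuildConfig(multidrug_mode="combined_only")
        )
        assert len(both) == 4 and len(split) == 3 and len(combined) == 1
        assert combined[0].drug_names == ("amlodipine", "metoprolol", "isosorbide")
        assert len(combined[0].answers) == 1

    def test_qa_ids_deterministic(self, albuterol_doc):
        first = [e.qa_id for e in build_qa_entries(albuterol_doc)]
        second = [e.qa_id for e in build_qa_entries(albuterol_doc)]
        assert first == second
        assert first == ["albuterol::albuterol sulfate::t0"]

    def test_conservation_with_templates(self, multidrug_doc):
        templates = [
            QuestionTemplate("Why was {drugs} given?", "Why were {drugs} given?"),
            QuestionTemplate("What indicated {drugs}?", "What indicated {drugs}?"),
        ]
        entries = build_qa_entries(
            multidrug_doc, BuildConfig(multidrug_mode="both", templates=templates)
        )
        # (3 single groups + 1 multidrug group) x 2 templates
        assert len(entries) == 8


class TestSquadIO:
    def test_single_entry_structure(self, morphine_doc):
        entries = build_qa_entries(morphine_doc)
        blob = write_squad(entries, [morphine_doc.document])
        payload = json.loads(blob)
        (qa,) = payload["data"][0]["paragraphs"][0]["qas"]
        assert qa["is_impossible"] is False
        assert qa["_mname"] == ["morphine"]
        assert qa["answers"] == [{"text": "pain", "answer_start": 34}]

    def test_round_trip_over_synthetic_corpus(self):
        docs, ann_sets, _ = generate_corpus(GeneratorConfig(seed=2))
        entries = [e for a in ann_sets for e in build_qa_entries(a)]
        blob = write_squad(entries, docs)
        docs2, entries2 = read_squad(blob)
        assert [d.text for d in docs2] == [d.text for d in docs]
        stripped = [
            (e.qa_id, e.doc_id, e.question, e.drug_names, e.is_impossible, e.answers)
            for e in entries
        ]
        stripped2 = [
            (e.qa_id, e.doc_id, e.question, e.drug_names, e.is_impossible, e.answers)
            for e in entries2
        ]
        assert stripped == stripped2

    def test_byte_identical_output(self, albuterol_doc):
        entries = build_qa_entries(albuterol_doc)
        assert write_squad(entries, [albuterol_doc.document]) == write_squad(
            entries, [albuterol_doc.document]
        )

    def test_offset_verification_aborts(self, morphine_doc):
        entries = build_qa_entries(morphine_doc)
        from rxwhyqa.annotation_io import Document

        corrupted = Document(morphine_doc.document.doc_id, "totally different text here")
        with pytest.raises(ValueError, match="morphine::morphine"):
            write_squad(entries, [corrupted])


class TestSplitDocuments:
    def test_largest_remainder_303(self):
        # quotas 151.5/60.6/90.9; two leftover seats go to the .9 and .6 cells
        assert largest_remainder_sizes(303, (5, 2, 3)) == [151, 61, 91]

    def test_partition_is_disjoint_and_total(self):
        ids = [f"d{i}" for i in range(303)]
        train, dev, test = split_documents(ids, (5, 2, 3), seed=4)
        assert len(train) + len(dev) + len(test) == 303
        assert set(train) | set(dev) | set(test) == set(ids)
        assert not (set(train) & set(dev)) and not (set(dev) & set(test))

    def test_degenerate_ratio_all_train(self):
        ids = ["a", "b", "c"]
        train, dev, test = split_documents(ids, (1, 0, 0), seed=0)
        assert sorted(train) == ids and dev == [] and test == []

    def test_same_seed_same_split(self):
        ids = [f"d{i}" for i in range(50)]
        assert split_documents(ids, (5, 2, 3), 9) == split_documents(ids, (5, 2, 3), 9)
        assert split_documents(ids, (5, 2, 3), 9) != split_documents(ids, (5, 2, 3), 10)

    def test_too_few_documents(self):
        with pytest.raises(ValueError):
            split_documents(["only", "two"], (5, 2, 3), seed=0)
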