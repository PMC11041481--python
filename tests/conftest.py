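"""Shared fixtures: tiny annotated notes built programmatically.

The five conversion-category examples (an unanswerable drug, a plain
drug-for-reason sentence, a multidrug list sharing one reason, a drug
with two reasons, and two drugs sharing two reasons) are constructed
from raw text with offsets located by string search, never hand-typed.
"""

from __future__ import annotations

import pytest

from rxwhyqa.annotation_io import AnnotationSet, read_brat_standoff


def make_standoff(
    text: str,
    mentions: list[tuple[str, str, int]],
    relations: list[tuple[int, int]] = (),
    doc_id: str = "doc",
) -> AnnotationSet:
    """Build an AnnotationSet from (type, substring, occurrence) mention
    specs and (drug_idx, reason_idx) relation specs, via the parser."""
    lines = []
    offsets = []
    for i, (ctype, sub, occurrence) in enumerate(mentions, start=1):
        pos = -1
        for _ in range(occurrence + 1):
            pos = text.index(sub, pos + 1)
        offsets.append(pos)
        lines.append(f"T{i}\t{ctype} {pos} {pos + len(sub)}\t{sub}")
    for k, (di, ri) in enumerate(relations, start=1):
        lines.append(f"R{k}\tReason-Drug Arg1:T{di + 1} Arg2:T{ri + 1}")
    return read_brat_standoff(text, "\n".join(lines) + "\n", doc_id=doc_id)


@pytest.fixture
def morphine_doc() -> AnnotationSet:
    """1 drug, 1 reason."""
    text = "The patient received morphine for pain as needed"
    return make_standoff(
        text,
        [("Drug", "morphine", 0), ("Reason", "pain", 0)],
        [(0, 1)],
        doc_id="morphine",
    )


@pytest.fixture
def mirtazapine_doc() -> AnnotationSet:
    """1 drug, no reason."""
    text = "Mirtazapine 15 mg PO QHS"
    return make_standoff(text, [("Drug", "Mirtazapine", 0)], doc_id="mirtazapine")


@pytest.fixture
def multidrug_doc() -> AnnotationSet:
    """N drugs, 1 reason."""
    text = (
        "Hypertension: severely elevated blood pressure. "
        "Started amlodipine, metoprolol, and isosorbide."
    )
    return make_standoff(
        text,
        [
            ("Reason", "severely elevated blood pressure", 0),
            ("Drug", "amlodipine", 0),
            ("Drug", "metoprolol", 0),
            ("Drug", "isosorbide", 0),
        ],
        [(1, 0), (2, 0), (3, 0)],
        doc_id="multidrug",
    )


@pytest.fixture
def albuterol_doc() -> AnnotationSet:
    """1 drug, N reasons."""
    text = "Albuterol sulfate 90 mcg Puff Inhalation Q4H for sob or wheeze."
    return make_standoff(
        text,
        [
            ("Drug", "Albuterol sulfate", 0),
            ("Reason", "sob", 0),
            ("Reason", "wheeze", 0),
        ],
        [(0, 1), (0, 2)],
        doc_id="albuterol",
    )


@pytest.fixture
def asa_plavix_doc() -> AnnotationSet:
    """M drugs, N reasons (with repeated drug mentions)."""
    text = (
        "Left frontoparietal stroke - maintained on ASA and plavix.\n"
        "Hx of CVA: restarted ASA and Plavix per the GI team's recommendation."
    )
    ann = make_standoff(
        text,
        [
            ("Reason", "Left frontoparietal stroke", 0),
            ("Drug", "ASA", 0),
            ("Drug", "plavix", 0),
            ("Reason", "Hx of CVA", 0),
            ("Drug", "ASA", 1),
            ("Drug", "Plavix", 0),
        ],
        [(1, 0), (2, 0), (4, 3), (5, 3)],
        doc_id="asa-plavix",
    )
    return ann
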