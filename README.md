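# rxwhyqa

A toolkit for building, analyzing, answering, and scoring **multi-answer /
multi-focus drug-reason extractive-QA corpora** derived from clinical notes.

Clinical "why" questions — *Why was morphine prescribed to the patient?* —
can be answered by locating the documented indication in the note itself.
Unlike mainstream extractive-QA datasets, realistic clinical notes break the
one-answer-per-question mold in two ways: one drug may have **several
documented reasons** (all of which are needed for a complete answer), and one
question may ask about **several drugs at once** (*Why were amlodipine,
metoprolol, and isosorbide prescribed...*). This package turns drug→reason
relation annotations (BRAT standoff, the clinical-challenge convention) into
a SQuAD-2.0-style dataset that keeps those constructs, including
unanswerable questions and duplicate answer mentions at distinct offsets.

It is aimed at clinical-NLP researchers who need to (a) regenerate or audit
such a dataset from relation annotations, (b) benchmark single-answer QA
models on multi-answer questions via **incremental answer masking**, and
(c) score M-gold-vs-N-model answer sets with partial credit.

## What's inside

| Module | Role |
|---|---|
| `annotation_io` | read/validate/write notes + standoff Drug/Reason annotations |
| `qa_builder` | relation grouping, question rendering, SQuAD-2.0 emission, 5:2:3 document splits |
| `corpus_stats` | answer-count distribution, term/pair frequencies, sentence distance, trigger-pattern matching, on/off-label screen |
| `synthetic_corpus` | seeded generator of notes with planted relations + ground-truth manifest |
| `eqa_models` | the single-answer model contract, a rule-based pattern baseline, a scripted test double, threshold calibration |
| `masking_driver` | the incremental-masking loop with a machine-checked termination certificate |
| `mn_eval` | weighted token-overlap precision/recall/F1 with per-slice reports |

## The two core algorithms

**Incremental answer masking.** A single-answer extractive model is run on a
question's context; its top answer *a* is recorded, then every
case-insensitive occurrence of *a* in that question's working copy of the
note is replaced with `_` characters of identical length. The model runs
again on the masked text; any *novel* answer (normalized string not yet
recorded, not composed of mask characters) is recorded and masked in turn.
A question freezes when the model refrains, repeats itself, or returns a
mask-only span; the loop ends when a full round yields no novel answer.
Masking is monotone and length-preserving, so each productive round masks at
least one new character — which bounds the number of rounds by the context
length and yields a checkable termination certificate.

**Weighted token-overlap F1.** With gold answers G and model answers M for a
question, let tok(·) be the normalized token multiset (lowercase, punctuation
stripped, articles removed). Anchoring on each gold answer g, the model
answer m\* with the most overlapping tokens is selected:

    wTP = Σ_g |tok(g) ∩ tok(m*)|        wFN = Σ_g |tok(g)| − |tok(g) ∩ tok(m*)|

and vice versa anchoring on each model answer m (against its best gold g\*):

    wFP = Σ_m |tok(m)| − |tok(m) ∩ tok(g*)|

Counts pool over the question set (micro), then

    P = wTP / (wTP + wFP)    R = wTP / (wTP + wFN)    F1 = 2PR / (P + R)

Correct abstention on an unanswerable question scores one sentinel
true-positive token, so those questions participate in the pooled metrics.
An independent brute-force oracle re-derives every score by exhaustive
enumeration in the test suite.

## Worked example

One drug, two documented reasons, recovered by the pattern baseline through
the masking loop and scored:

```python
from rxwhyqa import (read_brat_standoff, build_qa_entries,
                     extract_multi_answers, termination_certificate)
from rxwhyqa.eqa_models import PatternBaseline
from rxwhyqa import mn_eval

text = "oxycodone was given for pain.\noxycodone prn anxiety.\n"
ann_text = """T1\tDrug 0 9\toxycodone
T2\tReason 24 28\tpain
T3\tDrug 30 39\toxycodone
T4\tReason 44 51\tanxiety
R1\tReason-Drug Arg1:T1 Arg2:T2
R2\tReason-Drug Arg1:T3 Arg2:T4
"""
ann = read_brat_standoff(text, ann_text, doc_id="note-3")
(entry,) = build_qa_entries(ann)
print(entry.question)                     # Why was oxycodone prescribed to the patient?
print([(a.text, a.answer_start) for a in entry.answers])

result = extract_multi_answers(PatternBaseline(), [entry], [ann.document])
print(result.answers[entry.qa_id])
print([(r.round_index, r.novel_answers) for r in termination_certificate(result).rounds])
```

prints

```
Why was oxycodone prescribed to the patient?
[('pain', 24), ('anxiety', 44)]
[('pain', 24), ('anxiety', 44)]
[(0, 1), (1, 1), (2, 0)]
```

The entry is a 1-to-N question whose two gold spans carry character offsets
into the note. Round 0 extracts `pain`; after `pain` is masked, round 1
surfaces `anxiety`; round 2 finds nothing new and the loop stops. Scoring
this prediction with `mn_eval.score_question` gives wTP=2, wFN=0, wFP=0,
i.e. P = R = F1 = 1.0.

The same flow is available from the shell:

```bash
rxwhyqa synth --out corpus/ --seed 5          # synthetic notes + manifest
rxwhyqa validate --notes corpus/              # standoff sanity check
rxwhyqa build --notes corpus/ --out qa.json   # SQuAD-2.0-style file
rxwhyqa stats --squad qa.json --notes corpus/ --out stats.json
rxwhyqa answer --squad qa.json --model pattern --out pred.json
rxwhyqa eval --squad qa.json --pred pred.json --out report.json
```

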