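# Methods

This note records the models and procedures the package implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the design decisions taken where the design was genuinely open.

## Data model and annotation conventions

A corpus is a set of documents (clinical notes) with standoff annotations:
typed character-offset mentions (`Drug`, `Reason`) and binary drug→reason
relations between them. Offsets are 0-based, half-open, counted in unicode
characters; line endings are normalized to `\n` **before** offsets are
interpreted, because mixed `\r\n` endings silently shift every subsequent
offset. Discontinuous mentions are preserved as ordered fragment lists at
the annotation layer; only the QA layer flattens them (see below). Mention
types other than Drug/Reason and relations not linking a Drug to a Reason
are ignored with logged counts — the toolkit deliberately does not model
dosage, route, or adverse-event annotations.

Surface-text disagreements that differ only in whitespace are warnings, not
errors: real standoff files frequently collapse whitespace in the text
column while the offsets remain correct.

## From relations to QA entries

Drug identity is the lowercased surface string. Nothing stronger (brand ↔
generic merging, spelling normalization) is attempted, since that would
require a drug lexicon and would silently change question counts.

Per document, every distinct drug string yields one single-drug question
group collecting all reason mentions related to any of its mentions; its
category follows from the number of distinct lowercased reason strings
(0 → unanswerable, 1 → 1-to-1, ≥2 → 1-to-N). Additionally, each maximal set
of ≥2 drug strings with identical nonempty reason-string sets yields one
multidrug group (N-to-1 for a single shared reason, M-to-N otherwise). The
`multidrug_mode` setting controls emission: `both` (default) writes the
split single-drug entries **and** the combined multidrug entry — the
coexistence of split 1-to-1 entries with combined multidrug questions is
what the default models; `split_only` and `combined_only` suppress one side.

Answers are one span per related reason mention, duplicates at distinct
offsets retained on purpose (a reason like "pain" annotated at three places
yields three spans). Because SQuAD answers must be contiguous, a
discontinuous reason mention contributes its longest fragment; the dropped
fragments are logged. Unique-answer counting (for statistics and the 1-to-N
category) dedupes by lowercased answer string.

Questions come from an editable template file (`{drugs}` slot, singular and
plural forms per template); the default file holds only the canonical pair
*Why was/were {drugs} prescribed to the patient?*. Multiple templates
produce paraphrastic entries, the canonical template always first; qa_ids
are deterministic (`<doc>::<drugs>::t<template>`), so identical inputs give
byte-identical output files.

Document-level 5:2:3 splitting uses largest-remainder apportionment (floors
of the exact quotas, leftover seats to the largest fractional remainders,
ties to earlier cells) over a seed-shuffled document list: 303 documents
give 151/61/91. Splitting is by document, never by question, to prevent
context leakage across splits.

## Corpus statistics

* **Answer-count distribution** buckets answerable questions by distinct
  lowercased answer strings (1 / 2 / 3 / 4+); percents round
  half-away-from-zero to integers, so buckets sum to 100 ± 1.
* **Term frequencies** count QA entries (not mention occurrences) per
  lowercased drug, separately for answerable and unanswerable questions,
  plus drug–reason pair frequencies.
* **Sentence distance** is the minimum over all drug-mention × reason-mention
  pairs of the absolute difference of sentence indices (0 = same sentence);
  a mention sits in the sentence containing its first fragment's start. The
  splitter is rule-based — break on newline and on `[.?!]` followed by
  whitespace and an uppercase/numeric character — and pluggable, since any
  model-based splitter can be swapped in behind the same callable signature.
* **Contextual trigger patterns**: four families observed around drug-reason
  pairs (*Reason … started/maintained on Drug*; *Drug … prn / as needed for
  Reason*; *Drug … given for Reason*; *Reason … managed/treated with Drug*),
  compiled to regular expressions with a 12-word ellipsis gap limit,
  parenthesized optionals, and alternation sets. A match requires the slots
  to land exactly on the given mention offsets within the sentence window
  containing both. The optional "as needed for" trigger is read as also
  admitting its elided form (bare *Drug … for … Reason*), which is what lets
  the family match plain prose like "received morphine for pain".
* **On/off-label screen**: a pair is on-label iff the (lowercased drug,
  lowercased reason) strings appear verbatim in a two-column drug→indication
  table; everything else is "unknown" — a candidate off-label use for human
  review, reported with one-decimal rounding. The packaged table
  (`data/toy_kb.tsv`) is a small synthetic stand-in for a real indication
  knowledge base and exists for tests and demos only.

The count-table summarizer applies the same rounding rules to externally
supplied histograms, so published count tables can be fed through the exact
code path used for generated corpora.

## Synthetic corpus generator

The real source corpus sits behind a data-use agreement, so tests run on
synthetic notes with known ground truth. Each document carries one planted
question group; the five category counts, the drug/reason lexicons, the
sentence-gap histogram, the duplicate-answer rate, the trigger-family mix,
and the distractor rate are all configurable. Defaults (10/20/5/3/2 groups,
gap histogram 0.72/0.18/0.06/0.04 over gaps 0–3, duplicate rate 0.25,
family mix proportional to observed frequencies 25/18/14/13, distractor
rate 0.3) mirror the structure reported for the source data release: most
pairs in the same sentence, ~90% within one sentence, a mostly-single-answer
corpus with a multi-answer minority.

Gap-0 relations are realized by one trigger-family sentence containing both
terms; gap-k relations place an anaphoric reason statement k sentences from
a trigger-free drug sentence. Duplicate answer mentions are planted only in
the gap-0 regime, because a restated reason appended after a gap-k
realization would sit adjacent to the drug sentence and shrink the planted
distance. Distractor sentences mention a drug name with no reason trigger,
to exercise false-positive behavior. All sampling flows through one
`random.Random(seed)`; a fixed seed reproduces the corpus byte for byte.

A manifest records the planted truth (per-document category, drug terms,
distinct reasons, answer-mention counts, expected distances, and entry
totals per multidrug mode), and the test suite asserts that the QA builder
and the statistics reproduce it exactly.

`pattern_pure_config()` returns the canonical exact regime — all gaps 0,
single-token reasons, one relation per document, no duplicates, no
distractors — in which the pattern baseline is correct by construction, so
the full pipeline (baseline → masking → evaluation) must reach F1 = 1.0
there. **What passing in this regime shows** is that the plumbing (offsets,
masking bookkeeping, scoring) is sound; it says nothing about performance
on real notes, whose lexical variety, cross-sentence reasoning, abbreviation
noise, and section structure the generator does not emulate.

## The answerer contract and the pattern baseline

An answerer maps (question, drug names, context, no-answer threshold) to
either a single `ModelAnswer(text, answer_start, score)` that verifies
against the context, or an explicit refusal. It must be deterministic and
refrain whenever its best score falls below the threshold. The drug anchor
comes from the question's `_mname` payload rather than re-parsing the
question text, which would add avoidable fragility. (An optional `qa_id`
keyword rides along for test doubles keyed per question.)

The pattern baseline scans sentences containing a drug name with capture
variants of the four trigger families; the reason slot takes the shortest
contiguous token span (≤ 6 tokens, lazy matching), trimmed of leading and
trailing stopwords, punctuation, and mask characters. Each candidate scores
its family's observed-frequency weight (25/18/14/13); the best score wins,
ties break toward the earliest offset, and the baseline refrains when no
candidate survives trimming — which is also what ends its masking loop,
since a fully masked reason slot trims to nothing. The stopword list is a
small fixed set (be-verbs, prepositions, articles) shipped as data.

Threshold calibration runs the answerer once per development question with
an unreachable low threshold, then applies each grid value to the recorded
scores and picks the F1-maximizing value, ties toward the larger (more
conservative) threshold.

A transformer adapter can implement the same contract; its training and
weights are out of scope here and nothing in the test suite depends on one.

## Incremental masking

Masking state is **per question**: one document serves many questions, and
masking a shared copy would destroy other questions' evidence, so "mask
throughout the note" is interpreted per extraction context. The mask is `_`
repeated to the occurrence's length, applied to every case-insensitive,
non-overlapping occurrence left to right; it is monotone (only unmasked
characters change) and length-preserving (so masked-context offsets are
valid original-text coordinates).

Novelty is string identity on lowercased, whitespace-collapsed text — the
minimal reading of "no new answers". Mask-only answers are excluded from
the record but freeze the question, preventing infinite cycling when a
model clings to the masked span; a flag can keep them for replication
studies. The safety cap is 10 rounds (the loop naturally iterates to
quiescence; the cap guards against adversarial answerers) and a run that
hits it is flagged in the termination certificate rather than hidden. The
certificate reports per-round novel-answer and newly-masked-character
counts; strict positivity of the latter in every continuing round bounds
total rounds by context length.

## Evaluation

Scoring and aggregation are described in the README; further choices:

* Tokenization follows the SQuAD evaluation convention (lowercase, strip
  punctuation, drop a/an/the) since the data format is SQuAD-2.0; the
  tokenizer is a plain function and can be replaced.
* Gold and model sets are deduplicated by normalized string before scoring
  (duplicate offsets carry no extra token mass); a flag disables this for
  sensitivity analysis.
* Argmax ties break toward the answer with the smaller original offset, so
  permuting input order never changes a score.
* Micro-pooling (summing wTP/wFN/wFP over questions before computing
  P/R/F1) is the primary aggregate; a macro mean of per-question F1 is
  available separately.
* The abstention sentinel (one token) is what lets unanswerable questions
  contribute to pooled counts; without it a correct refusal would be
  invisible to the metric.
* Slices: full, unanswerable, single-answer vs multi-answer, single-drug vs
  multi-drug (the latter four partition the answerable questions two ways).
  Empty slices are absent from the report, not reported as zero.
* `brute_force_oracle` recomputes every score by exhaustive enumeration
  with an independent token matcher (≤ 6 answers per side); the test suite
  checks equality on worked examples and 1000 randomized instances.

## Problem sizes

The test suite and the acceptance script run on small corpora — 40-document
manifests, 50-question pattern-pure pipelines, 1000-instance oracle sweeps,
303-document splits — chosen so the whole battery completes in seconds
while still exercising every category, every trigger family, and multi-round
masking. The release-level summary numbers are derived from the published
count tables, which is an arithmetic reproduction, not a re-annotation.

## Known limitations

* The sentence splitter is intentionally simple; abbreviation-heavy notes
  ("q.h.s.", "Dr.") will over-split. The interface accepts any splitter.
* The pattern baseline only reads within single sentences; cross-sentence
  reasons (gap ≥ 1) are beyond it by design, as the generator's default
  corpus demonstrates.
* Off-label screening by exact string match has no synonymy; "heart
  failure" vs "CHF" count as unknown. That mirrors the screening step it
  models, where remaining pairs go to human review.
* The weighted overlap metric gives no credit to synonymous answers with
  disjoint tokens ("anaphylaxis" vs "allergic reaction"); reported scores
  are therefore conservative lower bounds.
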