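# Methods

## Problem and model

The package links biomedical text to the NCBI Taxonomy at two levels:
organism *mentions* (a text span plus a tax id) and per-gene organism
*assignments*. The design is deliberately unsupervised and rule-based: a
dictionary matcher plus a fixed four-stage cascade. The only trained
component is the cue-word fallback model, and even that is a closed-form
frequency estimate, not an iterative fit. Everything downstream of the
seeded fixture generator is deterministic by construction.

## Coordinates and preprocessing

All offsets are 0-based, half-open, character-based (not bytes), on the
NFC-normalized document text. A document's sections (title, abstract,
body) are joined with a single space into one `full_text`, and every
sentence, species span and gene span lives in that one coordinate system;
this is also the convention under which PubTator title+abstract offsets
line up without translation.

Sentence segmentation is a rule-based splitter: sentence-final `[.!?]`
must be followed by whitespace and an uppercase letter, digit or opening
quote, and is suppressed after single capital initials ("E." in
*E. coli*), a fixed biomedical abbreviation list (et al., Fig., sp., cf.,
…) and decimals. This errs on the side of under-splitting, which is the
safe direction for the co-occurrence rule (a missed split can only widen a
sentence, never separate a gene from its species). Plain-text input treats
the first non-empty line as the title and the rest as the abstract; a
title/abstract distinction is required for the title weighting below to be
reachable from text input.

Gene spans are inputs (gene NER is an external, upstream concern). A span
crossing a sentence boundary is kept and attributed to the sentence
containing its start, with a warning — input annotations are never
silently dropped; degenerate or out-of-bounds spans are hard errors.

## Dictionary matching

Lexicon names are normalized (lowercase, whitespace runs collapsed) and
compiled into a single case-insensitive regular-expression alternation,
longest pattern first, with token-boundary lookarounds: a match may not be
flanked by an ASCII letter or digit, while hyphens and periods are legal
inside names ("E. coli K-12" is one mention, "ratx" contains no mention).
Internal spaces in a name match arbitrary whitespace runs. Because the
alternation is ordered longest-first and scanning proceeds left to right,
overlapping candidates resolve leftmost-longest. The test suite holds this
path to exact agreement with a brute-force oracle that enumerates every
substring, checks normalized lexicon membership and boundaries, and
applies the same leftmost-longest selection.

Duplicate-name policy in lexicon construction: curated augmentations beat
taxonomy records; among taxonomy records, the lowest tax id wins, with a
logged warning. Conflicting duplicates within the curated set are a hard
error. The packaged lexicon is a small pre-filtered table (~20 organisms)
for tests and demonstrations; production lexicons are built offline with
`build-lexicon`, which applies a taxid whitelist (the offline analogue of
dropping species with no gene records) and curated vernacular additions.

## The cell-name rule

"Same noun phrase" is approximated without a parser: a cell-line name
yields an organism mention iff the token "cell"/"cells" occurs to its
right, within the same sentence, at most 4 tokens away, with every
intervening token a plain content word (alphabetic with internal hyphens
allowed, not on a function-word stoplist, no other punctuation). The
right-window form is an approximation of phrase co-occurrence; a left-side
"cells of the HeLa type" construction does not fire. The mention span
covers the cell-line name only, and a cell-derived mention overlapping a
dictionary mention is discarded in favor of the dictionary reading.

## Specificity inference

Scope is document-wide, not sentence-local: one mention of *Arabidopsis
thaliana* anywhere re-labels every *Arabidopsis* in the document. With a
hierarchy table (TSV `tax_id → parent`), "general" means proper ancestor;
without one, a name-prefix heuristic is used ("X" is general for "X y …").
Among several specific descendants the most-mentioned wins, then the
earliest first occurrence. Spans never change, only tax id and provenance,
and the operation is idempotent (a re-labeled mention is never treated as
general again).

## The cascade

Rules fire strictly in order; the first producing a tax id is recorded.

* **prefix** — pattern `^[a-z][A-Z]` with the letter in the prefix map
  (packaged default: h→9606, m→10090, r→10116, d→7227, z→7955, x→8355,
  y→4932; user-overridable). By default the rule does not require the
  abbreviated organism to be mentioned in the document; `--strict-prefix`
  adds that requirement.
* **cooccurrence** — distance is measured in characters between nearest
  span edges; left (mention end ≤ gene start) beats right; exact distance
  ties go to the earlier mention. Mentions overlapping the gene span are
  ignored.
* **focus** — weighted count = 2×title mentions + other mentions, counted
  over mentions *after* specificity inference so general and specific
  surface forms pool. Ties resolve by the global frequency table's total
  order (count descending, tax id ascending), never randomly. The packaged
  table's counts are synthetic rank-calibrated values; its datum is the
  ordering human > rat > mouse at the top.
* **sri** — reached only when the document has no species mention at all.
  Weight(w, s) = max(0, P(w|s) − max_{s'≠s} P(w|s')) over labels
  {9606, 10090, 4932, 7227}, with conditional probabilities estimated as
  label-conditional relative token frequencies; weights below a floor
  (default 0.01) are dropped, keeping the model sparse. Inference sums
  count-weighted margins; ties and all-zero scores fall back to the global
  frequency rank over the four organisms (human, with the packaged table),
  so every gene in evaluation receives a species whenever a model is
  configured. Tokenization for this model: lowercase alphabetic tokens of
  length ≥ 3, stopword-filtered. The packaged model is trained by
  `train_sri` on the deterministic synthetic cue-word corpus and shipped
  as TSV; it knows exactly the 12 planted cue words and is meant as a
  working default, not a corpus-calibrated model.

## Evaluation conventions

Mention P/R/F uses exact span + exact tax id matching (the strictest
criterion; an overlap mode exists but is labeled non-canonical). A
predicted sub-taxon of the gold species counts as wrong by default
(`ancestor_ok` relaxes this when a hierarchy is available). Assignment
accuracy is reported with a per-rule breakdown whose applicable counts
partition the gold set — so counts sum to the gene total and per-rule
errors sum to total errors, a conservation property the tests enforce on
arbitrary corpora. Empty-denominator conventions: precision 0 with no
predictions, recall 0 with no gold, F 0 when either is 0.

## Synthetic corpus generator

The generator slot-fills fixed sentence templates — no free text — so
character offsets and the gold species of each planted gene are correct by
construction and output is byte-reproducible from the seed. Each document
plants one gene resolvable by a chosen stage: prefix genes (with a
different organism mentioned, proving cascade order), co-occurrence
variants (left, left-beats-right, nearest-of-two-left, right-only,
cell-line-derived), focus documents including deliberate title-weight ties
whose winner is pre-computed with the same frequency table the cascade
uses, and species-free documents carrying cue words. Default quotas are
prefix 0.10, cooccurrence 0.34, focus 0.36, sri 0.20 — focus-heavy, as in
real abstracts, with a meaningful share of species-free documents; doc
counts per rule use floor allocation with largest-remainder rounding. An
optional `label_noise` parameter corrupts a fraction of gold labels, which
must (and does) degrade measured accuracy monotonically.

What the generator does *not* emulate: real biomedical language (anaphora,
acronym definitions, misspellings), multi-gene documents, species missing
from the lexicon, or annotation noise in real gold standards. Passing the
closed loop at accuracy 1.0 therefore demonstrates the internal
consistency of matcher + cascade + scorer under the stated rules, not
performance on real corpora; scoring real corpora additionally requires a
full lexicon build and a converted gold standard via `read_gold`.

## Problem sizes and numerical choices

The acceptance script runs 1000 random ~200-character documents for the
matcher/oracle comparison, a 50-document closed loop, a 25-document
determinism check, and 200 training + 200 held-out documents for cue-word
recovery — sizes at which every check is exact rather than sampled
approximations of an asymptotic claim. There is no floating-point
tolerance anywhere in the pipeline itself; the only real-valued outputs
(rates, weights) are ratios of integer counts.

## Known limitations

* The cell-name rule's right-window is a crude noun-phrase proxy; left
  constructions and long appositions are missed.
* The name-prefix fallback for specificity inference can relate organisms
  that merely share a surface prefix; supply a hierarchy table when
  available.
* The packaged frequency table encodes only a rank order; users evaluating
  tie-breaking against a specific corpus should supply real counts.
* The SRI coefficient is this package's own definition (a one-vs-rest
  conditional-probability margin); other cue-word formulations exist and
  the packaged model's vocabulary is synthetic.
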