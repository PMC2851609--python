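# Methods

This note records the modelling assumptions, parameter choices and numerical
conventions behind `genenorm`, and what the synthetic-data generators do and
do not establish about behavior on real corpora.

## Token model and shapes

Tokenization splits on whitespace and then peels leading/trailing punctuation
off each chunk as single-character tokens, keeping internal punctuation
(hyphens, balanced parentheses) inside the token. This makes shapes like
`aAAA(g)` for `cGKI(alpha)` reachable while still isolating sentence
punctuation, and it guarantees the round-trip invariant that concatenated
token texts equal the sentence's non-space characters — the property the
non-space offset arithmetic of the corpus format relies on.

Shape encoding is case-sensitive and class-based: one `A` per uppercase
letter (acronym length is informative), a single `a` per lowercase run and a
single `1` per digit run (the non-repetition convention for lowercase is
extended to digits; `IL12 → AA1`), whole-token stopwords become `p`, and a
letter run spelling a Greek name becomes `g`. Greek detection is
whole-sub-token, case-insensitive equality against the bundled table of the
24 spelled-out names; stopword detection is whole-token only. Prefix
(`pat$a`) and suffix (`a$vity`) shapes are emitted only for all-lowercase,
non-stopword tokens of at least 5 letters — shorter tokens make the affix
forms degenerate — and both are stored as alternative unknown-case shapes.
The affixes are always the token's own first 3 / last 4 letters, not drawn
from a fixed affix list.

The bundled stopword list is a standard small English list (a custom file
can be supplied everywhere a `SymbolTables` is accepted); the behavior of
the method depends on having *a* sensible list, not on its exact contents.
The biomedical lexicon (term, frequency, optional `gn`/`pr` flag) is empty
by default and is supplied by the user or by the fixture generator.

## The case-based tagger

Cases are `(key, category, previous-token category) → frequency` triples,
known cases keyed by verbatim token and unknown cases keyed by each shape
variant. Retrieval for a token proceeds:

1. known cases matching token and context category — most frequent wins;
2. known cases matching the token under *either* context — most frequent
   wins. This extra stage implements "known cases take priority" strictly:
   a token seen in training is never classified from shapes. It is what
   makes the tagger an exact memorizer on corpora whose tokens are
   unambiguous, which is the designed behavior (and the basis of the
   memorization test);
3. unknown cases by shape variant, plain shape first, then the prefix form,
   then the suffix form (most specific first), context-matched;
4. sub-parts of the token (split at punctuation and letter/digit
   boundaries): the token is positive if any part retrieves a positive case
   strictly more frequent than any negative retrieval for that part;
5. default: not a mention.

Frequency ties break toward "not a mention" (precision bias at the case
level). The tagger runs a forward sweep (running label as context, `False`
at the start) and a backward sweep (context for token *i* is the forward
label of token *i+1*, `False` at the end); a token is positive when either
sweep says so. The union is deliberately recall-oriented: the downstream
normalizer discards mentions that match nothing, so a spurious mention is
cheaper than a missed one. There is no retraining from retrieved cases.
Case bases persist as sorted TSV files (one case per line) in a directory
named by the model id, so models are diffable and portable.

## Corpus format

Annotations are `<id>|<start> <end>|<mention>` with 0-based, both-ends
inclusive offsets counting only non-space characters (`SGPT` in the pinned
training sentence is `0 3`; `alkaline phosphatase` is `13 31`). The reader
validates the length invariant `end − start + 1 = non-space length` per
line, rejects overlapping gold mentions within a sentence (the format cannot
express a preferred reading), accepts `\n`/`\r\n`, and writes `\n`.
`to_char_span` converts to ordinary half-open character offsets for
interoperability. Repeated mention strings are annotated per occurrence,
left to right.

## Variation generation

Within one lexicon tier the cascade is: parenthesis split (outside text +
each top-level group) → per-word validity filter (drop stopwords and lexicon
terms above the tier) → punctuation split → optional digit/Greek boundary
split → lowercase → alphabetical sort, joined by single spaces. Each
surviving part contributes the whole-part variation and, for multi-word
parts, one variation per word; digit-split and unsplit forms are both
emitted (`Bmp4` yields `bmp4` and `4 bmp`), maximizing the exact-match
surface. The tier schedule is fixed at 10,000 / 1,000 / 100 / 50 / 10 / 0
("filter terms with frequency strictly greater than the tier"), preceded by
a pass with no lexicon filtering so that the least-filtered variation is
always in the union regardless of how common a term is. Terms flagged
`gn`/`pr` in the lexicon name genes/proteins and are never filtered.
Filtering a part down to nothing simply contributes no variation at that
tier. Variations are lowercase, single-spaced and order-insensitive by
construction.

## The trainable matcher

Synonym features: lowercased 3-character prefix and suffix (whole string if
shorter), first maximal digit run, first Greek name, bigram and trigram
multisets, and the token shape (per-word shapes joined by spaces for
multi-word synonyms). Pair features compare two bundles: four equality
booleans (empty equals empty), bigram/trigram multiset Dice, a string
similarity, and shape similarity (normalized edit similarity between shape
strings, a pragmatic choice since no canonical formula exists). The `best`
feature set masks to bigram similarity, trigram similarity, equal-number and
string similarity; `all` uses all eight. Booleans enter the numeric vector
as 0/1.

Defaults: `pct_similarity` 0.9, gram selection `both` (a pair passes when
bigram *or* trigram Dice reaches the threshold), algorithm SVM (RBF, C = 1),
feature set `best`, string metric Smith-Waterman. Metric normalizations:
Levenshtein `1 − d/max(len)`; Jaro-Winkler native (prefix weight 0.1, max
4); Smith-Waterman local alignment score (match 2, mismatch −1, gap −1)
divided by `2·min(len)` so identical strings score 1; Monge-Elkan over
whitespace tokens with a Jaro-Winkler inner metric, symmetrized by averaging
both directions; Soft-TFIDF with Jaro-Winkler closeness threshold 0.9 and
IDF statistics taken from the dictionary's synonym set, also symmetrized.

Training pairs are all unordered pairs of distinct synonym strings passing
the n-gram cut-off; a pair is positive when the two strings share a gene.
Negatives are subsampled to 3 per positive (seeded); the classifier seed
also fixes random-forest and logistic-regression initialization, making
training byte-deterministic. Pair enumeration is quadratic in the synonym
count, which is fine at the dictionary sizes the tests use (hundreds of
synonyms); very large dictionaries would want blocking, which is out of
scope here. Degenerate inputs fail loudly: no positives → advise lowering
`pct_similarity`; single-class training sets are rejected.

## Disambiguation

Gene-documents are bags of lowercased, stopword-filtered tokens from the
record's synonyms plus any supplied field/value rows (summaries, GO term
names, interactions; `gene2go` ingestion supplies GO term names only).
Scores: term-frequency cosine (no IDF weighting — the bags are short and the
stopword filter already removes the worst offenders), common token *types*
(set semantics), or their product (default — it requires both lexical
overlap breadth and distributional agreement). `single` mode selects all
argmax-tied candidates (no principled tie-break exists; callers see the
ambiguity); `multiple` mode selects scores ≥ 0.5 × max — a fixed rule, not a
parameter. With all-zero scores, multiple mode selects every candidate
(0 ≥ 0.5·0): a documented edge case. Candidates with one competitor are
selected with score 0 (no disambiguation happened); missing gene-documents
score 0 with a warning. Output candidates are ordered by descending score,
then gene id.

## Synthetic fixtures

The generators encode the statistical structure the method exploits, not
linguistic realism:

* genes come in families of 5 sharing an 11-letter pronounceable symbol stem
  plus a member digit, so within-family symbol pairs sit just above 0.9
  bigram Dice — the hard negatives the matcher must reject;
* synonyms are deterministic perturbations of the symbol (case flip,
  punctuation insertion, Greek suffix and its spelling swap, number suffix,
  hyphen-part reorder), so same-gene pairs are near neighbours (at least one
  pair per gene above 0.6 bigram Dice under any single operator);
* every synonym is one whitespace-free word; with `ambiguity_rate` 0 this
  makes all variation forms gene-unique by construction, and ambiguity is
  injected only through deliberately shared synonyms (one per gene pair,
  `⌊rate·n_genes⌋` of them);
* gene-documents use disjoint per-gene vocabularies, so document-similarity
  disambiguation is solvable exactly;
* corpus sentences embed one synonym each into five templates covering
  sentence-initial, medial and final positions, so the preceding-category
  feature takes both values; template vocabulary contains no digits and so
  never collides with synonym tokens, making every training token
  unambiguous.

Defaults (50 genes × 4 synonyms, all operators, 60 sentences, ambiguity 0,
seed 0) are the conditions of the test suite. Passing tests therefore show
that each mechanism does what it is designed to do under its own modelling
assumptions — memorization, near-duplicate discrimination, tier logic,
relative-threshold selection — not that any particular precision/recall
holds on BioCreative-scale corpora with real nomenclature, which contain
ambiguous tokens, overlapping vocabulary between gene-documents, and
synonyms the perturbation model does not generate. The trainers accept such
corpora unchanged if the user supplies them.

## Numerical conventions and edge cases

* N-gram "percentage in common" is multiset Dice; two strings both shorter
  than `n` have similarity 0 (even when identical).
* Raising `pct_similarity` never increases the candidate-pair count
  (monotonicity is property-tested).
* All randomness (negative subsampling, train/test splits, fixture
  generation) flows from explicit integer seeds; identical seeds give
  byte-identical artifacts, including pickled models.
* Empty inputs are legal where a scientist would expect them (empty sentence
  → no tokens; empty corpus → empty case base with a warning; mention
  matching nothing → empty candidate list) and errors where silence would
  corrupt results (malformed lines carry line numbers; dangling sentence
  ids, duplicate gene ids and violated offset invariants raise).

## Problem sizes in the test suite

The suite trains on fixture corpora of 20–60 sentences, dictionaries of
10–50 genes (up to ~200 synonyms, ~1,200 candidate pairs at the loosest
threshold) and SVM training sets of a few hundred pairs; the whole run,
including the end-to-end acceptance checks, completes in a few seconds.
These sizes were chosen as the smallest at which every mechanism under test
is exercised with comfortable margins.
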