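# genenorm

Trainable gene/protein mention recognition and normalization for biomedical
text. The package is aimed at text-mining pipelines that need to (1) find
gene/protein names in abstracts, (2) map each mention to a database
identifier (e.g. an Entrez Gene ID) using nothing but freely available,
uncurated organism data, and (3) resolve ambiguous matches against the text
of the article itself. It is organism-agnostic: point it at a
`gene_info`-style dictionary for any taxon and train.

## The method

**Recognition — case-based reasoning over token shapes.** Training stores one
*known case* per corpus token, the triple *(token, category,
previous-token category)* with a frequency count, and one *unknown case* per
token **shape**. A shape encodes character classes over the alphabet
`{A, a, 1, p, g, punctuation}`: every uppercase letter is one `A`, a
lowercase run collapses to `a`, a digit run to `1`, a whole-token stopword is
`p`, a spelled-out Greek letter is `g` — so `Dorsal → Aa`, `Bmp4 → Aa1`,
`the → p`, `cGKI(alpha) → aAAA(g)`. Long lowercase tokens add literal-affix
shapes (`patterning → pat$a`, `activity → a$vity`). Tagging retrieves the
most frequent matching case — verbatim token first, shape second, token
sub-parts third — in a forward and a backward sweep whose positive labels are
unioned; maximal positive runs become mentions. Corpus files use the
two-file dialect `"<id> <sentence>"` + `"<id>|<start> <end>|<mention>"`,
with 0-based inclusive offsets counted over non-space characters only.

**Normalization — flexible and machine-learning matching.** *Flexible*
matching is exact matching on **variations**: each synonym (and each
mention) is split at parentheses, digits and Greek letters, stripped of
punctuation, filtered of stopwords and of frequency-tiered biomedical-lexicon
terms (tiers 10,000 → 1,000 → 100 → 50 → 10 → 0), lowercased and
alphabetically re-ordered — e.g. `YPK1 and YKR2(YPK2) genes` yields `ypk1`,
`ykr2` and `ypk2`. The *machine-learning* matcher trains a binary classifier
(SVM, random forest or logistic regression) on synonym pairs pre-selected by
bigram/trigram Dice similarity ≥ `pct_similarity` (same-gene pairs positive,
cross-gene pairs negative), represented by comparison features: equal
prefix/suffix/number/Greek letter, bigram/trigram similarity, string
similarity (Levenshtein, Jaro-Winkler, Smith-Waterman, Monge-Elkan or
Soft-TFIDF) and shape similarity.

**Disambiguation — document similarity.** Each gene carries a
*gene-document*, the token bag of its symbols, aliases, summaries, GO term
names and interactions. Competing candidates are scored against the article
token bag by cosine similarity, number of common tokens, or their product
(default). `single` selection keeps the argmax; `multiple` keeps every
candidate scoring ≥ 50% of the maximum. A mention with one candidate is
selected with score 0.

## Worked example

```python
from collections import Counter
from genenorm import (CBRTagger, SentenceRecord, MentionAnnotation, SymbolTables,
                      GeneRecord, build_dictionary, flexible_match, mention_offsets)
from genenorm.disambig import DisambiguationConfig, GeneDocument, disambiguate

tables = SymbolTables.default()
sentences = [SentenceRecord("S1", "TNF binds the IL-2 receptor ."),
             SentenceRecord("S2", "Expression of TNF was elevated .")]
gold = [MentionAnnotation("S1", *mention_offsets(sentences[0].text, "TNF"), "TNF"),
        MentionAnnotation("S1", *mention_offsets(sentences[0].text, "IL-2"), "IL-2"),
        MentionAnnotation("S2", *mention_offsets(sentences[1].text, "TNF"), "TNF")]

tagger = CBRTagger(model_id="demo").fit(sentences, gold)
for m in tagger.tag("We measured TNF and IL-2 in serum ."):
    print(m.text, (m.start, m.end))
```

prints `TNF (10, 12)` and `IL-2 (16, 19)` — offsets count only non-space
characters, both ends inclusive, so `TNF` starts after the 10 letters of
`Wemeasured`. Normalizing the first mention against a two-gene dictionary in
which `TNF` is a synonym of both genes:

```python
records = [GeneRecord("7124", "9606", "TNF", {"TNF-alpha", "TNFA"}),
           GeneRecord("7125", "9606", "TNNC2", {"TNF", "fast troponin C"})]
store = build_dictionary(records, tables)
mention = tagger.tag("We measured TNF and IL-2 in serum .")[0]
mention.candidates = flexible_match(mention.text, store, tables)

docs = {"7124": GeneDocument("7124", Counter({"tumor": 1, "necrosis": 1,
                                              "cytokine": 2, "inflammation": 1})),
        "7125": GeneDocument("7125", Counter({"troponin": 2, "muscle": 1, "calcium": 1}))}
disambiguate([mention], "a cytokine driving inflammation and necrosis",
             docs, DisambiguationConfig("product", "single"), tables)
for c in mention.candidates:
    print(c.gene_id, round(c.score, 4), c.selected)
```

prints `7124 2.2678 True` and `7125 0.0 False`: both genes matched the
ambiguous synonym `TNF`, but the article shares three token types with the
cytokine's gene-document (cosine ≈ 0.756 × 3 common tokens ≈ 2.268) and none
with the troponin's, so the cytokine is selected.

The same pipeline is available from the shell:

```bash
genenorm fixtures --seed 1 --genes 12 --sentences 30 --out fx
genenorm train-tagger --sentences fx/sentences.txt --annotations fx/annotations.txt --model demo
genenorm tag --model models/demo --in fx/sentences.txt --out tagged.txt
genenorm build-lexicon --gene-info fx/gene_info.tsv --taxon 9913 --name cattle \
    --bio-lexicon fx/bio_lexicon.tsv --out lex
genenorm normalize --lexicon lex/cattle --mode flexible --selection multiple \
    --abstract abstract.txt --mentions tagged.txt --gene-docs fx/gene_documents.tsv \
    --out normalized.tsv
```

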