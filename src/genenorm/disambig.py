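"""Candidate disambiguation by article/gene-document similarity.

Each gene is represented by a *gene-document*: the bag of lowercased,
stopword-filtered tokens compiled from its symbols, aliases, descriptions,
summaries, products, phenotypes, relationships, interactions and Gene
Ontology term names.  A mention with several candidates is resolved by
comparing the article's token bag with each candidate's gene-document using
one of three scores: cosine similarity of term-frequency vectors, the number
of common token types, or their product (the default).  ``single`` selection
keeps the top-scoring candidate(s); ``multiple`` selection keeps every
candidate scoring at least 50% of the maximum.  A mention with exactly one
candidate needs no disambiguation: it is selected with score 0.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from sklearn.base import BaseEstimator

from .lexicon import GeneRecord
from .mention import GeneCandidate, GeneMention
from .text import SymbolTables, token_bag

__all__ = [
    "GeneDocument",
    "DisambiguationConfig",
    "Disambiguator",
    "build_gene_document",
    "score_candidate",
    "disambiguate",
    "apply_selection",
    "load_gene_documents",
    "write_gene_documents",
]

METHODS = ("cosine", "common_tokens", "product")
MODES = ("single", "multiple")

#: Multiple selection keeps candidates scoring at least this fraction of the
#: per-mention maximum.  The rule is fixed, not a tunable parameter.
THRESHOLD_FRACTION = 0.5


@dataclass
class GeneDocument:
    gene_id: str
    tokens: Counter = field(default_factory=Counter)


@dataclass(frozen=True)
class DisambiguationConfig:
    method: str = "product"
    mode: str = "single"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")


def build_gene_document(
    record: GeneRecord,
    annotation_rows: Iterable[tuple[str, str]],
    tables: SymbolTables,
) -> GeneDocument:
    """Compile a gene's descriptive fields into one token bag.

    ``annotation_rows`` are ``(field_name, text)`` pairs (summaries, GO term
    names, interactions, ...); the record's own symbol and synonyms are always
    included.  Missing fields simply contribute nothing.
    """
    bag: Counter = Counter()
    for synonym in sorted(record.synonyms):
        bag.update(token_bag(synonym, tables))
    for _field, value in annotation_rows:
        if value:
            bag.update(token_bag(value, tables))
    return GeneDocument(gene_id=record.gene_id, tokens=bag)


def _cosine(a: Counter, b: Counter) -> float:
    if not a or not b:
        return 0.0
    dot = sum(count * b[token] for token, count in a.items())
    norm = math.sqrt(sum(c * c for c in a.values())) * math.sqrt(sum(c * c for c in b.values()))
    return dot / norm if norm else 0.0


def score_candidate(article_tokens: Counter, doc: GeneDocument, method: str) -> float:
    """Similarity between the article bag and one gene-document."""
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    if not doc.tokens:
        return 0.0
    common = len(set(article_tokens) & set(doc.tokens))
    if method == "common_tokens":
        return float(common)
    cosine = _cosine(article_tokens, doc.tokens)
    if method == "cosine":
        return cosine
    return cosine * common


def apply_selection(candidates: Sequence[GeneCandidate], mode: str) -> float:
    """Set ``selected`` flags from the scores already on the candidates.

    Returns the threshold used: the maximum score for ``single`` mode (ties
    all selected), half the maximum for ``multiple`` mode.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if not candidates:
        return 0.0
    best = max(c.score for c in candidates)
    threshold = best if mode == "single" else THRESHOLD_FRACTION * best
    for c in candidates:
        c.selected = c.score >= threshold
    return threshold


def disambiguate(
    mentions: Sequence[GeneMention],
    article_text: str,
    docs: Mapping[str, GeneDocument],
    config: DisambiguationConfig,
    tables: SymbolTables,
) -> Sequence[GeneMention]:
    """Fill scores and selected flags for every mention, in place.

    Mentions without candidates are untouched; a lone candidate is selected
    with score 0; otherwise candidates are scored against the article and the
    configured selection rule is applied.  Candidates are re-ordered by
    descending score, then gene id, for deterministic output.
    """
    article = token_bag(article_text, tables)
    for mention in mentions:
        if not mention.candidates:
            continue
        if len(mention.candidates) == 1:
            only = mention.candidates[0]
            only.score = 0.0
            only.selected = True
            continue
        for cand in mention.candidates:
            doc = docs.get(cand.gene_id)
            if doc is None:
                warnings.warn(
                    f"no gene-document for candidate {cand.gene_id}; scoring 0", stacklevel=2
                )
                cand.score = 0.0
            else:
                cand.score = score_candidate(article, doc, config.method)
        apply_selection(mention.candidates, config.mode)
        mention.candidates.sort(key=lambda c: (-c.score, c.gene_id))
    return mentions


class Disambiguator(BaseEstimator):
    """Scikit-learn-style wrapper: ``fit`` stores gene-documents, ``transform``
    scores and selects candidates on mentions."""

    def __init__(self, method: str = "product", mode: str = "single",
                 tables: SymbolTables | None = None):
        self.method = method
        self.mode = mode
        self.tables = tables

    def fit(self, X: Mapping[str, GeneDocument] | Iterable[GeneDocument], y=None) -> "Disambiguator":
        if isinstance(X, Mapping):
            self.docs_ = dict(X)
        else:
            self.docs_ = {doc.gene_id: doc for doc in X}
        return self

    def transform(
        self, X: Sequence[GeneMention], article_text: str = ""
    ) -> Sequence[GeneMention]:
        if not hasattr(self, "docs_"):
            raise RuntimeError("Disambiguator is not fitted; call fit() first")
        tables = self.tables if self.tables is not None else SymbolTables.default()
        return disambiguate(
            X, article_text, self.docs_, DisambiguationConfig(self.method, self.mode), tables
        )


# ---------------------------------------------------------------------------
# Gene-document store (TSV: gene_id, field name, text)


def load_gene_documents(
    source: str | Path | Iterable[str], tables: SymbolTables
) -> dict[str, GeneDocument]:
    if isinstance(source, Path):
        lines: Iterable[str] = source.read_text("utf-8").splitlines()
    elif isinstance(source, str):
        lines = source.splitlines()
    else:
        lines = (line.rstrip("\r\n") for line in source)
    docs: dict[str, GeneDocument] = {}
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"gene-document line {lineno}: expected 'gene_id<TAB>field<TAB>text'")
        gene_id, _field, text = parts
        doc = docs.setdefault(gene_id, GeneDocument(gene_id=gene_id))
        doc.tokens.update(token_bag(text, tables))
    return docs


def write_gene_documents(rows: Sequence[tuple[str, str, str]]) -> str:
    """Serialize raw ``(gene_id, field, text)`` rows to the TSV dialect."""
    return "".join(f"{g}\t{f}\t{t}\n" for g, f, t in rows)
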