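"""Organism synonym dictionaries and flexible (variation-based) matching.

A dictionary is built from an Entrez ``gene_info``-style TSV.  Every synonym
is expanded into *variations* by an editing cascade — parenthesis splitting,
stopword/bio-lexicon filtering, digit and Greek-letter boundary splitting,
punctuation removal, lowercasing and alphabetical re-ordering — repeated for
each lexicon frequency tier, so ``YPK1 and YKR2(YPK2) genes`` yields (among
others) the separate variations ``ypk1``, ``ykr2`` and ``ypk2``.  Flexible
matching is then exact matching between the variation sets of a mention and
of the stored synonyms: cheap, order-insensitive and robust to punctuation,
case and boilerplate words, while preserving genuine ambiguity (one variation
may map to several genes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .mention import GeneCandidate
from .text import SymbolTables

__all__ = [
    "GeneRecord",
    "DictionaryStore",
    "load_gene_info",
    "load_gene2go",
    "generate_variations",
    "build_dictionary",
    "flexible_match",
]


@dataclass
class GeneRecord:
    gene_id: str
    taxon_id: str
    symbol: str
    synonyms: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.synonyms = set(self.synonyms)
        if self.symbol:
            self.synonyms.add(self.symbol)
        if not self.synonyms:
            raise ValueError(f"gene {self.gene_id}: at least one synonym is required")


def load_gene_info(source: str | Path | Iterable[str], taxon_id: str) -> list[GeneRecord]:
    """Parse gene_info rows (tax_id, GeneID, Symbol, ..., pipe-separated Synonyms).

    Only rows whose first column equals ``taxon_id`` are kept; ``-`` marks an
    empty synonym field.  Comment lines starting with ``#`` are skipped.
    """
    if isinstance(source, Path):
        lines: Iterable[str] = source.read_text("utf-8").splitlines()
    elif isinstance(source, str):
        lines = source.splitlines()
    else:
        lines = (line.rstrip("\r\n") for line in source)

    records: list[GeneRecord] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 5:
            raise ValueError(f"gene_info row {lineno}: expected >= 5 tab-separated columns")
        if cols[0] != taxon_id:
            continue
        synonyms = set() if cols[4] == "-" else {s for s in cols[4].split("|") if s and s != "-"}
        records.append(
            GeneRecord(gene_id=cols[1], taxon_id=cols[0], symbol=cols[2], synonyms=synonyms)
        )
    if not records:
        warnings.warn(f"no gene_info rows matched taxon {taxon_id!r}", stacklevel=2)
    return records


def load_gene2go(source: str | Path | Iterable[str]) -> list[tuple[str, str, str]]:
    """Parse gene2go rows into ``(gene_id, field, text)`` gene-document rows.

    Columns: tax_id, GeneID, GO_ID, Evidence, Qualifier, GO_term, PubMed,
    Category.  Only the GO term name feeds the disambiguator's
    gene-documents; gene2go plays no role in matching.
    """
    if isinstance(source, Path):
        lines: Iterable[str] = source.read_text("utf-8").splitlines()
    elif isinstance(source, str):
        lines = source.splitlines()
    else:
        lines = (line.rstrip("\r\n") for line in source)
    rows = []
    for line in lines:
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) >= 6 and cols[5] != "-":
            rows.append((cols[1], "go", cols[5]))
    return rows


# ---------------------------------------------------------------------------
# Variation generation


def _paren_parts(text: str) -> list[str]:
    """Split into the outside text and each top-level parenthesized group."""
    outside: list[str] = []
    groups: list[str] = []
    depth = 0
    current: list[str] = []
    for ch in text:
        if ch == "(":
            depth += 1
            if depth == 1:
                continue
        elif ch == ")" and depth > 0:
            depth -= 1
            if depth == 0:
                groups.append("".join(current).strip())
                current = []
                continue
        if depth == 0:
            outside.append(ch)
        else:
            current.append(ch)
    if current:  # unbalanced '(' — treat the remainder as a group
        groups.append("".join(current).strip())
    parts = [" ".join("".join(outside).split())] + [g for g in groups if g]
    return [p for p in parts if p]


def _alnum_subtokens(word: str) -> list[str]:
    """Split a word at punctuation; keep alphanumeric runs."""
    out: list[str] = []
    current = ""
    for ch in word:
        if ch.isalnum():
            current += ch
        elif current:
            out.append(current)
            current = ""
    if current:
        out.append(current)
    return out


def _split_greek(run: str, tables: SymbolTables) -> list[str]:
    low = run.lower()
    if low in tables.greek_letters:
        return [run]
    for name in sorted(tables.greek_letters, key=len, reverse=True):
        if len(low) > len(name):
            if low.startswith(name):
                return [run[: len(name)]] + _split_greek(run[len(name) :], tables)
            if low.endswith(name):
                return _split_greek(run[: -len(name)], tables) + [run[-len(name) :]]
    return [run]


def _digit_greek_split(word: str, tables: SymbolTables) -> list[str]:
    pieces: list[str] = []
    for sub in _alnum_subtokens(word):
        run = ""
        kind = ""
        runs: list[str] = []
        for ch in sub:
            k = "1" if ch.isdigit() else "a"
            if k != kind and run:
                runs.append(run)
                run = ""
            run += ch
            kind = k
        if run:
            runs.append(run)
        for r in runs:
            if r.isdigit():
                pieces.append(r)
            else:
                pieces.extend(_split_greek(r, tables))
    return pieces


def _norm(tokens: Sequence[str]) -> str:
    cleaned = sorted(t.lower() for t in tokens if t)
    return " ".join(cleaned)


def _strip_word(word: str) -> str:
    return "".join(ch for ch in word if ch.isalnum()).lower()


def _is_valid(word: str, tier: int | None, tables: SymbolTables) -> bool:
    core = _strip_word(word)
    if not core:
        return False
    if core in tables.stopwords:
        return False
    return not tables.lexicon_filtered(core, tier)


def generate_variations(text: str, tables: SymbolTables) -> set[str]:
    """All normalized variation strings of a mention or synonym.

    The union is taken over the editing cascade at every lexicon frequency
    tier (plus a pass with no lexicon filtering, so the least-filtered
    variation is always present).  Each parenthesis part contributes both a
    whole-part variation and one variation per surviving word, each emitted
    with and without digit/Greek boundary splitting.
    """
    if not text or not text.strip():
        return set()
    out: set[str] = set()
    parts = _paren_parts(text)
    tiers: list[int | None] = [None] + list(tables.frequency_tiers)
    for tier in tiers:
        for part in parts:
            words = [w for w in part.split() if _is_valid(w, tier, tables)]
            if not words:
                continue
            unsplit: list[str] = []
            split: list[str] = []
            for w in words:
                unsplit.extend(_alnum_subtokens(w))
                split.extend(_digit_greek_split(w, tables))
            out.add(_norm(unsplit))
            out.add(_norm(split))
            if len(words) > 1:
                for w in words:
                    out.add(_norm(_alnum_subtokens(w)))
                    out.add(_norm(_digit_greek_split(w, tables)))
    out.discard("")
    return out


# ---------------------------------------------------------------------------
# Dictionary store


@dataclass
class DictionaryStore:
    """Variation-indexed synonym dictionary for one organism.

    ``variations`` maps each normalized form to ``{gene_id: source synonym}``;
    ambiguity (one form, several genes) is preserved, never resolved here.
    """

    taxon_id: str
    variations: dict[str, dict[str, str]] = field(default_factory=dict)
    records: dict[str, GeneRecord] = field(default_factory=dict)

    def synonyms(self) -> list[str]:
        """All raw synonyms, sorted, with their gene ids: ``[(synonym, gene_id)]``."""
        pairs = []
        for gene_id in sorted(self.records):
            for syn in sorted(self.records[gene_id].synonyms):
                pairs.append((syn, gene_id))
        return pairs

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        var_lines = []
        for form in sorted(self.variations):
            for gene_id in sorted(self.variations[form]):
                var_lines.append(f"{form}\t{gene_id}\t{self.variations[form][gene_id]}\n")
        (directory / "variations.tsv").write_text("".join(var_lines), "utf-8")
        rec_lines = []
        for gene_id in sorted(self.records):
            rec = self.records[gene_id]
            rec_lines.append(
                f"{gene_id}\t{rec.taxon_id}\t{rec.symbol}\t{'|'.join(sorted(rec.synonyms))}\n"
            )
        (directory / "records.tsv").write_text("".join(rec_lines), "utf-8")
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "DictionaryStore":
        directory = Path(directory)
        records: dict[str, GeneRecord] = {}
        taxon_id = ""
        for line in (directory / "records.tsv").read_text("utf-8").splitlines():
            if not line.strip():
                continue
            gene_id, taxon_id, symbol, syns = line.split("\t")
            records[gene_id] = GeneRecord(
                gene_id=gene_id, taxon_id=taxon_id, symbol=symbol, synonyms=set(syns.split("|"))
            )
        variations: dict[str, dict[str, str]] = {}
        for line in (directory / "variations.tsv").read_text("utf-8").splitlines():
            if not line.strip():
                continue
            form, gene_id, source = line.split("\t")
            variations.setdefault(form, {})[gene_id] = source
        store = cls(taxon_id=taxon_id, variations=variations, records=records)
        store._check()
        return store

    def _check(self) -> None:
        for form, genes in self.variations.items():
            for gene_id in genes:
                if gene_id not in self.records:
                    raise ValueError(f"variation {form!r} references unknown gene {gene_id!r}")


def build_dictionary(records: Sequence[GeneRecord], tables: SymbolTables) -> DictionaryStore:
    """Index every synonym of every record by its full variation set."""
    if not records:
        raise ValueError("cannot build a dictionary from zero gene records")
    store = DictionaryStore(taxon_id=records[0].taxon_id)
    for rec in records:
        if rec.gene_id in store.records:
            raise ValueError(f"duplicate gene_id {rec.gene_id!r}")
        store.records[rec.gene_id] = rec
    for rec in records:
        for synonym in sorted(rec.synonyms):
            for form in generate_variations(synonym, tables):
                slot = store.variations.setdefault(form, {})
                # First synonym (alphabetically) wins as the recorded source.
                slot.setdefault(rec.gene_id, synonym)
    return store


def flexible_match(
    mention_text: str, store: DictionaryStore, tables: SymbolTables
) -> list[GeneCandidate]:
    """Genes whose synonym variations intersect the mention's variations."""
    hits: dict[str, str] = {}
    for form in sorted(generate_variations(mention_text, tables)):
        for gene_id, source in store.variations.get(form, {}).items():
            hits.setdefault(gene_id, source)
    return [
        GeneCandidate(gene_id=gene_id, matched_synonym=hits[gene_id])
        for gene_id in sorted(hits)
    ]
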