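"""Seeded generators for toy dictionaries, gene-documents and tagged corpora.

The generators reproduce the statistical structure the method relies on
without any external downloads:

* genes come in *families* sharing a long symbol stem, so different genes
  have highly n-gram-similar symbols (the hard negatives the trainable
  matcher must learn to reject);
* each gene's synonyms are systematic perturbations of its symbol (case
  flips, punctuation insertion, Greek-letter spelling swaps, number suffixes,
  hyphen-part reordering), so same-gene pairs are near neighbours under
  n-gram similarity (the positives);
* every synonym is a single whitespace-free word, so with ``ambiguity_rate``
  0 no two genes share any variation form, and a controlled fraction of
  deliberately shared synonyms creates resolvable ambiguity;
* gene-documents get disjoint per-gene vocabularies, so disambiguation by
  document similarity is solvable by construction;
* corpus sentences embed synonyms at the start, middle and end of template
  sentences, so the preceding-token category takes both values in training.

All outputs are deterministic functions of the spec's seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

from .corpus import MentionAnnotation, SentenceRecord, mention_offsets, write_annotations
from .lexicon import GeneRecord, load_gene_info
from .text import SymbolTables

__all__ = [
    "FixtureSpec",
    "PERTURBATION_OPS",
    "synth_dictionary",
    "synth_records",
    "synth_corpus",
    "synth_bio_lexicon",
    "fixture_tables",
    "worked_example_bundle",
    "write_bundle",
]

PERTURBATION_OPS = (
    "case_flip",
    "punctuation_insert",
    "greek_spell_swap",
    "number_suffix",
    "token_reorder",
)

FIXTURE_TAXON = "9913"
_FAMILY_SIZE = 5
_STEM_LEN = 11  # long stems keep within-family symbol pairs above 0.9 bigram Dice
_DOC_TOKENS_PER_GENE = 10

_TEMPLATES = (
    "{m} was strongly expressed during early development .",
    "Expression of {m} was measured by quantitative assay .",
    "Researchers examined whether {m} interacts with downstream pathways .",
    "Little regulation occurs without {m}",
    "Mutations affecting {m} caused measurable phenotypes .",
)


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_genes: int = 50
    n_synonyms_per_gene: int = 4
    perturbation_ops: tuple[str, ...] = PERTURBATION_OPS
    n_sentences: int = 60
    ambiguity_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_synonyms_per_gene < 1 or self.n_sentences < 0:
            raise ValueError("fixture sizes must be positive (n_sentences may be zero)")
        if not 0.0 <= self.ambiguity_rate < 1.0:
            raise ValueError("ambiguity_rate must lie in [0, 1)")
        unknown = set(self.perturbation_ops) - set(PERTURBATION_OPS)
        if unknown:
            raise ValueError(f"unknown perturbation ops: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# Synonym perturbation operators (each returns a new single-word synonym)


def _op_case_flip(symbol: str) -> str:
    return symbol.lower() if any(c.isupper() for c in symbol) else symbol.upper()


def _op_punctuation_insert(symbol: str) -> str:
    for i in range(len(symbol) - 1, -1, -1):
        if symbol[i].isdigit() and (i == 0 or not symbol[i - 1].isdigit()):
            return symbol[:i] + "-" + symbol[i:]
    mid = len(symbol) // 2
    return symbol[:mid] + "-" + symbol[mid:]


def _op_greek_suffix(symbol: str) -> str:
    return symbol + "-alpha"


def _op_greek_spell_swap(symbol: str) -> str:
    return _op_greek_suffix(symbol).replace("-alpha", "-a")


def _op_number_suffix(symbol: str) -> str:
    return symbol + "-2"


def _op_token_reorder(symbol: str) -> str:
    greek = _op_greek_suffix(symbol)
    head, _, tail = greek.rpartition("-")
    return f"{tail}-{head}"


def _synonyms_for(symbol: str, ops: tuple[str, ...], n: int) -> set[str]:
    variants: list[str] = []
    if "greek_spell_swap" in ops:
        variants.append(_op_greek_suffix(symbol))  # the spelled form the swap acts on
    producers = {
        "case_flip": _op_case_flip,
        "punctuation_insert": _op_punctuation_insert,
        "greek_spell_swap": _op_greek_spell_swap,
        "number_suffix": _op_number_suffix,
        "token_reorder": _op_token_reorder,
    }
    for op in PERTURBATION_OPS:  # fixed order for determinism
        if op in ops:
            variants.append(producers[op](symbol))
    synonyms = {symbol}
    for v in variants:
        if len(synonyms) >= n:
            break
        synonyms.add(v)
    k = 2
    while len(synonyms) < n:  # fallback qualifiers when few ops are enabled
        synonyms.add(f"{symbol}-v{k}")
        k += 1
    return synonyms


# ---------------------------------------------------------------------------
# Dictionary and gene-document generation

_CONSONANTS = "bcdfghklmnprstvz"
_VOWELS = "aeiou"


def _random_stem(rng: random.Random, taken: set[str]) -> str:
    while True:
        chars = []
        for i in range(_STEM_LEN):
            pool = _CONSONANTS if i % 2 == 0 else _VOWELS
            chars.append(rng.choice(pool))
        stem = "".join(chars).upper()
        if stem not in taken:
            taken.add(stem)
            return stem


def _build_genes(spec: FixtureSpec) -> list[GeneRecord]:
    rng = random.Random(spec.seed)
    taken: set[str] = set()
    records: list[GeneRecord] = []
    n_families = (spec.n_genes + _FAMILY_SIZE - 1) // _FAMILY_SIZE
    gene_number = 0
    for _f in range(n_families):
        stem = _random_stem(rng, taken)
        for member in range(1, _FAMILY_SIZE + 1):
            if gene_number >= spec.n_genes:
                break
            gene_number += 1
            symbol = f"{stem}{member}"
            gene_id = str(1000 + gene_number)
            synonyms = _synonyms_for(symbol, spec.perturbation_ops, spec.n_synonyms_per_gene)
            records.append(
                GeneRecord(
                    gene_id=gene_id, taxon_id=FIXTURE_TAXON, symbol=symbol, synonyms=synonyms
                )
            )
    n_shared = min(int(spec.ambiguity_rate * spec.n_genes), spec.n_genes // 2)
    for j in range(n_shared):
        shared = f"AMBISHARED{j + 1}"
        records[2 * j].synonyms.add(shared)
        records[2 * j + 1].synonyms.add(shared)
    return records


def _gene_info_text(records: list[GeneRecord]) -> str:
    lines = []
    for rec in records:
        extra_synonyms = sorted(rec.synonyms - {rec.symbol})
        syn_field = "|".join(extra_synonyms) if extra_synonyms else "-"
        cols = [rec.taxon_id, rec.gene_id, rec.symbol, "-", syn_field] + ["-"] * 11
        lines.append("\t".join(cols) + "\n")
    return "".join(lines)


def _gene_doc_rows(records: list[GeneRecord]) -> list[tuple[str, str, str]]:
    rows = []
    for rec in records:
        vocab = [f"trait{rec.gene_id}w{j}" for j in range(_DOC_TOKENS_PER_GENE)]
        rows.append((rec.gene_id, "summary", " ".join(vocab[:5])))
        rows.append((rec.gene_id, "go", " ".join(vocab[5:8])))
        rows.append((rec.gene_id, "interaction", " ".join(vocab[8:])))
    return rows


def synth_dictionary(spec: FixtureSpec) -> tuple[str, str]:
    """Generate a gene_info-dialect TSV and a gene-document TSV (as text)."""
    records = _build_genes(spec)
    gene_info = _gene_info_text(records)
    docs = "".join(f"{g}\t{f}\t{t}\n" for g, f, t in _gene_doc_rows(records))
    return gene_info, docs


def synth_records(spec: FixtureSpec) -> list[GeneRecord]:
    """The same genes :func:`synth_dictionary` serializes, as parsed records."""
    gene_info, _ = synth_dictionary(spec)
    return load_gene_info(gene_info, FIXTURE_TAXON)


def synth_bio_lexicon() -> str:
    """A fixture bio-lexicon whose frequencies span all six filter tiers.

    The third column flags gene/protein terms that are exempt from filtering.
    """
    entries = [
        ("protein", 20000, ""),
        ("genes", 12000, ""),
        ("gene", 11000, ""),
        ("channel", 5000, ""),
        ("factor", 1200, ""),
        ("receptor", 500, "gn"),
        ("kinase", 300, ""),
        ("family", 80, ""),
        ("member", 60, ""),
        ("subunit", 30, ""),
        ("synthetic", 15, ""),
        ("binding", 8, ""),
        ("domain", 2, ""),
    ]
    return "".join(
        f"{t}\t{f}\t{flag}\n" if flag else f"{t}\t{f}\n" for t, f, flag in entries
    )


def fixture_tables() -> SymbolTables:
    """Bundled symbol tables plus the fixture bio-lexicon."""
    from .text import parse_bio_lexicon

    tables = SymbolTables.default()
    tables.bio_lexicon, tables.bio_keep = parse_bio_lexicon(synth_bio_lexicon())
    return tables


# ---------------------------------------------------------------------------
# Corpus generation


def synth_corpus(
    spec: FixtureSpec, records: list[GeneRecord]
) -> tuple[list[SentenceRecord], list[MentionAnnotation]]:
    """Embed dictionary synonyms into template sentences with gold annotations."""
    if not records:
        raise ValueError("synth_corpus needs a non-empty dictionary")
    rng = random.Random(spec.seed + 7)
    sentences: list[SentenceRecord] = []
    annotations: list[MentionAnnotation] = []
    for i in range(spec.n_sentences):
        rec = records[i % len(records)]
        synonym = rng.choice(sorted(rec.synonyms))
        template = rng.choice(_TEMPLATES)
        text = template.format(m=synonym)
        sentence_id = f"FX{spec.seed % 10_000:04d}S{i:04d}"
        sentences.append(SentenceRecord(sentence_id=sentence_id, text=text))
        start, end = mention_offsets(text, synonym, 0)
        annotations.append(
            MentionAnnotation(sentence_id=sentence_id, start=start, end=end, text=synonym)
        )
    return sentences, annotations


def worked_example_bundle() -> tuple[SentenceRecord, list[MentionAnnotation]]:
    """The pinned regression sentence and its three gold annotations."""
    sentence = SentenceRecord(
        sentence_id="P00030937A0119",
        text=(
            "SGPT, SGOT, and alkaline phosphatase concentrations were essentially "
            "normal in all subjects."
        ),
    )
    annotations = [
        MentionAnnotation("P00030937A0119", 0, 3, "SGPT"),
        MentionAnnotation("P00030937A0119", 5, 8, "SGOT"),
        MentionAnnotation("P00030937A0119", 13, 31, "alkaline phosphatase"),
    ]
    return sentence, annotations


def write_bundle(directory: str | Path, spec: FixtureSpec) -> Path:
    """Write the full fixture bundle (dictionary, docs, lexicon, corpus) to disk."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    gene_info, docs = synth_dictionary(spec)
    (directory / "gene_info.tsv").write_text(gene_info, "utf-8")
    (directory / "gene_documents.tsv").write_text(docs, "utf-8")
    (directory / "bio_lexicon.tsv").write_text(synth_bio_lexicon(), "utf-8")
    records = load_gene_info(gene_info, FIXTURE_TAXON)
    sentences, annotations = synth_corpus(spec, records)
    (directory / "sentences.txt").write_text(
        "".join(f"{s.sentence_id} {s.text}\n" for s in sentences), "utf-8"
    )
    (directory / "annotations.txt").write_text(write_annotations(annotations), "utf-8")
    return directory
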