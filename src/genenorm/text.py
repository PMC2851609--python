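"""Tokenization, token shapes and n-gram similarity.

Every downstream stage (the case-based tagger, the synonym variation
generator, the trainable matcher and the disambiguator) shares the small
text primitives defined here: a whitespace-plus-punctuation tokenizer, the
token *shape* encoding over the alphabet ``{A, a, 1, p, g, punctuation}``,
and multiset n-gram (Dice) similarity.

Shapes encode character classes rather than characters: every uppercase
letter contributes one ``A`` (so acronym length is preserved), a run of
lowercase letters collapses to a single ``a``, a run of digits collapses to
a single ``1``, a whole-token stopword becomes ``p``, a spelled-out Greek
letter becomes ``g`` and punctuation is kept literally.  Long lowercase
tokens additionally expose two literal-affix shapes, a 3-letter prefix form
(``patterning`` -> ``pat$a``) and a 4-letter suffix form (``activity`` ->
``a$vity``); the affixes are cut from the token itself, not drawn from a
predefined list.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "Token",
    "ShapeSet",
    "SymbolTables",
    "FREQUENCY_TIERS",
    "tokenize",
    "shape_of",
    "ngrams",
    "ngram_similarity",
    "load_stopwords",
    "load_bio_lexicon",
    "parse_bio_lexicon",
]

#: Descending cut-offs for tiered bio-lexicon filtering: at tier ``t`` every
#: lexicon term with frequency strictly greater than ``t`` is dropped from a
#: synonym before its variation is formed.  Tier 0 therefore drops all terms.
FREQUENCY_TIERS: tuple[int, ...] = (10000, 1000, 100, 50, 10, 0)

# Affix-form emission bounds: only all-lowercase tokens of at least this many
# letters get prefix/suffix shapes (shorter tokens degenerate).
_MIN_AFFIX_LEN = 5
_PREFIX_LEN = 3
_SUFFIX_LEN = 4


@dataclass(frozen=True)
class Token:
    """A corpus token: its verbatim text and 0-based sentence position."""

    text: str
    index: int

    def __post_init__(self) -> None:
        if not self.text or any(ch.isspace() for ch in self.text):
            raise ValueError(f"token text must be non-empty and space-free: {self.text!r}")
        if self.index < 0:
            raise ValueError("token index must be >= 0")


@dataclass(frozen=True)
class ShapeSet:
    """The shape encodings of one token.

    ``plain`` is always present; ``prefix_form``/``suffix_form`` are only
    emitted for all-lowercase tokens of at least five letters.
    """

    plain: str
    prefix_form: str | None = None
    suffix_form: str | None = None

    def variants(self) -> tuple[str, ...]:
        """All shape strings, most specific first (plain, prefix, suffix)."""
        out = [self.plain]
        if self.prefix_form is not None:
            out.append(self.prefix_form)
        if self.suffix_form is not None:
            out.append(self.suffix_form)
        return tuple(out)


def _read_packaged(name: str) -> list[str]:
    text = resources.files("genenorm.data").joinpath(name).read_text("utf-8")
    return [line.strip() for line in text.splitlines() if line.strip()]


def load_stopwords(path: str | Path) -> set[str]:
    """Load a one-word-per-line stopword file (lowercased on read)."""
    lines = Path(path).read_text("utf-8").splitlines()
    return {line.strip().lower() for line in lines if line.strip()}


def load_bio_lexicon(path: str | Path) -> tuple[dict[str, int], set[str]]:
    """Load a frequency-annotated biomedical-term lexicon file.

    See :func:`parse_bio_lexicon` for the format.
    """
    return parse_bio_lexicon(Path(path).read_text("utf-8"))


def parse_bio_lexicon(text: str) -> tuple[dict[str, int], set[str]]:
    """Parse a frequency-annotated biomedical-term lexicon.

    Format: ``term<TAB>frequency`` with an optional third column holding a
    gene/protein flag (``gn`` or ``pr``).  Flagged terms are recorded in the
    returned keep-set and are exempt from filtering, since they name the very
    entities the normalizer is trying to keep.

    Returns ``(term -> frequency, keep_flagged_terms)``.
    """
    lexicon: dict[str, int] = {}
    keep: set[str] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ValueError(f"bio-lexicon line {lineno}: expected 'term<TAB>frequency'")
        term = parts[0].strip().lower()
        try:
            freq = int(parts[1])
        except ValueError as exc:
            raise ValueError(f"bio-lexicon line {lineno}: bad frequency {parts[1]!r}") from exc
        if freq < 0:
            raise ValueError(f"bio-lexicon line {lineno}: negative frequency")
        lexicon[term] = freq
        if len(parts) > 2 and parts[2].strip().lower() in {"gn", "pr"}:
            keep.add(term)
    return lexicon, keep


@dataclass
class SymbolTables:
    """Shared symbol tables: Greek names, stopwords and the bio-lexicon."""

    greek_letters: set[str] = field(default_factory=set)
    stopwords: set[str] = field(default_factory=set)
    bio_lexicon: dict[str, int] = field(default_factory=dict)
    bio_keep: set[str] = field(default_factory=set)
    frequency_tiers: tuple[int, ...] = FREQUENCY_TIERS

    @classmethod
    def default(
        cls,
        stopwords_path: str | Path | None = None,
        bio_lexicon_path: str | Path | None = None,
    ) -> "SymbolTables":
        """Bundled Greek table and stopword list; empty bio-lexicon unless given."""
        greek = {w.lower() for w in _read_packaged("greek_letters.txt")}
        if stopwords_path is None:
            stop = {w.lower() for w in _read_packaged("stopwords.txt")}
        else:
            stop = load_stopwords(stopwords_path)
        lexicon: dict[str, int] = {}
        keep: set[str] = set()
        if bio_lexicon_path is not None:
            lexicon, keep = load_bio_lexicon(bio_lexicon_path)
        return cls(greek_letters=greek, stopwords=stop, bio_lexicon=lexicon, bio_keep=keep)

    def lexicon_filtered(self, term_lower: str, tier: int | None) -> bool:
        """True when the bio-lexicon drops ``term_lower`` at ``tier``.

        ``tier=None`` means no lexicon filtering at all.  Keep-flagged terms
        (gene/protein names) are never filtered.
        """
        if tier is None or term_lower in self.bio_keep:
            return False
        freq = self.bio_lexicon.get(term_lower)
        return freq is not None and freq > tier


# ---------------------------------------------------------------------------
# Tokenization

_OPEN_FOR = {")": "(", "]": "[", "}": "{"}


def _split_chunk(chunk: str) -> list[str]:
    # Peel leading punctuation one character at a time, then trailing, but
    # keep a trailing closer whose opener is still inside the core so tokens
    # like "cGKI(alpha)" survive whole.
    leading: list[str] = []
    trailing: list[str] = []
    while len(chunk) > 1 and not chunk[0].isalnum():
        leading.append(chunk[0])
        chunk = chunk[1:]
    while len(chunk) > 1 and not chunk[-1].isalnum():
        ch = chunk[-1]
        opener = _OPEN_FOR.get(ch)
        if opener is not None and chunk.count(opener) > chunk[:-1].count(ch):
            break
        trailing.append(ch)
        chunk = chunk[:-1]
    return leading + [chunk] + trailing[::-1]


def tokenize(sentence: str) -> list[Token]:
    """Split a sentence into tokens.

    Whitespace delimits; leading/trailing punctuation of each chunk becomes
    its own single-character token; internal punctuation (hyphens, balanced
    parentheses) stays inside the token.  Concatenating the token texts
    reproduces the sentence's non-space characters exactly.
    """
    texts: list[str] = []
    for chunk in sentence.split():
        texts.extend(_split_chunk(chunk))
    return [Token(t, i) for i, t in enumerate(texts)]


# ---------------------------------------------------------------------------
# Shapes


def _char_class(ch: str) -> str:
    if ch.isalpha():
        return "alpha"
    if ch.isdigit():
        return "digit"
    return "punct"


def _class_runs(text: str) -> Iterator[tuple[str, str]]:
    start = 0
    for i in range(1, len(text) + 1):
        if i == len(text) or _char_class(text[i]) != _char_class(text[start]):
            yield _char_class(text[start]), text[start:i]
            start = i


def _alpha_run_shape(run: str, tables: SymbolTables) -> str:
    if run.lower() in tables.greek_letters:
        return "g"
    out: list[str] = []
    for is_upper, sub in _case_runs(run):
        out.append("A" * len(sub) if is_upper else "a")
    return "".join(out)


def _case_runs(run: str) -> Iterator[tuple[bool, str]]:
    start = 0
    for i in range(1, len(run) + 1):
        if i == len(run) or run[i].isupper() != run[start].isupper():
            yield run[start].isupper(), run[start:i]
            start = i


def shape_of(token_text: str, tables: SymbolTables) -> ShapeSet:
    """Encode a token as its shape strings.

    Examples: ``Dorsal -> Aa``, ``Bmp4 -> Aa1``, ``the -> p``,
    ``cGKI(alpha) -> aAAA(g)``; plus affix forms ``patterning -> pat$a``
    and ``activity -> a$vity`` for long lowercase tokens.
    """
    if not token_text or any(ch.isspace() for ch in token_text):
        raise ValueError(f"shape_of requires a non-empty, space-free token: {token_text!r}")
    low = token_text.lower()
    if low in tables.stopwords:
        plain = "p"
    else:
        pieces: list[str] = []
        for kind, run in _class_runs(token_text):
            if kind == "alpha":
                pieces.append(_alpha_run_shape(run, tables))
            elif kind == "digit":
                pieces.append("1")
            else:
                pieces.append(run)
        plain = "".join(pieces)

    prefix_form: str | None = None
    suffix_form: str | None = None
    if (
        token_text.isalpha()
        and token_text.islower()
        and len(token_text) >= _MIN_AFFIX_LEN
        and low not in tables.stopwords
        and low not in tables.greek_letters
    ):
        prefix_form = token_text[:_PREFIX_LEN] + "$a"
        suffix_form = "a$" + token_text[-_SUFFIX_LEN:]
    return ShapeSet(plain=plain, prefix_form=prefix_form, suffix_form=suffix_form)


# ---------------------------------------------------------------------------
# N-grams


def ngrams(text: str, n: int) -> Counter:
    """Multiset of all contiguous length-``n`` substrings of the lowercased text."""
    if n < 1:
        raise ValueError("n must be >= 1")
    low = text.lower()
    return Counter(low[i : i + n] for i in range(len(low) - n + 1))


def ngram_similarity(a: str, b: str, n: int) -> float:
    """Multiset Dice coefficient between the n-gram profiles of two strings.

    Defined as 0.0 when both strings are shorter than ``n``.
    """
    if not a or not b:
        raise ValueError("ngram_similarity requires non-empty strings")
    ga, gb = ngrams(a, n), ngrams(b, n)
    total = sum(ga.values()) + sum(gb.values())
    if total == 0:
        return 0.0
    common = sum((ga & gb).values())
    return 2.0 * common / total


def token_bag(text: str, tables: SymbolTables) -> Counter:
    """Lowercased, stopword-filtered bag of word tokens for document scoring."""
    bag: Counter = Counter()
    for tok in tokenize(text):
        low = tok.text.lower()
        if low in tables.stopwords:
            continue
        if not any(ch.isalnum() for ch in low):
            continue
        bag[low] += 1
    return bag


def iter_nonspace_offsets(texts: Iterable[str]) -> Iterator[tuple[str, int, int]]:
    """Yield ``(text, start, end)`` cumulative non-space spans for a token sequence."""
    pos = 0
    for text in texts:
        yield text, pos, pos + len(text) - 1
        pos += len(text)
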