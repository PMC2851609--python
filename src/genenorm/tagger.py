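"""Case-based-reasoning gene/protein mention tagger.

Training stores one *known* case per token — the verbatim token text, its
category (inside a gold mention or not) and the category of the preceding
token — and one *unknown* case per shape variant of the token.  Identical
attribute triples are never duplicated; their frequency is incremented
instead.  Tagging retrieves the most frequent matching case, giving known
cases priority over shape-based unknown cases, and falls back to classifying
sub-parts of the token.  A forward pass and a backward pass are combined by
union: a token is positive when either pass labels it positive, which favours
recall (the normalization stage tolerates spurious mentions far better than
missed ones).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from sklearn.base import BaseEstimator

from .corpus import MentionAnnotation, SentenceRecord, mention_offsets
from .mention import GeneMention
from .text import ShapeSet, SymbolTables, Token, shape_of, tokenize

__all__ = ["CaseBase", "CBRTagger", "train", "merge_cases", "classify_token", "tag"]

CaseKey = tuple[str, bool, bool]  # (token text or shape, category, prev category)


@dataclass
class CaseBase:
    """Known (verbatim-token) and unknown (shape) case stores with frequencies."""

    known: dict[CaseKey, int] = field(default_factory=dict)
    unknown: dict[CaseKey, int] = field(default_factory=dict)
    model_id: str = "model"

    def __post_init__(self) -> None:
        if not self.model_id:
            raise ValueError("model_id must be non-empty")

    def upsert_known(self, token_text: str, category: bool, prev: bool, count: int = 1) -> None:
        key = (token_text, category, prev)
        self.known[key] = self.known.get(key, 0) + count

    def upsert_unknown(self, shape: str, category: bool, prev: bool, count: int = 1) -> None:
        key = (shape, category, prev)
        self.unknown[key] = self.unknown.get(key, 0) + count

    # -- persistence: one TSV per store under a directory named by model_id --

    @staticmethod
    def _dump(store: dict[CaseKey, int]) -> str:
        lines = [
            f"{text}\t{int(cat)}\t{int(prev)}\t{freq}\n"
            for (text, cat, prev), freq in sorted(store.items())
        ]
        return "".join(lines)

    @staticmethod
    def _parse(text: str) -> dict[CaseKey, int]:
        store: dict[CaseKey, int] = {}
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"case line {lineno}: expected 4 tab-separated fields")
            store[(parts[0], parts[1] == "1", parts[2] == "1")] = int(parts[3])
        return store

    def save(self, parent_dir: str | Path) -> Path:
        model_dir = Path(parent_dir) / self.model_id
        model_dir.mkdir(parents=True, exist_ok=True)
        (model_dir / "known.tsv").write_text(self._dump(self.known), "utf-8")
        (model_dir / "unknown.tsv").write_text(self._dump(self.unknown), "utf-8")
        return model_dir

    @classmethod
    def load(cls, model_dir: str | Path) -> "CaseBase":
        model_dir = Path(model_dir)
        return cls(
            known=cls._parse((model_dir / "known.tsv").read_text("utf-8")),
            unknown=cls._parse((model_dir / "unknown.tsv").read_text("utf-8")),
            model_id=model_dir.name,
        )


# ---------------------------------------------------------------------------
# Training


def _token_categories(
    tokens: Sequence[Token], annotations: Sequence[MentionAnnotation]
) -> list[bool]:
    """Category per token: True when its non-space span overlaps a gold mention."""
    spans = []
    pos = 0
    for tok in tokens:
        spans.append((pos, pos + len(tok.text) - 1))
        pos += len(tok.text)
    return [
        any(s <= ann.end and ann.start <= e for ann in annotations) for s, e in spans
    ]


def train(
    sentences: Sequence[SentenceRecord],
    annotations: Sequence[MentionAnnotation],
    tables: SymbolTables,
    model_id: str = "model",
) -> CaseBase:
    """Build a case base from a BC2-format corpus."""
    by_sentence: dict[str, list[MentionAnnotation]] = {}
    ids = {s.sentence_id for s in sentences}
    for ann in annotations:
        if ann.sentence_id not in ids:
            raise ValueError(f"annotation references unknown sentence id {ann.sentence_id!r}")
        by_sentence.setdefault(ann.sentence_id, []).append(ann)

    base = CaseBase(model_id=model_id)
    if not sentences:
        warnings.warn("training on an empty corpus: the case base will be empty", stacklevel=2)
        return base
    for record in sentences:
        tokens = tokenize(record.text)
        categories = _token_categories(tokens, by_sentence.get(record.sentence_id, []))
        prev = False
        for tok, cat in zip(tokens, categories):
            base.upsert_known(tok.text, cat, prev)
            for variant in shape_of(tok.text, tables).variants():
                base.upsert_unknown(variant, cat, prev)
            prev = cat
    return base


def merge_cases(base_a: CaseBase, base_b: CaseBase, model_id: str | None = None) -> CaseBase:
    """Union of two case bases; frequencies of identical triples are summed."""
    merged = CaseBase(model_id=model_id or f"{base_a.model_id}+{base_b.model_id}")
    for store_name in ("known", "unknown"):
        target = getattr(merged, store_name)
        for source in (getattr(base_a, store_name), getattr(base_b, store_name)):
            for key, freq in source.items():
                target[key] = target.get(key, 0) + freq
    return merged


# ---------------------------------------------------------------------------
# Classification


def _decide(pos_freq: int, neg_freq: int) -> bool:
    # Frequency tie breaks toward "not a mention" (precision bias).
    return pos_freq > neg_freq


def _known_lookup(base: CaseBase, text: str, prev: bool) -> tuple[int, int] | None:
    pos = base.known.get((text, True, prev), 0)
    neg = base.known.get((text, False, prev), 0)
    if pos or neg:
        return pos, neg
    # Known-case priority extends to prev-mismatched retrievals: a token seen
    # in training is always classified from its own cases, never from shapes.
    pos = sum(base.known.get((text, True, p), 0) for p in (False, True))
    neg = sum(base.known.get((text, False, p), 0) for p in (False, True))
    if pos or neg:
        return pos, neg
    return None


def _unknown_lookup(base: CaseBase, shapes: ShapeSet, prev: bool) -> tuple[int, int] | None:
    for variant in shapes.variants():  # plain first, then prefix, then suffix
        pos = base.unknown.get((variant, True, prev), 0)
        neg = base.unknown.get((variant, False, prev), 0)
        if pos or neg:
            return pos, neg
    return None


def _sub_parts(token_text: str) -> list[str]:
    """Split at punctuation and letter/digit boundaries."""
    parts: list[str] = []
    current = ""
    kind = ""
    for ch in token_text:
        k = "a" if ch.isalpha() else "1" if ch.isdigit() else ""
        if not k:
            if current:
                parts.append(current)
            current, kind = "", ""
            continue
        if k != kind and current:
            parts.append(current)
            current = ""
        current += ch
        kind = k
    if current:
        parts.append(current)
    return parts


def classify_token(
    token: Token | str, prev_category: bool, base: CaseBase, tables: SymbolTables
) -> bool:
    """Classify one token: known cases, then shapes, then sub-parts, else False."""
    text = token.text if isinstance(token, Token) else token
    freqs = _known_lookup(base, text, prev_category)
    if freqs is not None:
        return _decide(*freqs)
    freqs = _unknown_lookup(base, shape_of(text, tables), prev_category)
    if freqs is not None:
        return _decide(*freqs)
    for part in _sub_parts(text):
        if part == text:
            continue
        part_freqs = _known_lookup(base, part, prev_category) or _unknown_lookup(
            base, shape_of(part, tables), prev_category
        )
        if part_freqs is not None and part_freqs[0] > part_freqs[1]:
            return True
    return False


# ---------------------------------------------------------------------------
# Tagging


def _tokenize_with_char_spans(text: str) -> list[tuple[Token, int, int]]:
    out: list[tuple[Token, int, int]] = []
    tokens = tokenize(text)
    cursor = 0
    for tok in tokens:
        start = text.index(tok.text, cursor)
        out.append((tok, start, start + len(tok.text)))
        cursor = start + len(tok.text)
    return out


def tag(text: str, base: CaseBase, tables: SymbolTables) -> list[GeneMention]:
    """Extract mentions from free text.

    Forward pass: left-to-right with the running label as the preceding-token
    category.  Backward pass: right-to-left, taking as context the forward
    label of the right-hand neighbour.  A token is positive when either pass
    says so; maximal positive runs become mentions with non-space offsets.
    """
    spans = _tokenize_with_char_spans(text)
    if not spans:
        return []
    tokens = [tok for tok, _, _ in spans]

    forward: list[bool] = []
    prev = False
    for tok in tokens:
        label = classify_token(tok, prev, base, tables)
        forward.append(label)
        prev = label

    n = len(tokens)
    combined = list(forward)
    for i in range(n - 1, -1, -1):
        context = forward[i + 1] if i + 1 < n else False
        if classify_token(tokens[i], context, base, tables):
            combined[i] = True

    # Cumulative non-space offsets per token.
    nonspace_starts: list[int] = []
    pos = 0
    for tok in tokens:
        nonspace_starts.append(pos)
        pos += len(tok.text)

    mentions: list[GeneMention] = []
    i = 0
    while i < n:
        if not combined[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and combined[j + 1]:
            j += 1
        char_start = spans[i][1]
        char_end = spans[j][2]
        mention_text = text[char_start:char_end]
        start = nonspace_starts[i]
        end = nonspace_starts[j] + len(tokens[j].text) - 1
        mentions.append(GeneMention(text=mention_text, start=start, end=end))
        i = j + 1
    return mentions


# ---------------------------------------------------------------------------
# Estimator interface


class CBRTagger(BaseEstimator):
    """Scikit-learn-style wrapper around the case-based tagger.

    Parameters
    ----------
    model_id : str
        Short identifier naming the on-disk case-base directory.
    tables : SymbolTables or None
        Symbol tables used for shapes; bundled defaults when None.

    Attributes
    ----------
    case_base_ : CaseBase
        The trained known/unknown case stores.
    """

    def __init__(self, model_id: str = "model", tables: SymbolTables | None = None):
        self.model_id = model_id
        self.tables = tables

    def _tables(self) -> SymbolTables:
        return self.tables if self.tables is not None else SymbolTables.default()

    def fit(
        self,
        X: Sequence[SentenceRecord],
        y: Sequence[MentionAnnotation],
    ) -> "CBRTagger":
        """Train on sentences ``X`` with gold mention annotations ``y``."""
        self.case_base_ = train(X, y, self._tables(), model_id=self.model_id)
        return self

    def predict(self, X: Iterable[SentenceRecord | str]) -> list[list[GeneMention]]:
        """Tag each sentence (or raw string); mentions carry the sentence id."""
        self._check_fitted()
        results: list[list[GeneMention]] = []
        for item in X:
            record = item if isinstance(item, SentenceRecord) else SentenceRecord("_", item)
            mentions = tag(record.text, self.case_base_, self._tables())
            for m in mentions:
                m.sentence_id = record.sentence_id if isinstance(item, SentenceRecord) else ""
            results.append(mentions)
        return results

    def tag(self, text: str) -> list[GeneMention]:
        self._check_fitted()
        return tag(text, self.case_base_, self._tables())

    def annotate(self, X: Sequence[SentenceRecord]) -> list[MentionAnnotation]:
        """Tag sentences and return BC2-format annotations."""
        annotations: list[MentionAnnotation] = []
        for record, mentions in zip(X, self.predict(X)):
            for m in mentions:
                annotations.append(
                    MentionAnnotation(
                        sentence_id=record.sentence_id, start=m.start, end=m.end, text=m.text
                    )
                )
        return annotations

    def save(self, parent_dir: str | Path) -> Path:
        self._check_fitted()
        return self.case_base_.save(parent_dir)

    @classmethod
    def from_saved(cls, model_dir: str | Path, tables: SymbolTables | None = None) -> "CBRTagger":
        est = cls(model_id=Path(model_dir).name, tables=tables)
        est.case_base_ = CaseBase.load(model_dir)
        return est

    def _check_fitted(self) -> None:
        if not hasattr(self, "case_base_"):
            raise RuntimeError("CBRTagger is not fitted; call fit() or from_saved() first")


def annotations_for_text(
    sentence: SentenceRecord, mentions: Sequence[GeneMention]
) -> list[MentionAnnotation]:
    """Convenience: re-derive annotations from mention surface strings."""
    seen: dict[str, int] = {}
    out = []
    for m in mentions:
        occ = seen.get(m.text, 0)
        start, end = mention_offsets(sentence.text, m.text, occ)
        seen[m.text] = occ + 1
        out.append(MentionAnnotation(sentence.sentence_id, start, end, m.text))
    return out
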