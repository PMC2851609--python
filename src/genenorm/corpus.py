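"""Reading and writing the BioCreative-2 Gene Mention corpus dialect.

A corpus is two line-oriented UTF-8 files: a sentence file with lines
``<id> <sentence text>`` and an annotation file with lines
``<id>|<start> <end>|<mention text>``.  Offsets are 0-based, both ends
inclusive, and count only non-space characters of the sentence — so for
``SGPT, SGOT, and alkaline phosphatase ...`` the mention ``SGPT`` spans
(0, 3) and ``alkaline phosphatase`` spans (13, 31).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "SentenceRecord",
    "MentionAnnotation",
    "CorpusFormatError",
    "read_sentences",
    "read_annotations",
    "write_annotations",
    "mention_offsets",
    "to_char_span",
]


class CorpusFormatError(ValueError):
    """A malformed sentence or annotation line (carries the line number)."""


def _nonspace_len(text: str) -> int:
    return sum(1 for ch in text if not ch.isspace())


@dataclass(frozen=True)
class SentenceRecord:
    sentence_id: str
    text: str

    def __post_init__(self) -> None:
        if not self.sentence_id or any(ch.isspace() for ch in self.sentence_id):
            raise ValueError(f"sentence id must be non-empty and space-free: {self.sentence_id!r}")


@dataclass(frozen=True)
class MentionAnnotation:
    """One gold or predicted mention with inclusive non-space offsets."""

    sentence_id: str
    start: int
    end: int
    text: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"bad offsets ({self.start}, {self.end})")
        expected = self.end - self.start + 1
        actual = _nonspace_len(self.text)
        if actual != expected:
            raise ValueError(
                f"offset span {expected} does not match non-space length {actual} "
                f"of mention {self.text!r}"
            )


def _iter_lines(source: str | Path | Iterable[str]) -> Iterable[str]:
    if isinstance(source, Path):
        return source.read_text("utf-8").splitlines()
    if isinstance(source, str):
        return source.splitlines()
    return (line.rstrip("\r\n") for line in source)


def read_sentences(source: str | Path | Iterable[str]) -> list[SentenceRecord]:
    """Parse a sentence file: one ``<id> <text>`` record per non-empty line."""
    records: list[SentenceRecord] = []
    for lineno, line in enumerate(_iter_lines(source), start=1):
        if not line.strip():
            continue
        sep = line.find(" ")
        if sep <= 0:
            raise CorpusFormatError(f"sentence line {lineno}: expected '<id> <text>'")
        records.append(SentenceRecord(sentence_id=line[:sep], text=line[sep + 1 :]))
    return records


def read_annotations(source: str | Path | Iterable[str]) -> list[MentionAnnotation]:
    """Parse an annotation file, validating offsets and rejecting overlaps.

    Two mentions of the same sentence whose inclusive spans intersect are
    rejected: the format has no way to express which overlapping reading is
    intended.
    """
    annotations: list[MentionAnnotation] = []
    for lineno, line in enumerate(_iter_lines(source), start=1):
        if not line.strip():
            continue
        parts = line.split("|", 2)
        if len(parts) != 3:
            raise CorpusFormatError(f"annotation line {lineno}: expected '<id>|<start> <end>|<text>'")
        ident, span, text = parts
        span_parts = span.split()
        if len(span_parts) != 2:
            raise CorpusFormatError(f"annotation line {lineno}: bad span field {span!r}")
        try:
            start, end = int(span_parts[0]), int(span_parts[1])
        except ValueError as exc:
            raise CorpusFormatError(f"annotation line {lineno}: non-integer offsets") from exc
        try:
            ann = MentionAnnotation(sentence_id=ident, start=start, end=end, text=text)
        except ValueError as exc:
            raise CorpusFormatError(f"annotation line {lineno}: {exc}") from exc
        annotations.append(ann)

    by_sentence: dict[str, list[MentionAnnotation]] = {}
    for ann in annotations:
        for other in by_sentence.get(ann.sentence_id, ()):
            if ann.start <= other.end and other.start <= ann.end:
                raise CorpusFormatError(
                    f"overlapping mentions in sentence {ann.sentence_id}: "
                    f"({other.start},{other.end}) vs ({ann.start},{ann.end})"
                )
        by_sentence.setdefault(ann.sentence_id, []).append(ann)
    return annotations


def write_annotations(annotations: Sequence[MentionAnnotation]) -> str:
    """Serialize annotations; inverse of :func:`read_annotations`."""
    return "".join(f"{a.sentence_id}|{a.start} {a.end}|{a.text}\n" for a in annotations)


def mention_offsets(sentence_text: str, mention_text: str, occurrence: int = 0) -> tuple[int, int]:
    """Non-space (start, end) of the ``occurrence``-th substring match.

    ``start`` counts the non-space characters strictly before the match;
    ``end`` is inclusive.
    """
    if not mention_text:
        raise LookupError("empty mention")
    pos = -1
    for _ in range(occurrence + 1):
        pos = sentence_text.find(mention_text, pos + 1)
        if pos < 0:
            raise LookupError(
                f"mention {mention_text!r} (occurrence {occurrence}) not found in sentence"
            )
    start = _nonspace_len(sentence_text[:pos])
    return start, start + _nonspace_len(mention_text) - 1


def to_char_span(sentence_text: str, start: int, end: int) -> tuple[int, int]:
    """Convert inclusive non-space offsets to a 0-based half-open character span."""
    positions = [i for i, ch in enumerate(sentence_text) if not ch.isspace()]
    if end >= len(positions):
        raise ValueError(f"offset {end} beyond sentence non-space length {len(positions)}")
    return positions[start], positions[end] + 1
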