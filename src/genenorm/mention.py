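"""Shared result types: an extracted mention and its dictionary candidates."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class GeneCandidate:
    """A dictionary gene matched to a mention.

    ``score`` stays 0 when no disambiguation was needed (single candidate);
    ``selected`` marks candidates surviving the active selection rule.
    """

    gene_id: str
    matched_synonym: str
    score: float = 0.0
    selected: bool = False

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("candidate score must be non-negative")


@dataclass
class GeneMention:
    """A tagged span with inclusive non-space offsets and its candidates."""

    text: str
    start: int
    end: int
    sentence_id: str = ""
    candidates: list[GeneCandidate] = field(default_factory=list)

    def selected_candidates(self) -> list[GeneCandidate]:
        return [c for c in self.candidates if c.selected]
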