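"""String similarity metrics for synonym matching, all normalized to [0, 1].

Five metrics are exposed: Levenshtein (edit distance via edlib, normalized by
the longer string), Jaro-Winkler, Smith-Waterman (local alignment with match
+2, mismatch -1, gap -1, normalized by twice the shorter length so identical
strings score 1), Monge-Elkan (token-level average of best Jaro-Winkler
matches, symmetrized) and Soft-TFIDF (TF-IDF-weighted token matching with a
Jaro-Winkler closeness threshold of 0.9, symmetrized by averaging the two
directions).
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Iterable

import edlib
from Bio import Align

__all__ = ["string_similarity", "jaro_winkler", "SoftTfIdfCorpus", "STRING_METRICS"]

STRING_METRICS = ("levenshtein", "jaro_winkler", "smith_waterman", "monge_elkan", "soft_tfidf")

_JW_THRESHOLD = 0.9  # Soft-TFIDF token closeness cut-off
_JW_PREFIX_WEIGHT = 0.1
_JW_MAX_PREFIX = 4


def _levenshtein_distance(a: str, b: str) -> int:
    try:
        return edlib.align(a, b, task="distance")["editDistance"]
    except (ValueError, UnicodeEncodeError):  # alphabet too large for edlib
        return _levenshtein_dp(a, b)


def _levenshtein_dp(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def _jaro(a: str, b: str) -> float:
    if a == b:
        return 1.0
    la, lb = len(a), len(b)
    window = max(la, lb) // 2 - 1
    match_a = [False] * la
    match_b = [False] * lb
    matches = 0
    for i, ch in enumerate(a):
        lo, hi = max(0, i - window), min(lb, i + window + 1)
        for j in range(lo, hi):
            if not match_b[j] and b[j] == ch:
                match_a[i] = match_b[j] = True
                matches += 1
                break
    if matches == 0:
        return 0.0
    transpositions = 0
    k = 0
    for i in range(la):
        if match_a[i]:
            while not match_b[k]:
                k += 1
            if a[i] != b[k]:
                transpositions += 1
            k += 1
    t = transpositions / 2
    m = matches
    return (m / la + m / lb + (m - t) / m) / 3


def jaro_winkler(a: str, b: str) -> float:
    """Jaro similarity with the standard prefix bonus (p = 0.1, max 4 chars)."""
    j = _jaro(a, b)
    prefix = 0
    for ca, cb in zip(a, b):
        if ca != cb or prefix == _JW_MAX_PREFIX:
            break
        prefix += 1
    return j + prefix * _JW_PREFIX_WEIGHT * (1 - j)


def _smith_waterman_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner


_SW = _smith_waterman_aligner()


def _smith_waterman(a: str, b: str) -> float:
    score = _SW.score(a, b)
    return max(0.0, min(1.0, score / (2.0 * min(len(a), len(b)))))


def _monge_elkan_directed(tokens_a: list[str], tokens_b: list[str]) -> float:
    if not tokens_a or not tokens_b:
        return 0.0
    return sum(max(jaro_winkler(ta, tb) for tb in tokens_b) for ta in tokens_a) / len(tokens_a)


class SoftTfIdfCorpus:
    """IDF statistics over a synonym corpus for the Soft-TFIDF metric.

    Without corpus statistics every token weighs the same (IDF = 1).
    """

    def __init__(self, documents: Iterable[str] = ()):
        df: Counter = Counter()
        n = 0
        for doc in documents:
            n += 1
            df.update(set(doc.lower().split()))
        self._df = df
        self._n = n

    def idf(self, token: str) -> float:
        if self._n == 0:
            return 1.0
        return math.log((self._n + 1) / (self._df.get(token, 0) + 1)) + 1.0

    def weights(self, tokens: list[str]) -> dict[str, float]:
        tf = Counter(tokens)
        raw = {t: c * self.idf(t) for t, c in tf.items()}
        norm = math.sqrt(sum(v * v for v in raw.values()))
        return {t: v / norm for t, v in raw.items()} if norm else {}


_EMPTY_CORPUS = SoftTfIdfCorpus()


def _soft_tfidf_directed(tokens_a: list[str], tokens_b: list[str], corpus: SoftTfIdfCorpus) -> float:
    wa = corpus.weights(tokens_a)
    wb = corpus.weights(tokens_b)
    total = 0.0
    for ta, va in wa.items():
        best, best_sim = None, 0.0
        for tb in wb:
            sim = jaro_winkler(ta, tb)
            if sim > best_sim:
                best, best_sim = tb, sim
        if best is not None and best_sim >= _JW_THRESHOLD:
            total += va * wb[best] * best_sim
    return min(1.0, total)


def string_similarity(
    a: str, b: str, metric: str, corpus: SoftTfIdfCorpus | None = None
) -> float:
    """Normalized similarity between two non-empty strings under ``metric``."""
    if not a or not b:
        raise ValueError("string_similarity requires non-empty strings")
    if metric == "levenshtein":
        return 1.0 - _levenshtein_distance(a, b) / max(len(a), len(b))
    if metric == "jaro_winkler":
        return jaro_winkler(a, b)
    if metric == "smith_waterman":
        return _smith_waterman(a, b)
    if metric == "monge_elkan":
        ta, tb = a.split(), b.split()
        return (_monge_elkan_directed(ta, tb) + _monge_elkan_directed(tb, ta)) / 2.0
    if metric == "soft_tfidf":
        c = corpus or _EMPTY_CORPUS
        ta, tb = a.lower().split(), b.lower().split()
        return (_soft_tfidf_directed(ta, tb, c) + _soft_tfidf_directed(tb, ta, c)) / 2.0
    raise ValueError(f"unknown string metric {metric!r}; expected one of {STRING_METRICS}")
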