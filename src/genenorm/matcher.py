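"""Trainable approximate synonym matching.

Training compares dictionary synonyms pairwise: a pair of *different*
synonyms of the same gene is a positive example, a cross-gene pair is a
negative one.  Pairs enter training only when their bigram or trigram Dice
similarity reaches ``pct_similarity`` (0.9 by default), which keeps the
quadratic pair enumeration focused on near-misses — exactly the pairs the
classifier must learn to tell apart.  Each pair is represented by comparison
features (equal prefix/suffix/number/Greek letter, bigram and trigram
similarity, string similarity under one of five metrics, and shape
similarity) and fed to an SVM, random forest or logistic regression.  At
normalization time a mention is paired with every sufficiently similar
synonym and each positively classified pair contributes its gene as a
candidate.
"""

from __future__ import annotations

import dataclasses
import json
import pickle
import random
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .lexicon import DictionaryStore, _digit_greek_split
from .mention import GeneCandidate
from .similarity import SoftTfIdfCorpus, string_similarity
from .text import SymbolTables, ngram_similarity, ngrams, shape_of

__all__ = [
    "SynonymFeatures",
    "PairFeatures",
    "MatcherConfig",
    "MatcherModel",
    "MLMatcher",
    "synonym_features",
    "candidate_pairs",
    "pair_features",
    "train_matcher",
    "ml_match",
    "holdout_accuracy",
]

GRAM_SELECTIONS = ("bigram", "trigram", "both")
ALGORITHMS = ("svm", "random_forest", "logistic_regression")
FEATURE_SETS = ("all", "best")

_AFFIX_LEN = 3  # matcher prefixes and suffixes are both 3 characters


@dataclass(frozen=True)
class MatcherConfig:
    """Matcher hyper-parameters; defaults are the recommended configuration."""

    pct_similarity: float = 0.9
    gram_selection: str = "both"
    algorithm: str = "svm"
    feature_set: str = "best"
    string_metric: str = "smith_waterman"
    negative_ratio: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_similarity <= 1.0:
            raise ValueError("pct_similarity must lie in [0, 1]")
        if self.gram_selection not in GRAM_SELECTIONS:
            raise ValueError(f"gram_selection must be one of {GRAM_SELECTIONS}")
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"feature_set must be one of {FEATURE_SETS}")
        if self.negative_ratio < 1:
            raise ValueError("negative_ratio must be a positive integer")


@dataclass(frozen=True)
class SynonymFeatures:
    prefix3: str
    suffix3: str
    number_part: str
    greek_part: str
    bigrams: Counter
    trigrams: Counter
    shape: str


def _first_digit_run(text: str) -> str:
    run = ""
    for ch in text:
        if ch.isdigit():
            run += ch
        elif run:
            return run
    return run


def _first_greek(text: str, tables: SymbolTables) -> str:
    for word in text.split():
        for piece in _digit_greek_split(word, tables):
            if piece.lower() in tables.greek_letters:
                return piece.lower()
    return ""


def _shape_string(text: str, tables: SymbolTables) -> str:
    return " ".join(shape_of(w, tables).plain for w in text.split())


def synonym_features(text: str, tables: SymbolTables) -> SynonymFeatures:
    """Deterministic feature extraction for one synonym or mention string."""
    if not text or not text.strip():
        raise ValueError("synonym_features requires non-empty text")
    low = text.lower()
    return SynonymFeatures(
        prefix3=low[:_AFFIX_LEN],
        suffix3=low[-_AFFIX_LEN:],
        number_part=_first_digit_run(text),
        greek_part=_first_greek(text, tables),
        bigrams=ngrams(text, 2),
        trigrams=ngrams(text, 3),
        shape=_shape_string(text, tables),
    )


@dataclass(frozen=True)
class PairFeatures:
    equal_prefix: bool
    equal_suffix: bool
    equal_number: bool
    equal_greek: bool
    bigram_sim: float
    trigram_sim: float
    string_sim: float
    shape_sim: float
    label: bool | None = None

    def vector(self, feature_set: str) -> list[float]:
        if feature_set == "best":
            return [self.bigram_sim, self.trigram_sim, float(self.equal_number), self.string_sim]
        return [
            float(self.equal_prefix),
            float(self.equal_suffix),
            float(self.equal_number),
            float(self.equal_greek),
            self.bigram_sim,
            self.trigram_sim,
            self.string_sim,
            self.shape_sim,
        ]


def _dice(a: Counter, b: Counter) -> float:
    total = sum(a.values()) + sum(b.values())
    if total == 0:
        return 0.0
    return 2.0 * sum((a & b).values()) / total


def _shape_similarity(shape_a: str, shape_b: str) -> float:
    if shape_a == shape_b:
        return 1.0
    if not shape_a or not shape_b:
        return 0.0
    # normalized edit similarity over the shape strings
    from .similarity import _levenshtein_dp

    return 1.0 - _levenshtein_dp(shape_a, shape_b) / max(len(shape_a), len(shape_b))


def pair_features(
    fa: SynonymFeatures,
    fb: SynonymFeatures,
    config: MatcherConfig,
    *,
    text_a: str,
    text_b: str,
    corpus: SoftTfIdfCorpus | None = None,
    label: bool | None = None,
) -> PairFeatures:
    """Comparison features of two synonym-feature bundles."""
    return PairFeatures(
        equal_prefix=fa.prefix3 == fb.prefix3,
        equal_suffix=fa.suffix3 == fb.suffix3,
        equal_number=fa.number_part == fb.number_part,
        equal_greek=fa.greek_part == fb.greek_part,
        bigram_sim=_dice(fa.bigrams, fb.bigrams),
        trigram_sim=_dice(fa.trigrams, fb.trigrams),
        string_sim=string_similarity(text_a.lower(), text_b.lower(), config.string_metric, corpus),
        shape_sim=_shape_similarity(fa.shape, fb.shape),
        label=label,
    )


class LabeledPair(NamedTuple):
    a: str
    b: str
    label: bool


def _pair_selected(a: str, b: str, config: MatcherConfig) -> bool:
    bi = ngram_similarity(a, b, 2)
    tri = ngram_similarity(a, b, 3)
    if config.gram_selection == "bigram":
        return bi >= config.pct_similarity
    if config.gram_selection == "trigram":
        return tri >= config.pct_similarity
    return bi >= config.pct_similarity or tri >= config.pct_similarity


def candidate_pairs(store: DictionaryStore, config: MatcherConfig) -> list[LabeledPair]:
    """Labeled training pairs from the dictionary's synonym set.

    Positives are distinct same-gene synonyms passing the n-gram similarity
    cut-off; negatives (cross-gene pairs passing the same cut-off) are
    subsampled to ``negative_ratio`` per positive with the configured seed.
    """
    genes_of: dict[str, set[str]] = {}
    for synonym, gene_id in store.synonyms():
        genes_of.setdefault(synonym, set()).add(gene_id)
    universe = sorted(genes_of)

    positives: list[LabeledPair] = []
    negatives: list[LabeledPair] = []
    for i, s1 in enumerate(universe):
        for s2 in universe[i + 1 :]:
            if not _pair_selected(s1, s2, config):
                continue
            label = bool(genes_of[s1] & genes_of[s2])
            (positives if label else negatives).append(LabeledPair(s1, s2, label))
    if not positives:
        raise ValueError(
            "no positive synonym pairs pass the similarity cut-off; "
            "lower pct_similarity and retrain"
        )
    keep = config.negative_ratio * len(positives)
    if len(negatives) > keep:
        rng = random.Random(config.seed)
        negatives = sorted(rng.sample(negatives, keep))
    return positives + negatives


@dataclass
class MatcherModel:
    """A trained pair classifier plus the configuration it was trained with."""

    classifier: object
    config: MatcherConfig
    taxon_id: str
    corpus: SoftTfIdfCorpus = field(default_factory=SoftTfIdfCorpus)

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "config.json").write_text(
            json.dumps(dataclasses.asdict(self.config), indent=2, sort_keys=True) + "\n", "utf-8"
        )
        with open(directory / "model.pkl", "wb") as fh:
            pickle.dump(self, fh, protocol=4)
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "MatcherModel":
        with open(Path(directory) / "model.pkl", "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, cls):
            raise TypeError("model.pkl does not hold a MatcherModel")
        return model


def _make_classifier(config: MatcherConfig):
    if config.algorithm == "svm":
        return SVC(kernel="rbf", C=1.0, random_state=config.seed)
    if config.algorithm == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=config.seed)
    return LogisticRegression(max_iter=1000, random_state=config.seed)


def _featurize_pairs(
    pairs: Sequence[LabeledPair],
    tables: SymbolTables,
    config: MatcherConfig,
    corpus: SoftTfIdfCorpus,
) -> tuple[np.ndarray, np.ndarray]:
    cache: dict[str, SynonymFeatures] = {}

    def feats(s: str) -> SynonymFeatures:
        if s not in cache:
            cache[s] = synonym_features(s, tables)
        return cache[s]

    rows = []
    labels = []
    for a, b, label in pairs:
        pf = pair_features(
            feats(a), feats(b), config, text_a=a, text_b=b, corpus=corpus, label=label
        )
        rows.append(pf.vector(config.feature_set))
        labels.append(label)
    return np.asarray(rows, dtype=float), np.asarray(labels, dtype=int)


class MLMatcher(BaseEstimator):
    """Scikit-learn-style estimator for the trainable synonym matcher.

    Parameters mirror :class:`MatcherConfig`.  ``fit`` takes a
    :class:`DictionaryStore`; ``match`` normalizes a mention against it.

    Attributes
    ----------
    model_ : MatcherModel
        Trained classifier with its configuration and corpus statistics.
    pairs_ : list[LabeledPair]
        The (cached) labeled training pairs.
    """

    def __init__(
        self,
        pct_similarity: float = 0.9,
        gram_selection: str = "both",
        algorithm: str = "svm",
        feature_set: str = "best",
        string_metric: str = "smith_waterman",
        negative_ratio: int = 3,
        seed: int = 0,
        tables: SymbolTables | None = None,
    ):
        self.pct_similarity = pct_similarity
        self.gram_selection = gram_selection
        self.algorithm = algorithm
        self.feature_set = feature_set
        self.string_metric = string_metric
        self.negative_ratio = negative_ratio
        self.seed = seed
        self.tables = tables

    def config(self) -> MatcherConfig:
        return MatcherConfig(
            pct_similarity=self.pct_similarity,
            gram_selection=self.gram_selection,
            algorithm=self.algorithm,
            feature_set=self.feature_set,
            string_metric=self.string_metric,
            negative_ratio=self.negative_ratio,
            seed=self.seed,
        )

    def _tables(self) -> SymbolTables:
        return self.tables if self.tables is not None else SymbolTables.default()

    def fit(self, X: DictionaryStore, y=None) -> "MLMatcher":
        config = self.config()
        tables = self._tables()
        corpus = SoftTfIdfCorpus(s.lower() for s, _ in X.synonyms())
        self.pairs_ = candidate_pairs(X, config)
        features, labels = _featurize_pairs(self.pairs_, tables, config, corpus)
        if len(set(labels.tolist())) < 2:
            raise ValueError(
                "degenerate single-class training set; the dictionary yields no "
                "negative pairs at this similarity cut-off"
            )
        classifier = _make_classifier(config)
        classifier.fit(features, labels)
        self.model_ = MatcherModel(
            classifier=classifier, config=config, taxon_id=X.taxon_id, corpus=corpus
        )
        self.store_ = X
        return self

    def match(self, mention_text: str, store: DictionaryStore | None = None) -> list[GeneCandidate]:
        self._check_fitted()
        return ml_match(mention_text, store or self.store_, self.model_, self._tables())

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError("MLMatcher is not fitted; call fit() first")


def train_matcher(
    store: DictionaryStore, config: MatcherConfig, tables: SymbolTables | None = None
) -> MatcherModel:
    """Functional wrapper over :class:`MLMatcher`."""
    est = MLMatcher(tables=tables, **dataclasses.asdict(config))
    est.fit(store)
    return est.model_


def ml_match(
    mention_text: str,
    store: DictionaryStore,
    model: MatcherModel,
    tables: SymbolTables,
    config: MatcherConfig | None = None,
) -> list[GeneCandidate]:
    """Normalize one mention with a trained matcher.

    Candidate synonyms are pre-selected by n-gram similarity to the mention;
    each surviving mention-synonym pair is featurized and classified, and
    positive classifications yield the synonym's gene(s) as candidates.
    """
    if config is not None and config != model.config:
        raise ValueError("supplied config differs from the one the model was trained with")
    cfg = model.config
    if not mention_text or not mention_text.strip():
        return []
    mention_feats = synonym_features(mention_text, tables)

    genes_of: dict[str, set[str]] = {}
    for synonym, gene_id in store.synonyms():
        genes_of.setdefault(synonym, set()).add(gene_id)
    selected = [s for s in sorted(genes_of) if _pair_selected(mention_text, s, cfg)]
    if not selected:
        return []

    rows = []
    for synonym in selected:
        pf = pair_features(
            mention_feats,
            synonym_features(synonym, tables),
            cfg,
            text_a=mention_text,
            text_b=synonym,
            corpus=model.corpus,
        )
        rows.append(pf.vector(cfg.feature_set))
    predictions = model.classifier.predict(np.asarray(rows, dtype=float))

    hits: dict[str, str] = {}
    for synonym, positive in zip(selected, predictions):
        if positive:
            for gene_id in sorted(genes_of[synonym]):
                hits.setdefault(gene_id, synonym)
    return [GeneCandidate(gene_id=g, matched_synonym=hits[g]) for g in sorted(hits)]


def holdout_accuracy(
    store: DictionaryStore,
    config: MatcherConfig,
    tables: SymbolTables | None = None,
    test_fraction: float = 0.3,
) -> tuple[float, float]:
    """Held-out pair-classification accuracy and the majority-class baseline.

    Pairs are enumerated once, shuffled with the configured seed, split, and
    the classifier is trained on the training portion only.
    """
    tables = tables or SymbolTables.default()
    pairs = candidate_pairs(store, config)
    rng = random.Random(config.seed + 1)
    shuffled = list(pairs)
    rng.shuffle(shuffled)
    n_test = max(1, int(len(shuffled) * test_fraction))
    test, training = shuffled[:n_test], shuffled[n_test:]
    corpus = SoftTfIdfCorpus(s.lower() for s, _ in store.synonyms())
    X_train, y_train = _featurize_pairs(training, tables, config, corpus)
    X_test, y_test = _featurize_pairs(test, tables, config, corpus)
    if len(set(y_train.tolist())) < 2:
        raise ValueError("degenerate single-class training split")
    classifier = _make_classifier(config)
    classifier.fit(X_train, y_train)
    accuracy = float((classifier.predict(X_test) == y_test).mean())
    baseline = float(max(np.mean(y_test), 1.0 - np.mean(y_test)))
    return accuracy, baseline
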