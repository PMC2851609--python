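"""Synonym features, pair selection and the trainable matcher."""

import pickle

import pytest

from genenorm.fixtures import FixtureSpec, fixture_tables, synth_records
from genenorm.lexicon import GeneRecord, build_dictionary
from genenorm.matcher import (
    MatcherConfig,
    MLMatcher,
    candidate_pairs,
    holdout_accuracy,
    ml_match,
    pair_features,
    synonym_features,
    train_matcher,
)


@pytest.fixture(scope="module")
def fx_tables_m():
    return fixture_tables()


@pytest.fixture(scope="module")
def small_store(fx_tables_m):
    return build_dictionary(synth_records(FixtureSpec(seed=11, n_genes=20)), fx_tables_m)


class TestSynonymFeatures:
    def test_rule_trace(self, tables):
        f = synonym_features("YPK1", tables)
        assert (f.prefix3, f.suffix3, f.number_part, f.greek_part) == ("ypk", "pk1", "1", "")

    def test_short_strings_use_whole_string(self, tables):
        f = synonym_features("ab", tables)
        assert f.prefix3 == "ab" and f.suffix3 == "ab"

    def test_greek_lookup(self, tables):
        assert synonym_features("TNF-alpha", tables).greek_part == "alpha"

    def test_shape_uses_token_encoding(self, tables):
        assert synonym_features("Bmp4", tables).shape == "Aa1"


class TestPairFeatures:
    def test_identity_pair(self, tables):
        cfg = MatcherConfig()
        f = synonym_features("YPK1", tables)
        pf = pair_features(f, f, cfg, text_a="YPK1", text_b="YPK1")
        assert pf.equal_prefix and pf.equal_suffix and pf.equal_number and pf.equal_greek
        assert pf.bigram_sim == pf.trigram_sim == pf.string_sim == pf.shape_sim == 1.0

    def test_number_mismatch(self, tables):
        cfg = MatcherConfig()
        pf = pair_features(
            synonym_features("YPK1", tables),
            synonym_features("YPK2", tables),
            cfg,
            text_a="YPK1",
            text_b="YPK2",
        )
        assert pf.equal_prefix and not pf.equal_number

    def test_disjoint_strings(self, tables):
        cfg = MatcherConfig()
        pf = pair_features(
            synonym_features("abc", tables),
            synonym_features("xyz", tables),
            cfg,
            text_a="abc",
            text_b="xyz",
        )
        assert pf.bigram_sim == 0.0

    @pytest.mark.parametrize(("a", "b"), [("YPK1", "ypk-1"), ("TNF-alpha", "TNFA"), ("Abc12", "xy")])
    def test_symmetry_on_every_nonlabel_field(self, a, b, tables):
        cfg = MatcherConfig(string_metric="levenshtein")
        fa, fb = synonym_features(a, tables), synonym_features(b, tables)
        ab = pair_features(fa, fb, cfg, text_a=a, text_b=b)
        ba = pair_features(fb, fa, cfg, text_a=b, text_b=a)
        assert ab == ba

    def test_best_feature_mask(self, tables):
        cfg = MatcherConfig()
        f = synonym_features("YPK1", tables)
        pf = pair_features(f, f, cfg, text_a="YPK1", text_b="YPK1")
        assert len(pf.vector("best")) == 4
        assert len(pf.vector("all")) == 8


class TestCandidatePairs:
    def test_same_gene_near_variants_are_positive(self, tables):
        store = build_dictionary(
            [
                GeneRecord("1", "9913", "ABCD1", {"abcd1"}),
                GeneRecord("2", "9913", "WXYZ9", {"wxyz9"}),
            ],
            tables,
        )
        pairs = candidate_pairs(store, MatcherConfig(pct_similarity=0.9, negative_ratio=1))
        labels = {(p.a, p.b): p.label for p in pairs}
        assert labels[("ABCD1", "abcd1")] is True  # case variants, bigram Dice 1.0
        assert all(label for (a, b), label in labels.items())  # no cross-gene pair is that close

    def test_identical_strings_never_paired(self, tables):
        store = build_dictionary(
            [GeneRecord("1", "9913", "ABCD1"), GeneRecord("2", "9913", "ABCD1X", {"abcd1"})],
            tables,
        )
        pairs = candidate_pairs(store, MatcherConfig(pct_similarity=0.5))
        assert all(p.a != p.b for p in pairs)

    def test_monotone_in_similarity_threshold(self, small_store):
        counts = [
            len(candidate_pairs(small_store, MatcherConfig(pct_similarity=pct)))
            for pct in (0.6, 0.7, 0.8, 0.9)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_no_positive_pairs_is_an_error(self, tables):
        lone = build_dictionary(
            [GeneRecord("1", "9913", "ABCD1"), GeneRecord("2", "9913", "WXYZ9")], tables
        )
        with pytest.raises(ValueError, match="lower pct_similarity"):
            candidate_pairs(lone, MatcherConfig())

    def test_negative_subsampling_ratio(self, small_store):
        cfg = MatcherConfig(pct_similarity=0.8, negative_ratio=1)
        pairs = candidate_pairs(small_store, cfg)
        n_pos = sum(p.label for p in pairs)
        assert len(pairs) - n_pos <= n_pos


class TestConfig:
    def test_defaults(self):
        cfg = MatcherConfig()
        assert cfg.pct_similarity == 0.9
        assert cfg.gram_selection == "both"
        assert cfg.algorithm == "svm"
        assert cfg.feature_set == "best"
        assert cfg.string_metric == "smith_waterman"

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"pct_similarity": 1.5},
            {"gram_selection": "fourgram"},
            {"algorithm": "perceptron"},
            {"feature_set": "worst"},
            {"negative_ratio": 0},
        ],
    )
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            MatcherConfig(**kwargs)


class TestTrainAndMatch:
    def test_seeded_training_is_byte_deterministic(self, small_store, fx_tables_m, tmp_path):
        cfg = MatcherConfig(seed=7)
        m1 = train_matcher(small_store, cfg, fx_tables_m)
        m2 = train_matcher(small_store, cfg, fx_tables_m)
        assert pickle.dumps(m1.classifier) == pickle.dumps(m2.classifier)
        d1 = m1.save(tmp_path / "a")
        d2 = m2.save(tmp_path / "b")
        assert (d1 / "model.pkl").read_bytes() == (d2 / "model.pkl").read_bytes()

    def test_exact_synonym_matches(self, small_store, fx_tables_m):
        model = train_matcher(small_store, MatcherConfig(), fx_tables_m)
        rec = small_store.records["1001"]
        cands = ml_match(rec.symbol, small_store, model, fx_tables_m)
        assert rec.gene_id in {c.gene_id for c in cands}

    def test_no_ngram_overlap_gives_no_candidates(self, small_store, fx_tables_m):
        model = train_matcher(small_store, MatcherConfig(), fx_tables_m)
        assert ml_match("qqqq", small_store, model, fx_tables_m) == []

    def test_spacing_variant_recovered_at_lower_threshold(self, small_store, fx_tables_m):
        """A mention with punctuation replaced by a space still normalizes."""
        model = train_matcher(small_store, MatcherConfig(pct_similarity=0.6), fx_tables_m)
        rec = small_store.records["1003"]
        mention = rec.symbol[:-1] + " " + rec.symbol[-1]  # "STEM1" -> "STEM 1"
        cands = ml_match(mention, small_store, model, fx_tables_m)
        assert rec.gene_id in {c.gene_id for c in cands}

    def test_config_mismatch_rejected(self, small_store, fx_tables_m):
        model = train_matcher(small_store, MatcherConfig(), fx_tables_m)
        with pytest.raises(ValueError, match="config"):
            ml_match("x1", small_store, model, fx_tables_m, config=MatcherConfig(seed=99))

    def test_degenerate_single_class_training_rejected(self, tables):
        # only same-gene case variants pass the cut-off: no negatives exist
        store = build_dictionary([GeneRecord("1", "9913", "ABCD1", {"abcd1"})], tables)
        with pytest.raises(ValueError, match="single-class"):
            MLMatcher(tables=tables).fit(store)

    def test_holdout_beats_majority_baseline(self, small_store, fx_tables_m):
        accuracy, baseline = holdout_accuracy(small_store, MatcherConfig(), fx_tables_m)
        assert accuracy >= baseline + 0.2

    def test_estimator_params_round_trip(self):
        est = MLMatcher(pct_similarity=0.7, algorithm="random_forest")
        clone_params = est.get_params()
        assert clone_params["pct_similarity"] == 0.7
        assert MLMatcher(**clone_params).config() == est.config()
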