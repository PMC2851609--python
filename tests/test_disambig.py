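"""Gene-document construction, candidate scoring and selection rules."""

import math
from collections import Counter

import pytest

from genenorm.disambig import (
    DisambiguationConfig,
    Disambiguator,
    GeneDocument,
    apply_selection,
    build_gene_document,
    disambiguate,
    load_gene_documents,
    score_candidate,
    write_gene_documents,
)
from genenorm.lexicon import GeneRecord
from genenorm.mention import GeneCandidate, GeneMention


def make_candidates(scores):
    return [GeneCandidate(f"g{i}", "syn", score=s) for i, s in enumerate(scores)]


class TestBuildGeneDocument:
    def test_symbol_only(self, tables):
        doc = build_gene_document(GeneRecord("1", "9913", "TNF"), [], tables)
        assert doc.tokens == Counter({"tnf": 1})

    def test_fields_tokenized_and_filtered(self, tables):
        doc = build_gene_document(
            GeneRecord("1", "9913", "TNF"),
            [("summary", "tumor necrosis factor"), ("go", "cytokine activity")],
            tables,
        )
        assert {"necrosis", "cytokine"} <= set(doc.tokens)
        assert "the" not in doc.tokens

    def test_empty_rows_keep_synonym_tokens(self, tables):
        rec = GeneRecord("1", "9913", "TNF", {"TNF-alpha"})
        doc = build_gene_document(rec, [], tables)
        assert "tnf" in doc.tokens


class TestScoreCandidate:
    def test_identical_bags_cosine_one(self):
        doc = GeneDocument("g", Counter({"a": 2, "b": 1}))
        assert score_candidate(doc.tokens, doc, "cosine") == pytest.approx(1.0)

    def test_disjoint_bags_all_methods_zero(self):
        doc = GeneDocument("g", Counter({"x": 1}))
        art = Counter({"y": 3})
        for method in ("cosine", "common_tokens", "product"):
            assert score_candidate(art, doc, method) == 0.0

    def test_closed_form_example(self):
        art = Counter({"a": 1, "b": 1, "c": 2})
        doc = GeneDocument("g", Counter({"b": 1, "c": 1}))
        assert score_candidate(art, doc, "common_tokens") == 2
        cosine = 3 / (math.sqrt(6) * math.sqrt(2))
        assert score_candidate(art, doc, "cosine") == pytest.approx(cosine)
        assert score_candidate(art, doc, "product") == pytest.approx(2 * cosine)

    def test_empty_gene_document_scores_zero(self):
        assert score_candidate(Counter({"a": 1}), GeneDocument("g"), "product") == 0.0

    def test_cosine_invariant_to_duplicating_both_bags(self):
        art = Counter({"a": 1, "b": 2})
        doc = GeneDocument("g", Counter({"b": 1, "c": 1}))
        doubled_art = Counter({k: 2 * v for k, v in art.items()})
        doubled_doc = GeneDocument("g", Counter({k: 2 * v for k, v in doc.tokens.items()}))
        assert score_candidate(art, doc, "cosine") == pytest.approx(
            score_candidate(doubled_art, doubled_doc, "cosine")
        )

    def test_common_tokens_uses_type_semantics(self):
        art = Counter({"a": 5})
        doc = GeneDocument("g", Counter({"a": 9, "b": 1}))
        assert score_candidate(art, doc, "common_tokens") == 1

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            score_candidate(Counter(), GeneDocument("g"), "euclidean")


class TestSelection:
    def test_multiple_selection_half_of_max(self):
        cands = make_candidates([0.9, 0.7, 0.5, 0.4])
        threshold = apply_selection(cands, "multiple")
        assert threshold == pytest.approx(0.45)
        assert [c.selected for c in cands] == [True, True, True, False]

    def test_single_selection_argmax(self):
        cands = make_candidates([0.9, 0.7, 0.5, 0.4])
        apply_selection(cands, "single")
        assert [c.selected for c in cands] == [True, False, False, False]

    def test_single_tie_selects_all_tied(self):
        cands = make_candidates([0.8, 0.8, 0.1])
        apply_selection(cands, "single")
        assert [c.selected for c in cands] == [True, True, False]

    def test_multiple_superset_of_single_and_contains_argmax(self):
        scores = [0.31, 0.9, 0.46, 0.44, 0.89]
        single = make_candidates(scores)
        multiple = make_candidates(scores)
        apply_selection(single, "single")
        apply_selection(multiple, "multiple")
        chosen_single = {c.gene_id for c in single if c.selected}
        chosen_multiple = {c.gene_id for c in multiple if c.selected}
        assert chosen_single <= chosen_multiple
        assert "g1" in chosen_multiple  # argmax always selected

    def test_scale_invariance(self):
        scores = [0.9, 0.7, 0.5, 0.4]
        base = make_candidates(scores)
        scaled = make_candidates([s * 37.0 for s in scores])
        apply_selection(base, "multiple")
        apply_selection(scaled, "multiple")
        assert [c.selected for c in base] == [c.selected for c in scaled]

    def test_all_zero_scores_select_everything_in_multiple_mode(self):
        cands = make_candidates([0.0, 0.0])
        apply_selection(cands, "multiple")
        assert all(c.selected for c in cands)


class TestDisambiguate:
    def make_docs(self):
        return {
            "g1": GeneDocument("g1", Counter({"spindle": 2, "mitosis": 1})),
            "g2": GeneDocument("g2", Counter({"membrane": 1, "transport": 1})),
        }

    def test_single_candidate_selected_with_zero_score(self, tables):
        m = GeneMention("TNF", 0, 2, candidates=[GeneCandidate("g1", "TNF", score=9.0)])
        disambiguate([m], "anything", self.make_docs(), DisambiguationConfig(), tables)
        assert m.candidates[0].selected and m.candidates[0].score == 0.0

    def test_no_candidates_untouched(self, tables):
        m = GeneMention("Alu repeats", 0, 9)
        disambiguate([m], "text", self.make_docs(), DisambiguationConfig(), tables)
        assert m.candidates == []

    def test_article_similarity_decides(self, tables):
        m = GeneMention(
            "X1",
            0,
            1,
            candidates=[GeneCandidate("g1", "X1"), GeneCandidate("g2", "X1")],
        )
        disambiguate(
            [m], "spindle assembly during mitosis", self.make_docs(),
            DisambiguationConfig("product", "single"), tables,
        )
        assert [c.gene_id for c in m.selected_candidates()] == ["g1"]
        assert m.candidates[0].gene_id == "g1"  # sorted by descending score

    def test_missing_gene_document_scores_zero_with_warning(self, tables):
        m = GeneMention(
            "X1", 0, 1,
            candidates=[GeneCandidate("g1", "X1"), GeneCandidate("ghost", "X1")],
        )
        with pytest.warns(UserWarning, match="ghost"):
            disambiguate(
                [m], "spindle mitosis", self.make_docs(),
                DisambiguationConfig("cosine", "single"), tables,
            )
        ghost = [c for c in m.candidates if c.gene_id == "ghost"][0]
        assert ghost.score == 0.0

    def test_estimator_interface(self, tables):
        m = GeneMention(
            "X1", 0, 1,
            candidates=[GeneCandidate("g1", "X1"), GeneCandidate("g2", "X1")],
        )
        est = Disambiguator(method="cosine", mode="multiple", tables=tables)
        est.fit(self.make_docs().values())
        est.transform([m], article_text="membrane transport")
        assert [c.gene_id for c in m.selected_candidates()] == ["g2"]

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DisambiguationConfig(method="tfidf")
        with pytest.raises(ValueError):
            DisambiguationConfig(mode="triple")


class TestGeneDocumentStore:
    def test_write_load_round_trip(self, tables):
        rows = [("g1", "summary", "spindle assembly factor"), ("g1", "go", "mitosis"),
                ("g2", "summary", "membrane transport")]
        docs = load_gene_documents(write_gene_documents(rows), tables)
        assert set(docs) == {"g1", "g2"}
        assert docs["g1"].tokens["spindle"] == 1
        assert "mitosis" in docs["g1"].tokens

    def test_malformed_line(self, tables):
        with pytest.raises(ValueError, match="line 1"):
            load_gene_documents("g1\tonly-two-fields", tables)
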