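"""Two-step cascade: NER step, candidate pairs, relation classifiers."""

import numpy as np
import pytest

from attrseq.baseline import (
    CandidatePair,
    LstmRelationClassifier,
    MarginRelationClassifier,
    PairLstmConfig,
    TwoStepSystem,
    featurize_pair,
    generate_candidates,
    gold_mentions_by_sentence,
    ner_sequences,
    ner_train,
)
from attrseq.corpus import (
    AttributeMention,
    ConceptMention,
    Relation,
    build_document,
    tokenize,
)
from attrseq.evaluation import gold_pair_set, predicted_pair_set
from attrseq.synthetic import GenConfig, generate_corpus
from attrseq.tagger import TaggerConfig, task_label_set

from conftest import span_of


def small_ner_config(**kw):
    kw.setdefault("epochs", 1)
    return TaggerConfig(
        label_set=task_label_set("disorder"), use_roles=False, seed=0,
        word_dim=10, char_dim=5, word_hidden=8, char_hidden=4, **kw)


class TestNerStep:
    def test_sequences_label_every_attribute_once(self, shared_attr_doc):
        (seq,) = ner_sequences([shared_attr_doc])
        assert seq.labels.count("B-NEG") == 1  # linked to 2 concepts, 1 label
        assert all(r == "Outside" for r in seq.concept_tags)

    def test_requires_role_free_config(self, denied_doc):
        cfg = TaggerConfig(label_set=task_label_set("disorder"), use_roles=True)
        with pytest.raises(ValueError):
            ner_train([denied_doc], cfg)

    def test_empty_document_list_raises(self):
        with pytest.raises(ValueError):
            ner_train([], small_ner_config())


class TestCandidates:
    def test_product_count(self, kidney_doc):
        cands = generate_candidates(
            kidney_doc, gold_mentions_by_sentence([kidney_doc])["kidney"])
        assert len(cands) == 2 * 4
        assert sum(c.label for c in cands) == 4

    def test_no_attributes_no_candidates(self):
        text = "chest pain today ."
        doc = build_document(
            "x", text,
            concepts=[ConceptMention("C1", "Disorder", span_of(text, "chest pain"))])
        assert generate_candidates(doc, []) == []

    def test_candidates_respect_sentence_boundaries(self):
        text = "no chest pain\nsevere headache today"
        doc = build_document(
            "x", text,
            concepts=[ConceptMention("C1", "Disorder", span_of(text, "chest pain")),
                      ConceptMention("C2", "Disorder", span_of(text, "headache"))],
            attributes=[AttributeMention("A1", "NEG", span_of(text, "no")),
                        AttributeMention("A2", "SEV", span_of(text, "severe"))],
            relations=[Relation("C1", "A1"), Relation("C2", "A2")],
        )
        cands = generate_candidates(doc, gold_mentions_by_sentence([doc])["x"])
        assert len(cands) == 2  # one per sentence, never across
        assert all(c.concept.id != "C1" or c.attribute.id != "A2" for c in cands)


class TestPairFeatures:
    def _pair(self, text, concept_phrase, attr_phrase, attr_type="NEG"):
        tokens = tokenize(text)
        return CandidatePair(
            doc_id="x", sentence_index=0,
            concept=ConceptMention("C", "Disorder", span_of(text, concept_phrase)),
            attribute=AttributeMention("A", attr_type, span_of(text, attr_phrase)),
            tokens=tokens)

    def test_adjacent_mentions_empty_between_bag(self):
        f = featurize_pair(self._pair("no headache", "headache", "no"))
        assert f.between == []
        assert f.signed_distance == -1

    def test_attribute_left_of_concept_negative_distance(self):
        f = featurize_pair(self._pair("no acute chest pain", "chest pain", "no"))
        assert f.signed_distance == -2
        assert f.between == ["acute"]

    def test_attribute_right_positive_distance(self):
        f = featurize_pair(self._pair("blood pressure was 134/75",
                                      "blood pressure", "134/75", "VAL"))
        assert f.signed_distance == 2
        assert f.between == ["was"]

    def test_overlap_distance_zero(self):
        f = featurize_pair(self._pair("enlarged R kidney seen", "enlarged R kidney",
                                      "R kidney", "BDL"))
        assert f.signed_distance == 0 and f.overlap
        assert "overlap" in f.to_strings()


class TestMarginClassifier:
    def _separable_pairs(self, n=40):
        # relatedness is exactly "attribute adjacent to concept"
        rng = np.random.default_rng(0)
        pairs = []
        for i in range(n):
            gap = int(rng.integers(0, 4))
            text = "no " + "x " * gap + "rash seen ."
            p = CandidatePair(
                doc_id=f"d{i}", sentence_index=0,
                concept=ConceptMention("C", "Disorder", span_of(text, "rash")),
                attribute=AttributeMention("A", "NEG", span_of(text, "no")),
                tokens=tokenize(text), label=(gap == 0))
            pairs.append(p)
        return pairs

    def test_separable_data_perfect_training_accuracy(self):
        pairs = self._separable_pairs()
        clf = MarginRelationClassifier(("NEG",)).fit(pairs)
        acc = (clf.predict(pairs) == np.array([p.label for p in pairs])).mean()
        assert acc == 1.0

    def test_single_class_constant_predictor_with_warning(self):
        pairs = [p for p in self._separable_pairs() if p.label]
        with pytest.warns(UserWarning, match="single-class"):
            clf = MarginRelationClassifier(("NEG",)).fit(pairs)
        assert clf.predict(pairs).all()

    def test_contradictory_pairs_do_not_crash(self):
        pairs = self._separable_pairs()[:2]
        pairs[1].label = not pairs[0].label
        pairs[1].tokens = pairs[0].tokens
        pairs[1].concept, pairs[1].attribute = pairs[0].concept, pairs[0].attribute
        MarginRelationClassifier(("NEG",)).fit(pairs)  # non-separable but finite


class TestLstmPairClassifier:
    def _position_only_pairs(self, n=30):
        """Word identities carry no signal: relatedness is purely positional
        (attribute immediately precedes the concept)."""
        pairs = []
        for i in range(n):
            near = i % 2 == 0
            text = "w w no w rash w ." if not near else "w w w no rash w ."
            p = CandidatePair(
                doc_id=f"d{i}", sentence_index=0,
                concept=ConceptMention("C", "Disorder", span_of(text, "rash")),
                attribute=AttributeMention("A", "NEG", span_of(text, "no")),
                tokens=tokenize(text), label=near)
            pairs.append(p)
        return pairs

    def test_overfits_position_only_task(self):
        pairs = self._position_only_pairs()
        cfg = PairLstmConfig(word_dim=8, pos_dim=4, hidden=8, epochs=30,
                             learning_rate=0.1, seed=1)
        clf = LstmRelationClassifier(("NEG",), cfg).fit(pairs)
        acc = (clf.predict(pairs) == np.array([p.label for p in pairs])).mean()
        assert acc == 1.0

    def test_ablating_position_embeddings_drops_to_chance(self):
        pairs = self._position_only_pairs()
        cfg = PairLstmConfig(word_dim=8, pos_dim=4, hidden=8, epochs=30,
                             learning_rate=0.1, seed=1)
        clf = LstmRelationClassifier(("NEG",), cfg).fit(pairs)
        params = clf.params_by_type["NEG"]
        params["E_pc"].data[:] = 0.0
        params["E_pa"].data[:] = 0.0
        preds = clf.predict(pairs)
        # with positions zeroed every pair looks identical -> constant output
        assert len(set(preds.tolist())) == 1

    def test_fixed_seed_deterministic(self):
        pairs = self._position_only_pairs(10)
        cfg = PairLstmConfig(word_dim=6, pos_dim=3, hidden=6, epochs=2, seed=7)
        a = LstmRelationClassifier(("NEG",), cfg).fit(pairs).predict(pairs)
        b = LstmRelationClassifier(("NEG",), cfg).fit(pairs).predict(pairs)
        assert np.array_equal(a, b)


@pytest.fixture(scope="module")
def corpus():
    # shared attributes off so gold pairs and gold mentions are 1:1,
    # making the NER-recall bound exact
    docs, _ = generate_corpus(GenConfig(
        task="disorder", n_documents=6, distractor_prob=0.0,
        shared_attribute_prob=0.0, seed=17))
    return docs


class TestTwoStepComposition:

    def test_perfect_components_recover_gold(self, corpus):
        """Gold mentions + an oracle classifier compose to the gold relation
        set (the cascade is lossless when both steps are perfect)."""
        system = TwoStepSystem("disorder", "margin",
                               ner_config=small_ner_config())
        system.fit(corpus)

        class OracleClassifier:
            def predict(self, pairs):
                return np.array([bool(p.label) for p in pairs])

        gold_links = {d.doc_id: {(r.concept_id, r.attribute_id)
                                 for r in d.relations} for d in corpus}

        class GoldLookup:
            def predict(self, pairs):
                return np.array([
                    (p.concept.id, p.attribute.id) in gold_links[p.doc_id]
                    for p in pairs])

        system.relation_model = GoldLookup()
        preds = system.predict(
            corpus, mentions=gold_mentions_by_sentence(corpus))
        assert predicted_pair_set(corpus, preds) == gold_pair_set(corpus)

    def test_deleted_mentions_make_their_pairs_unrecoverable(self, corpus):
        system = TwoStepSystem("disorder", "margin",
                               ner_config=small_ner_config())
        system.fit(corpus)
        mentions = gold_mentions_by_sentence(corpus)
        # delete every NEG mention before relation classification
        kept = {d: [(s, m) for s, m in ms if m.attr_type != "NEG"]
                for d, ms in mentions.items()}
        preds = system.predict(corpus, mentions=kept)
        pred_pairs = predicted_pair_set(corpus, preds)
        assert not any(p.attr_type == "NEG" for p in pred_pairs)

    def test_recall_bounded_by_ner_recall(self, corpus):
        """Two-step recall on pairs can never exceed the NER step's recall
        on attribute mentions."""
        system = TwoStepSystem("disorder", "margin",
                               ner_config=small_ner_config(epochs=2))
        system.fit(corpus)
        from attrseq.baseline import ner_predict
        mentions = ner_predict(system.ner_model, corpus)
        gold_mentions = {(d.doc_id, a.span.start, a.span.end, a.attr_type)
                         for d in corpus for a in d.attributes}
        found = {(doc_id, m.span.start, m.span.end, m.attr_type)
                 for doc_id, ms in mentions.items() for _, m in ms}
        ner_recall = (len(gold_mentions & found) / len(gold_mentions)
                      if gold_mentions else 1.0)
        gold = gold_pair_set(corpus)
        pred = predicted_pair_set(corpus, system.predict(corpus, mentions=mentions))
        # every recovered pair needs its mention found, and a mention's
        # pairs can at most all be recovered
        pair_recall = len(gold & pred) / len(gold)
        assert pair_recall <= ner_recall + 1e-9

    def test_both_relation_modes_share_output_shape(self, corpus):
        for mode in ("margin", "lstm"):
            system = TwoStepSystem(
                "disorder", mode, ner_config=small_ner_config(),
                pair_config=PairLstmConfig(word_dim=6, pos_dim=3, hidden=6,
                                           epochs=1, seed=0))
            system.fit(corpus[:3])
            preds = system.predict(corpus[3:4])
            assert set(preds) == {corpus[3].doc_id}
            for cid, mention in preds[corpus[3].doc_id]:
                assert isinstance(mention, AttributeMention)
                assert any(c.id == cid for c in corpus[3].concepts)
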