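"""Concept-focused sequence transformation: encode, expand, decode."""

import pytest

from attrseq.cfs import (
    DecodeError,
    LabelingConflictError,
    decode_cfs,
    expand_corpus,
    expand_document,
    make_cfs,
)
from attrseq.corpus import (
    AttributeMention,
    ConceptMention,
    Relation,
    Span,
    build_document,
)
from attrseq.synthetic import GenConfig, generate_corpus

from conftest import span_of


def brute_force_decode(tokens, labels):
    """Independent run-length decoding oracle: scan left to right, opening a
    mention at every B (or at an I not continuing a same-type run) and
    extending it over subsequent same-type I labels."""
    spans = []
    open_run = None  # (type, first_idx, last_idx)
    for i, lab in enumerate(labels):
        if lab == "O":
            open_run = None
            continue
        prefix, atype = lab.split("-", 1)
        if prefix == "B" or open_run is None or open_run[0] != atype:
            if open_run is not None:
                pass
            open_run = (atype, i, i)
            spans.append(open_run)
        else:
            spans[-1] = (atype, spans[-1][1], i)
            open_run = spans[-1]
    return [(t, tokens[lo].span.start, tokens[hi].span.end) for t, lo, hi in spans]


class TestMakeCfs:
    def test_worked_example_targets_only_own_attributes(self, kidney_doc):
        target = kidney_doc.concept_by_id("C1")
        cfs = make_cfs(kidney_doc, 0, target)
        labeled = {tok.text for tok, lab in zip(cfs.tokens, cfs.labels) if lab != "O"}
        # only the target's attribute cues are labeled...
        assert labeled == {"markedly", "R", "kidney"}
        # ...while the other concept's cues are O
        for word in ("no", "small", "bowel", "Abdominal"):
            idx = [i for i, t in enumerate(cfs.tokens) if t.text == word]
            assert all(cfs.labels[i] == "O" for i in idx)

    def test_roles_partition_tokens(self, kidney_doc):
        cfs = make_cfs(kidney_doc, 0, kidney_doc.concept_by_id("C1"))
        by_role = {r: [t.text for t, cr in zip(cfs.tokens, cfs.concept_tags) if cr == r]
                   for r in ("Target", "NotTarget", "Outside")}
        assert by_role["Target"] == ["enlarged", "R", "kidney"]
        assert by_role["NotTarget"] == ["air", "fluid", "level"]
        assert "Abdominal" in by_role["Outside"]

    def test_nested_attribute_keeps_target_role_and_bio_label(self, kidney_doc):
        cfs = make_cfs(kidney_doc, 0, kidney_doc.concept_by_id("C1"))
        i = [t.text for t in cfs.tokens].index("R")
        assert cfs.concept_tags[i] == "Target" and cfs.labels[i] == "B-BDL"
        assert cfs.concept_tags[i + 1] == "Target" and cfs.labels[i + 1] == "I-BDL"

    def test_no_relations_yields_all_O(self, denied_doc):
        doc = build_document(
            "x", denied_doc.text, concepts=denied_doc.concepts,
            attributes=denied_doc.attributes, relations=[],
        )
        cfs = make_cfs(doc, 0, doc.concepts[0])
        assert set(cfs.labels) == {"O"}
        assert cfs.concept_tags[2] == cfs.concept_tags[3] == "Target"

    def test_two_token_attribute_is_one_B_one_I(self):
        text = "negative for infection today ."
        doc = build_document(
            "x", text,
            concepts=[ConceptMention("C1", "Disorder", span_of(text, "infection"))],
            attributes=[AttributeMention("A1", "NEG", span_of(text, "negative for"))],
            relations=[Relation("C1", "A1")],
        )
        cfs = make_cfs(doc, 0, doc.concepts[0])
        assert cfs.labels == ["B-NEG", "I-NEG", "O", "O", "O"]

    def test_target_not_in_sentence_raises(self, kidney_doc):
        stray = ConceptMention("C9", "Disorder", Span(0, 9, "Abdominal"))
        doc = build_document(
            "x", kidney_doc.text + "\nanother line",
            concepts=kidney_doc.concepts, attributes=kidney_doc.attributes,
            relations=kidney_doc.relations,
        )
        with pytest.raises(ValueError):
            make_cfs(doc, 1, doc.concepts[0])

    def test_conflicting_labels_raise(self):
        text = "severe chest pain"
        doc = build_document(
            "x", text,
            concepts=[ConceptMention("C1", "Disorder", span_of(text, "chest pain"))],
            attributes=[
                AttributeMention("A1", "SEV", span_of(text, "severe")),
                AttributeMention("A2", "COU", span_of(text, "severe")),
            ],
            relations=[Relation("C1", "A1"), Relation("C1", "A2")],
        )
        with pytest.raises(LabelingConflictError):
            make_cfs(doc, 0, doc.concepts[0])


class TestExpand:
    def test_one_sequence_per_concept(self, kidney_doc):
        seqs = expand_document(kidney_doc)
        assert len(seqs) == 2
        assert [s.target_concept_id for s in seqs] == ["C1", "C2"]

    def test_zero_concept_document(self):
        doc = build_document("x", "nothing here .")
        assert expand_document(doc) == []

    def test_count_equals_concepts_per_sentence_sum(self):
        docs, _ = generate_corpus(GenConfig(task="disorder", n_documents=6, seed=8))
        seqs = expand_corpus(docs)
        assert len(seqs) == sum(len(d.concepts) for d in docs)

    def test_concept_order_permutation_invariant(self, kidney_doc):
        reordered = build_document(
            "kidney", kidney_doc.text, list(reversed(kidney_doc.concepts)),
            kidney_doc.attributes, kidney_doc.relations,
        )
        a = [(s.target_concept_id, tuple(s.labels)) for s in expand_document(kidney_doc)]
        b = [(s.target_concept_id, tuple(s.labels)) for s in expand_document(reordered)]
        assert a == b


class TestDecode:
    def test_decode_matches_brute_force_on_generated_gold(self):
        docs, _ = generate_corpus(GenConfig(
            task="disorder", n_documents=8, shared_attribute_prob=0.3, seed=4))
        for cfs in expand_corpus(docs):
            got = {(m.attr_type, m.span.start, m.span.end)
                   for m, _ in decode_cfs(cfs, cfs.labels)}
            assert got == set(brute_force_decode(cfs.tokens, cfs.labels))

    def test_encode_decode_recovers_gold_attribute_sets(self):
        docs, _ = generate_corpus(GenConfig(
            task="medication", n_documents=8, shared_attribute_prob=0.2, seed=6))
        for doc in docs:
            for cfs in expand_document(doc):
                gold = {
                    (a.attr_type, a.span.start, a.span.end)
                    for a in doc.attributes_of(cfs.target_concept_id)
                }
                got = {(m.attr_type, m.span.start, m.span.end)
                       for m, _ in decode_cfs(cfs, cfs.labels)}
                assert got == gold

    def test_two_runs_two_mentions(self, kidney_doc):
        cfs = make_cfs(kidney_doc, 0, kidney_doc.concept_by_id("C1"))
        labels = ["O"] * len(cfs.tokens)
        labels[2] = "B-SEV"
        labels[4], labels[5] = "B-BDL", "I-BDL"
        out = decode_cfs(cfs, labels)
        assert [(m.attr_type) for m, _ in out] == ["SEV", "BDL"]
        assert all(r.concept_id == "C1" for _, r in out)

    def test_all_O_decodes_empty(self, denied_doc):
        cfs = make_cfs(denied_doc, 0, denied_doc.concepts[0])
        assert decode_cfs(cfs, ["O"] * len(cfs.tokens)) == []

    def test_dangling_I_repaired_as_B(self, denied_doc):
        cfs = make_cfs(denied_doc, 0, denied_doc.concepts[0])
        labels = ["I-NEG"] + ["O"] * (len(cfs.tokens) - 1)
        out = decode_cfs(cfs, labels)
        assert len(out) == 1
        assert out[0][0].attr_type == "NEG"
        assert out[0][0].span.text == "Denied"

    def test_type_switch_without_B_starts_new_mention(self, denied_doc):
        cfs = make_cfs(denied_doc, 0, denied_doc.concepts[0])
        labels = ["B-NEG", "I-SEV", "O", "O", "O"]
        out = decode_cfs(cfs, labels)
        assert [m.attr_type for m, _ in out] == ["NEG", "SEV"]

    def test_unknown_label_raises(self, denied_doc):
        cfs = make_cfs(denied_doc, 0, denied_doc.concepts[0])
        with pytest.raises(DecodeError):
            decode_cfs(cfs, ["X-NEG"] + ["O"] * (len(cfs.tokens) - 1))

    def test_length_mismatch_raises(self, denied_doc):
        cfs = make_cfs(denied_doc, 0, denied_doc.concepts[0])
        with pytest.raises(ValueError):
            decode_cfs(cfs, ["O"])
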