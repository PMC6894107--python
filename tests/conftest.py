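"""Shared fixtures: small hand-built documents with known annotations."""

from __future__ import annotations

import pytest

from attrseq.corpus import (
    AnnotatedDocument,
    AttributeMention,
    ConceptMention,
    Relation,
    Span,
    build_document,
)


def span_of(text: str, phrase: str, occurrence: int = 0) -> Span:
    """Span of the nth occurrence of ``phrase`` in ``text``."""
    pos = -1
    for _ in range(occurrence + 1):
        pos = text.index(phrase, pos + 1)
    return Span(pos, pos + len(phrase), phrase)


@pytest.fixture
def denied_doc() -> AnnotatedDocument:
    """'Denied any chest pain.' — one concept, one negation attribute."""
    text = "Denied any chest pain."
    return build_document(
        "denied", text,
        concepts=[ConceptMention("T1", "Disorder", span_of(text, "chest pain"))],
        attributes=[AttributeMention("T2", "NEG", span_of(text, "Denied"))],
        relations=[Relation("T1", "T2")],
    )


@pytest.fixture
def kidney_doc() -> AnnotatedDocument:
    """Two disorders in one sentence, two attributes each, with a nested
    body-location attribute inside the first concept span and an
    unannotated attribute-like word ('Abdominal')."""
    text = ("Abdominal CT showed markedly enlarged R kidney "
            "but no air fluid level in small bowel .")
    concepts = [
        ConceptMention("C1", "Disorder", span_of(text, "enlarged R kidney")),
        ConceptMention("C2", "Disorder", span_of(text, "air fluid level")),
    ]
    attributes = [
        AttributeMention("A1", "SEV", span_of(text, "markedly")),
        AttributeMention("A2", "BDL", span_of(text, "R kidney")),
        AttributeMention("A3", "NEG", span_of(text, "no")),
        AttributeMention("A4", "BDL", span_of(text, "small bowel")),
    ]
    relations = [
        Relation("C1", "A1"), Relation("C1", "A2"),
        Relation("C2", "A3"), Relation("C2", "A4"),
    ]
    return build_document("kidney", text, concepts, attributes, relations)


@pytest.fixture
def shared_attr_doc() -> AnnotatedDocument:
    """One negation cue linked to two concepts (counted twice in eval)."""
    text = "no chest pain or nausea today ."
    concepts = [
        ConceptMention("C1", "Disorder", span_of(text, "chest pain")),
        ConceptMention("C2", "Disorder", span_of(text, "nausea")),
    ]
    attributes = [AttributeMention("A1", "NEG", span_of(text, "no"))]
    relations = [Relation("C1", "A1"), Relation("C2", "A1")]
    return build_document("shared", text, concepts, attributes, relations)
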