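"""Concept-focused sequence (CFS) transformation.

Attribute detection for a *given* concept is recast as sequence labeling:
each (sentence, target concept) pair becomes one training sequence in which

* every token carries a concept-role tag — ``Target`` for tokens of the
  target concept, ``NotTarget`` for tokens of any other concept mention in
  the sentence, ``Outside`` elsewhere — and
* tokens of attributes *related to the target* carry BIO labels of their
  attribute type, while attributes of other concepts and unassociated
  attribute-like spans are plain ``O``.

A sentence with k target concepts yields k sequences, so entity recognition
and concept-attribute relation classification collapse into a single
tagging pass per target.  ``decode_cfs`` inverts the encoding: maximal
B..I runs in a predicted label sequence become attribute mentions, each
related to the target concept.

Roles and BIO labels are independent channels: an attribute nested inside
the target concept (a body-location cue inside a disorder span, say) keeps
role=Target *and* receives B/I labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .corpus import (
    AnnotatedDocument,
    AttributeMention,
    ConceptMention,
    Relation,
    Span,
    Token,
    align_span,
)

logger = logging.getLogger(__name__)

ROLE_TAGS = ("Target", "NotTarget", "Outside")


class LabelingConflictError(ValueError):
    """Two target-linked attributes of different types claim one token."""


class DecodeError(ValueError):
    """An unknown label string in model output."""


@dataclass
class ConceptFocusedSequence:
    """One sentence viewed from one target concept.

    ``tokens``, ``concept_tags`` and ``labels`` are parallel lists; labels
    use the BIO scheme over attribute types (``B-NEG``, ``I-NEG``, ... or
    ``O``).
    """

    doc_id: str
    sentence_index: int
    target_concept_id: str
    tokens: list[Token]
    concept_tags: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        n = len(self.tokens)
        if not (len(self.concept_tags) == len(self.labels) == n):
            raise ValueError("tokens, concept_tags and labels must align")
        for tag in self.concept_tags:
            if tag not in ROLE_TAGS:
                raise ValueError(f"unknown concept-role tag {tag!r}")

    @property
    def token_texts(self) -> list[str]:
        return [t.text for t in self.tokens]


def make_cfs(
    doc: AnnotatedDocument, sentence_index: int, target: ConceptMention
) -> ConceptFocusedSequence:
    """Build the CFS of ``target`` for the indexed sentence of ``doc``."""
    sspan, tokens = doc.sentences[sentence_index]
    if not (sspan.start <= target.span.start and target.span.end <= sspan.end):
        raise ValueError(
            f"target {target.id} is not inside sentence {sentence_index}"
        )

    roles = ["Outside"] * len(tokens)
    for concept in doc.concepts:
        if not concept.span.overlaps(sspan):
            continue
        lo, hi = align_span(concept.span, tokens)
        role = "Target" if concept.id == target.id else "NotTarget"
        for i in range(lo, hi):
            # Target wins where concept mentions overlap each other
            if roles[i] != "Target":
                roles[i] = role

    labels = ["O"] * len(tokens)
    for rel in doc.relations:
        if rel.concept_id != target.id:
            continue
        attr = doc.attribute_by_id(rel.attribute_id)
        if not attr.span.overlaps(sspan):
            # intra-sentential candidate space: cross-sentence links dropped
            logger.warning(
                "%s: relation %s->%s crosses sentence boundary; dropped",
                doc.doc_id, rel.concept_id, rel.attribute_id,
            )
            continue
        lo, hi = align_span(attr.span, tokens)
        for i in range(lo, hi):
            tag = ("B-" if i == lo else "I-") + attr.attr_type
            if labels[i] != "O" and labels[i].split("-", 1)[1] != attr.attr_type:
                raise LabelingConflictError(
                    f"{doc.doc_id}: token {i} ({tokens[i].text!r}) claimed by "
                    f"both {labels[i]} and {tag}"
                )
            labels[i] = tag

    return ConceptFocusedSequence(
        doc_id=doc.doc_id,
        sentence_index=sentence_index,
        target_concept_id=target.id,
        tokens=list(tokens),
        concept_tags=roles,
        labels=labels,
    )


def expand_document(doc: AnnotatedDocument) -> list[ConceptFocusedSequence]:
    """One CFS per concept mention, in document order then start offset."""
    out: list[ConceptFocusedSequence] = []
    for si, (sspan, _) in enumerate(doc.sentences):
        in_sentence = [
            c
            for c in doc.concepts
            if sspan.start <= c.span.start and c.span.end <= sspan.end
        ]
        for concept in sorted(in_sentence, key=lambda c: (c.span.start, c.span.end)):
            out.append(make_cfs(doc, si, concept))
    return out


def expand_corpus(docs: Iterable[AnnotatedDocument]) -> list[ConceptFocusedSequence]:
    return [cfs for doc in docs for cfs in expand_document(doc)]


def decode_cfs(
    cfs: ConceptFocusedSequence,
    predicted_labels: Sequence[str],
    id_prefix: str = "P",
) -> list[tuple[AttributeMention, Relation]]:
    """Turn predicted BIO labels back into concept-attached mentions.

    Maximal ``B-t (I-t)*`` runs become one attribute mention each, with the
    character span stretching from the first to the last token of the run,
    related to the target concept.  A dangling ``I-t`` (no preceding B or
    I of the same type) is repaired by treating it as ``B-t``.
    """
    if len(predicted_labels) != len(cfs.tokens):
        raise ValueError("label list length must equal token count")
    runs: list[tuple[str, int, int]] = []  # (type, lo, hi) token ranges
    cur_type: str | None = None
    cur_lo = 0
    for i, label in enumerate(predicted_labels):
        if label == "O":
            cur_type = None
            continue
        if "-" not in label or label.split("-", 1)[0] not in ("B", "I"):
            raise DecodeError(f"unknown label {label!r} at position {i}")
        prefix, atype = label.split("-", 1)
        if prefix == "B" or atype != cur_type:
            runs.append((atype, i, i + 1))
            cur_type, cur_lo = atype, i
        else:
            t, lo, _ = runs[-1]
            runs[-1] = (t, lo, i + 1)
    out: list[tuple[AttributeMention, Relation]] = []
    for k, (atype, lo, hi) in enumerate(runs, start=1):
        start = cfs.tokens[lo].span.start
        end = cfs.tokens[hi - 1].span.end
        # surface text reconstructed from token spans; gaps are whitespace
        text_parts: list[str] = []
        pos = start
        for tok in cfs.tokens[lo:hi]:
            text_parts.append(" " * (tok.span.start - pos))
            text_parts.append(tok.text)
            pos = tok.span.end
        mention = AttributeMention(
            id=f"{id_prefix}{cfs.doc_id}_{cfs.sentence_index}_"
            f"{cfs.target_concept_id}_{k}",
            attr_type=atype,
            span=Span(start, end, "".join(text_parts)),
        )
        out.append((mention, Relation(cfs.target_concept_id, mention.id)))
    return out


# ---------------------------------------------------------------------------
# CoNLL-style sequence file I/O
# ---------------------------------------------------------------------------

def write_sequences(
    sequences: Iterable[ConceptFocusedSequence], path: str | Path
) -> Path:
    """One token per line ``token<TAB>role<TAB>label``; blank line between
    sequences; a ``# target=...`` header comment before each sequence."""
    path = Path(path)
    lines: list[str] = []
    for cfs in sequences:
        lines.append(
            f"# doc={cfs.doc_id} sentence={cfs.sentence_index} "
            f"target={cfs.target_concept_id}"
        )
        for tok, role, label in zip(cfs.tokens, cfs.concept_tags, cfs.labels):
            lines.append(
                f"{tok.text}\t{role}\t{label}\t{tok.span.start}\t{tok.span.end}"
            )
        lines.append("")
    path.write_text("".join(line + "\n" for line in lines), encoding="utf-8")
    return path


def read_sequences(path: str | Path) -> list[ConceptFocusedSequence]:
    path = Path(path)
    out: list[ConceptFocusedSequence] = []
    header: dict[str, str] | None = None
    rows: list[tuple[str, str, str, int, int]] = []

    def flush() -> None:
        nonlocal header, rows
        if header is None or not rows:
            header, rows = None, []
            return
        tokens = [Token(t, Span(s, e, t)) for t, _, _, s, e in rows]
        out.append(
            ConceptFocusedSequence(
                doc_id=header["doc"],
                sentence_index=int(header["sentence"]),
                target_concept_id=header["target"],
                tokens=tokens,
                concept_tags=[r for _, r, _, _, _ in rows],
                labels=[l for _, _, l, _, _ in rows],
            )
        )
        header, rows = None, []

    for raw in path.read_text(encoding="utf-8").splitlines():
        if not raw.strip():
            flush()
            continue
        if raw.startswith("#"):
            header = dict(kv.split("=", 1) for kv in raw[1:].split())
            continue
        parts = raw.split("\t")
        rows.append((parts[0], parts[1], parts[2], int(parts[3]), int(parts[4])))
    flush()
    return out
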