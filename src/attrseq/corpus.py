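"""Data model for annotated clinical text and BRAT-style standoff I/O.

A corpus is a set of documents, each a plain-text file plus an annotation
file listing concept mentions (disorders, medications, lab tests), attribute
mentions (negation cues, dosages, lab values, ...) and concept->attribute
relations.  Offsets are 0-based half-open character offsets into the raw
text, the standard standoff convention, so reading back what was written is
the identity.

Sentences are newline-delimited by default (clinical notes are strongly
line-oriented); an opt-in rule-based splitter on ". " is available.
Discontiguous (disjoint) mentions are not representable and are rejected at
load, mirroring the usual pre-processing of the shared-task corpora.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

CONCEPT_TYPES = ("Disorder", "Medication", "LabTest")

#: Attribute type inventories per task.
TASK_ATTR_TYPES = {
    "disorder": ("NEG", "SUB", "CON", "SEV", "COU", "UNC", "BDL"),
    "medication": ("DOS", "MOD", "FRE", "DUR", "REA"),
    "labtest": ("VAL",),
}

ALL_ATTR_TYPES = tuple(t for types in TASK_ATTR_TYPES.values() for t in types)

#: Concept type used for each task's target concepts.
TASK_CONCEPT_TYPE = {
    "disorder": "Disorder",
    "medication": "Medication",
    "labtest": "LabTest",
}


class StandoffParseError(ValueError):
    """A malformed line in a .ann file (reports the line number)."""


class IntegrityError(ValueError):
    """Annotations inconsistent with the text or with each other."""


class AlignmentError(ValueError):
    """A span does not coincide with token boundaries in strict mode."""


@dataclass(frozen=True)
class Span:
    """Half-open character interval [start, end) with its surface text."""

    start: int
    end: int
    text: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")
        if len(self.text) != self.end - self.start:
            raise ValueError(
                f"span text length {len(self.text)} != {self.end - self.start}"
            )

    def overlaps(self, other: "Span") -> bool:
        return self.start < other.end and other.start < self.end

    def contains(self, other: "Span") -> bool:
        return self.start <= other.start and other.end <= self.end


@dataclass(frozen=True)
class Token:
    text: str
    span: Span


@dataclass(frozen=True)
class ConceptMention:
    id: str
    concept_type: str
    span: Span

    def __post_init__(self) -> None:
        if self.concept_type not in CONCEPT_TYPES:
            raise ValueError(f"unknown concept type {self.concept_type!r}")


@dataclass(frozen=True)
class AttributeMention:
    id: str
    attr_type: str
    span: Span

    def __post_init__(self) -> None:
        if self.attr_type not in ALL_ATTR_TYPES:
            raise ValueError(f"unknown attribute type {self.attr_type!r}")


@dataclass(frozen=True)
class Relation:
    concept_id: str
    attribute_id: str


@dataclass
class AnnotatedDocument:
    """One document: text, sentence/token structure, and annotations.

    ``sentences`` is a list of ``(Span, [Token, ...])`` pairs whose token
    spans use global (document-level) offsets.  Invariants are enforced by
    :meth:`validate`: every mention lies inside exactly one sentence, every
    mention/token surface string equals the document substring at its span,
    relation endpoints resolve, and relations are not duplicated.
    """

    doc_id: str
    text: str
    sentences: list[tuple[Span, list[Token]]] = field(default_factory=list)
    concepts: list[ConceptMention] = field(default_factory=list)
    attributes: list[AttributeMention] = field(default_factory=list)
    relations: list[Relation] = field(default_factory=list)

    # -- lookups -----------------------------------------------------------
    def concept_by_id(self, cid: str) -> ConceptMention:
        for c in self.concepts:
            if c.id == cid:
                return c
        raise KeyError(cid)

    def attribute_by_id(self, aid: str) -> AttributeMention:
        for a in self.attributes:
            if a.id == aid:
                return a
        raise KeyError(aid)

    def attributes_of(self, concept_id: str) -> list[AttributeMention]:
        return [
            self.attribute_by_id(r.attribute_id)
            for r in self.relations
            if r.concept_id == concept_id
        ]

    def sentence_index_of(self, span: Span) -> int:
        """Index of the unique sentence containing ``span``.

        Raises :class:`IntegrityError` if the span crosses sentence
        boundaries or lies outside every sentence.
        """
        for i, (ss, _) in enumerate(self.sentences):
            if ss.start <= span.start and span.end <= ss.end:
                return i
        raise IntegrityError(
            f"{self.doc_id}: span [{span.start},{span.end}) "
            "crosses a sentence boundary or lies outside all sentences"
        )

    # -- integrity ---------------------------------------------------------
    def validate(self) -> None:
        ids = [m.id for m in self.concepts] + [m.id for m in self.attributes]
        if len(set(ids)) != len(ids):
            raise IntegrityError(f"{self.doc_id}: duplicate mention ids")
        for sspan, tokens in self.sentences:
            _check_text(self.text, sspan, self.doc_id)
            prev_end = sspan.start
            for tok in tokens:
                _check_text(self.text, tok.span, self.doc_id)
                if tok.span.start < prev_end:
                    raise IntegrityError(
                        f"{self.doc_id}: overlapping or unordered tokens"
                    )
                if self.text[prev_end : tok.span.start].strip():
                    raise IntegrityError(
                        f"{self.doc_id}: tokens do not tile sentence text"
                    )
                prev_end = tok.span.end
            if self.text[prev_end : sspan.end].strip():
                raise IntegrityError(
                    f"{self.doc_id}: tokens do not tile sentence text"
                )
        for m in list(self.concepts) + list(self.attributes):
            _check_text(self.text, m.span, self.doc_id)
            self.sentence_index_of(m.span)
        cids = {c.id for c in self.concepts}
        aids = {a.id for a in self.attributes}
        seen: set[tuple[str, str]] = set()
        for r in self.relations:
            if r.concept_id not in cids:
                raise IntegrityError(
                    f"{self.doc_id}: relation references unknown concept "
                    f"{r.concept_id!r}"
                )
            if r.attribute_id not in aids:
                raise IntegrityError(
                    f"{self.doc_id}: relation references unknown attribute "
                    f"{r.attribute_id!r}"
                )
            key = (r.concept_id, r.attribute_id)
            if key in seen:
                raise IntegrityError(f"{self.doc_id}: duplicate relation {key}")
            seen.add(key)


def _check_text(text: str, span: Span, doc_id: str) -> None:
    actual = text[span.start : span.end]
    if actual != span.text:
        raise IntegrityError(
            f"{doc_id}: span [{span.start},{span.end}) text {span.text!r} "
            f"!= document substring {actual!r}"
        )


# ---------------------------------------------------------------------------
# Tokenization and sentence splitting
# ---------------------------------------------------------------------------

_PUNCT = set(".,;:!?()[]{}\"'`")
# dotted abbreviations like "p.m." or "q.a.m." keep their trailing period
_ABBREV_RE = re.compile(r"^(?:[A-Za-z]\.)+$")


def tokenize(sentence_text: str, sentence_offset: int = 0) -> list[Token]:
    """Whitespace tokenization with leading/trailing punctuation split off.

    Numeric/symbol compounds like ``134/75`` stay whole (only edge
    punctuation is split), and dotted abbreviations such as ``p.m.`` retain
    their final period.  Token offsets are global: ``sentence_offset`` is
    added to every span.
    """
    tokens: list[Token] = []
    for m in re.finditer(r"\S+", sentence_text):
        start, end = m.start(), m.end()
        # strip leading punctuation into 1-char tokens
        while start < end and sentence_text[start] in _PUNCT:
            tokens.append(_tok(sentence_text, start, start + 1, sentence_offset))
            start += 1
        # collect trailing punctuation (added after the core token)
        trail: list[int] = []
        while end > start and sentence_text[end - 1] in _PUNCT:
            core = sentence_text[start:end]
            if _ABBREV_RE.match(core):
                break
            trail.append(end - 1)
            end -= 1
        if start < end:
            tokens.append(_tok(sentence_text, start, end, sentence_offset))
        for pos in reversed(trail):
            tokens.append(_tok(sentence_text, pos, pos + 1, sentence_offset))
    return tokens


def _tok(text: str, start: int, end: int, offset: int) -> Token:
    surface = text[start:end]
    return Token(surface, Span(start + offset, end + offset, surface))


def split_sentences(
    text: str, mode: Literal["newline", "rule"] = "newline"
) -> list[Span]:
    """Sentence spans over ``text``.

    ``newline`` (default) treats each non-blank line as one sentence;
    ``rule`` additionally splits lines on ``". "`` after a lowercase word.
    """
    spans: list[Span] = []
    for m in re.finditer(r"[^\n]+", text):
        line = m.group()
        if not line.strip():
            continue
        if mode == "rule":
            parts = re.split(r"(?<=[a-z]\.)\s+(?=[A-Z0-9])", line)
            pos = m.start()
            for part in parts:
                idx = text.index(part, pos)
                if part.strip():
                    spans.append(Span(idx, idx + len(part), part))
                pos = idx + len(part)
        else:
            spans.append(Span(m.start(), m.end(), line))
    return spans


def align_span(
    span: Span, tokens: list[Token], mode: Literal["strict", "expand"] = "expand"
) -> tuple[int, int]:
    """Smallest contiguous token range ``[i, j)`` covering ``span``.

    In ``strict`` mode the span must coincide exactly with token
    boundaries; in ``expand`` mode the returned range may overtop the span.
    """
    lo = hi = None
    for i, tok in enumerate(tokens):
        if tok.span.overlaps(span):
            if lo is None:
                lo = i
            hi = i + 1
    if lo is None or hi is None:
        raise AlignmentError(
            f"span [{span.start},{span.end}) covers no token"
        )
    if mode == "strict":
        if tokens[lo].span.start != span.start or tokens[hi - 1].span.end != span.end:
            raise AlignmentError(
                f"span [{span.start},{span.end}) {span.text!r} does not "
                "coincide with token boundaries"
            )
    return lo, hi


# ---------------------------------------------------------------------------
# Standoff reading / writing
# ---------------------------------------------------------------------------

_T_LINE = re.compile(r"^(T\S+)\t(\S+) (\d+) (\d+)\t(.*)$")
_R_LINE = re.compile(r"^(R\S+)\t(\S+) Arg1:(T\S+) Arg2:(T\S+)\s*$")


def build_document(
    doc_id: str,
    text: str,
    concepts: Iterable[ConceptMention] = (),
    attributes: Iterable[AttributeMention] = (),
    relations: Iterable[Relation] = (),
    sentence_mode: Literal["newline", "rule"] = "newline",
) -> AnnotatedDocument:
    """Assemble and validate a document, tokenizing each sentence."""
    sentences = [
        (ss, tokenize(ss.text, ss.start)) for ss in split_sentences(text, sentence_mode)
    ]
    doc = AnnotatedDocument(
        doc_id=doc_id,
        text=text,
        sentences=sentences,
        concepts=list(concepts),
        attributes=list(attributes),
        relations=list(relations),
    )
    doc.validate()
    return doc


def read_standoff(
    text_path: str | Path,
    ann_path: str | Path,
    sentence_mode: Literal["newline", "rule"] = "newline",
) -> AnnotatedDocument:
    """Read a ``.txt`` + ``.ann`` standoff pair into an AnnotatedDocument.

    Mention surface strings are re-derived from offsets and checked against
    the annotation file; mismatches raise :class:`IntegrityError`.
    Mentions whose offsets contain a newline would be cross-sentence and are
    rejected.  Discontiguous mentions (``;``-separated offset fragments) are
    rejected with a warning, as is standard for these corpora.
    """
    text_path, ann_path = Path(text_path), Path(ann_path)
    text = text_path.read_text(encoding="utf-8")
    concepts: list[ConceptMention] = []
    attributes: list[AttributeMention] = []
    relations: list[Relation] = []
    for lineno, raw in enumerate(
        ann_path.read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not raw.strip():
            continue
        if raw.startswith("T"):
            if ";" in raw.split("\t")[1]:
                warnings.warn(
                    f"{ann_path.name}:{lineno}: discontiguous mention rejected"
                )
                raise IntegrityError(
                    f"{ann_path.name}:{lineno}: discontiguous mentions are "
                    "not supported"
                )
            m = _T_LINE.match(raw)
            if not m:
                raise StandoffParseError(
                    f"{ann_path.name}:{lineno}: malformed T line: {raw!r}"
                )
            tid, mtype, start, end, quoted = m.groups()
            start, end = int(start), int(end)
            if not (0 <= start < end <= len(text)):
                raise IntegrityError(
                    f"{ann_path.name}:{lineno}: offsets [{start},{end}) out of "
                    f"range for document of length {len(text)}"
                )
            surface = text[start:end]
            if surface != quoted:
                raise IntegrityError(
                    f"{ann_path.name}:{lineno}: quoted text {quoted!r} != "
                    f"document substring {surface!r}"
                )
            span = Span(start, end, surface)
            if mtype in CONCEPT_TYPES:
                concepts.append(ConceptMention(tid, mtype, span))
            elif mtype in ALL_ATTR_TYPES:
                attributes.append(AttributeMention(tid, mtype, span))
            else:
                raise StandoffParseError(
                    f"{ann_path.name}:{lineno}: unknown mention type {mtype!r}"
                )
        elif raw.startswith("R"):
            m = _R_LINE.match(raw)
            if not m:
                raise StandoffParseError(
                    f"{ann_path.name}:{lineno}: malformed R line: {raw!r}"
                )
            _, _, arg1, arg2 = m.groups()
            relations.append(Relation(concept_id=arg1, attribute_id=arg2))
        else:
            raise StandoffParseError(
                f"{ann_path.name}:{lineno}: unrecognized line: {raw!r}"
            )
    return build_document(
        text_path.stem, text, concepts, attributes, relations, sentence_mode
    )


def write_standoff(doc: AnnotatedDocument, out_dir: str | Path) -> tuple[Path, Path]:
    """Write ``<doc_id>.txt`` and ``<doc_id>.ann``; round-trips exactly."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    txt = out_dir / f"{doc.doc_id}.txt"
    ann = out_dir / f"{doc.doc_id}.ann"
    txt.write_text(doc.text, encoding="utf-8")
    lines: list[str] = []
    for m in doc.concepts:
        lines.append(f"{m.id}\t{m.concept_type} {m.span.start} {m.span.end}\t{m.span.text}")
    for m in doc.attributes:
        lines.append(f"{m.id}\t{m.attr_type} {m.span.start} {m.span.end}\t{m.span.text}")
    for i, r in enumerate(doc.relations, start=1):
        rel_type = doc.attribute_by_id(r.attribute_id).attr_type
        lines.append(f"R{i}\t{rel_type} Arg1:{r.concept_id} Arg2:{r.attribute_id}")
    ann.write_text("".join(line + "\n" for line in lines), encoding="utf-8")
    return txt, ann


def read_corpus(
    corpus_dir: str | Path,
    sentence_mode: Literal["newline", "rule"] = "newline",
) -> list[AnnotatedDocument]:
    """Read every ``.txt``/``.ann`` pair in a directory, sorted by name."""
    corpus_dir = Path(corpus_dir)
    docs = []
    for txt in sorted(corpus_dir.glob("*.txt")):
        ann = txt.with_suffix(".ann")
        if not ann.exists():
            raise FileNotFoundError(f"missing annotation file {ann}")
        docs.append(read_standoff(txt, ann, sentence_mode))
    return docs


def write_corpus(docs: Iterable[AnnotatedDocument], out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    for doc in docs:
        write_standoff(doc, out_dir)
    return out_dir
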