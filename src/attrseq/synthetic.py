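"""Seeded generator of clinical-style annotated corpora.

Real corpora for concept-attribute detection (disorder modifiers,
medication signatures, lab-test values) are restricted by data-use
agreements, so the package ships a generator that emulates their
*structure*: line-oriented documents whose sentences carry 0-3 target
concepts; per-concept attribute sets drawn from the task's type inventory
with configurable attachment rates; attributes occasionally shared between
two concepts; unassociated attribute-like *distractor* spans that are left
unannotated (the "omitted annotation" phenomenon that breaks concept-blind
attribute NER); and, on demand, *crossing* sentences in which each
attribute belongs to the farther of two concepts, defeating proximity
heuristics.

Sentence realization is template-based (concept slots + cue slots +
fillers) rather than grammar-sampled: statistically sufficient for the
sequence-labeling task and fully auditable — every planted item is
recorded in a generation ledger that downstream tests check against the
emitted standoff annotations.  Generation is deterministic under the seed.

Lab-test values come in the two flavors seen in practice: numeric
("134/75", "7.2") and categorical ("NEG", "trace").
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np

from .corpus import (
    AnnotatedDocument,
    AttributeMention,
    ConceptMention,
    Relation,
    Span,
    TASK_ATTR_TYPES,
    TASK_CONCEPT_TYPE,
    build_document,
)

# ---------------------------------------------------------------------------
# Default vocabulary tables per task (surface forms are token sequences that
# the package tokenizer reproduces exactly; cue and filler vocabularies are
# kept disjoint so alignment is unambiguous)
# ---------------------------------------------------------------------------

CONCEPT_VOCAB = {
    "disorder": [
        "chest pain", "shortness of breath", "enlarged R kidney",
        "air fluid level", "pleural effusion", "nausea", "headache",
        "atrial fibrillation", "bowel obstruction", "rash",
    ],
    "medication": [
        "insulin Lente", "aspirin", "metformin", "lisinopril",
        "warfarin", "albuterol", "prednisone", "amoxicillin",
    ],
    "labtest": [
        "blood pressure", "URINE BLOOD", "glucose", "hematocrit",
        "white count", "creatinine", "troponin", "potassium",
    ],
}

CUE_VOCAB = {
    "NEG": ["no", "denied", "without", "negative for", "ruled out"],
    "SUB": ["mother", "father", "family history of"],
    "CON": ["if needed", "with exertion", "when standing"],
    "SEV": ["mild", "severe", "markedly", "moderate", "slightly"],
    "COU": ["worsening", "improving", "resolved", "chronic", "stable"],
    "UNC": ["possible", "probable", "suspected", "likely"],
    "BDL": ["chest", "abdomen", "left arm", "right leg", "head", "back"],
    "DOS": ["12 units", "500 mg", "two tablets", "10 mg", "40 mg"],
    "MOD": ["subcu", "po", "iv", "orally", "topically"],
    "FRE": ["q p.m.", "daily", "b.i.d.", "twice daily", "q8h"],
    "DUR": ["for 10 days", "x3 days", "for two weeks"],
    "REA": ["for pain", "for hypertension", "for infection"],
    "VAL": ["NEG", "POS", "trace", "normal"],  # plus generated numerics
}

FILLERS = ["the", "patient", "has", "and", "noted", "on", "exam",
           "today", "showed", "also", "follow", "up"]

#: Cue position tendency: probability the cue precedes its concept.
_PRE_PROB = {
    "NEG": 0.95, "SUB": 0.9, "CON": 0.1, "SEV": 0.9, "COU": 0.7,
    "UNC": 0.9, "BDL": 0.35, "DOS": 0.05, "MOD": 0.05, "FRE": 0.05,
    "DUR": 0.05, "REA": 0.05, "VAL": 0.02,
}

#: Default per-type attachment probabilities (roughly matching the relative
#: frequencies seen in the shared-task corpora: body locations and negation
#: dominate for disorders; dosage/mode/frequency dominate for medications).
DEFAULT_ATTACH = {
    "disorder": {"NEG": 0.30, "SUB": 0.05, "CON": 0.08, "SEV": 0.25,
                 "COU": 0.10, "UNC": 0.10, "BDL": 0.40},
    "medication": {"DOS": 0.50, "MOD": 0.40, "FRE": 0.45, "DUR": 0.10,
                   "REA": 0.10},
    "labtest": {"VAL": 0.80},
}


@dataclass
class GenConfig:
    """Knobs of the generator; defaults are the package's study conditions."""

    task: str = "disorder"
    n_documents: int = 20
    sentences_per_document: tuple[int, int] = (3, 6)
    concepts_per_sentence: dict[int, float] = field(
        default_factory=lambda: {0: 0.10, 1: 0.50, 2: 0.30, 3: 0.10}
    )
    attach_prob: dict[str, float] | None = None  # None -> DEFAULT_ATTACH[task]
    shared_attribute_prob: float = 0.1
    distractor_prob: float = 0.2
    crossing_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in TASK_ATTR_TYPES:
            raise ValueError(f"unknown task {self.task!r}")
        if self.attach_prob is None:
            self.attach_prob = dict(DEFAULT_ATTACH[self.task])
        probs = (list(self.attach_prob.values())
                 + list(self.concepts_per_sentence.values())
                 + [self.shared_attribute_prob, self.distractor_prob,
                    self.crossing_prob])
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.concepts_per_sentence.values()) - 1.0) > 1e-9:
            raise ValueError("concepts_per_sentence must sum to 1")
        for t in self.attach_prob:
            if t not in TASK_ATTR_TYPES[self.task]:
                raise ValueError(f"attribute type {t} not in task {self.task}")
        if not CONCEPT_VOCAB[self.task]:
            raise ValueError("empty concept vocabulary")


@dataclass
class LedgerEntry:
    kind: str                 # concept | attribute | distractor
    doc_id: str
    start: int
    end: int
    text: str
    type: str
    linked_to: tuple[str, ...] = ()   # concept ids (attributes only)
    mention_id: str = ""


# -- sentence assembly -------------------------------------------------------

class _SentenceDraft:
    """Token accumulator that later resolves to global character spans."""

    def __init__(self) -> None:
        self.tokens: list[str] = []
        self.mentions: list[tuple[int, int, str, str, tuple[str, ...]]] = []
        # (tok_lo, tok_hi, kind, type, linked) over self.tokens

    def add(self, words: Sequence[str]) -> tuple[int, int]:
        lo = len(self.tokens)
        self.tokens.extend(words)
        return lo, len(self.tokens)


def _cue_tokens(attr_type: str, rng: np.random.Generator) -> list[str]:
    if attr_type == "VAL" and rng.random() < 0.6:
        if rng.random() < 0.4:
            return [f"{rng.integers(90, 180)}/{rng.integers(50, 110)}"]
        return [f"{rng.integers(1, 300)}" if rng.random() < 0.5
                else f"{float(rng.integers(10, 99)) / 10:.1f}"]
    cues = CUE_VOCAB[attr_type]
    return cues[rng.integers(len(cues))].split()


def _fillers(rng: np.random.Generator, lo: int = 1, hi: int = 3) -> list[str]:
    n = int(rng.integers(lo, hi + 1))
    return [FILLERS[rng.integers(len(FILLERS))] for _ in range(n)]


def generate_corpus(
    config: GenConfig,
) -> tuple[list[AnnotatedDocument], list[LedgerEntry]]:
    """Generate documents plus the ledger of every planted item."""
    rng = np.random.default_rng(config.seed)
    attr_types = list(config.attach_prob)
    primary_type = attr_types[0]
    cps_levels = sorted(config.concepts_per_sentence)
    cps_probs = [config.concepts_per_sentence[k] for k in cps_levels]
    docs: list[AnnotatedDocument] = []
    ledger: list[LedgerEntry] = []

    for d in range(config.n_documents):
        doc_id = f"doc{d:04d}"
        lo, hi = config.sentences_per_document
        n_sent = int(rng.integers(lo, hi + 1))
        sentence_texts: list[str] = []
        drafts: list[_SentenceDraft] = []
        for s in range(n_sent):
            n_c = int(rng.choice(cps_levels, p=cps_probs))
            draft = _SentenceDraft()
            if n_c >= 2 and rng.random() < config.crossing_prob:
                _realize_crossing(draft, config, primary_type, rng)
            else:
                _realize_regular(draft, config, n_c, attr_types, rng)
            drafts.append(draft)
            sentence_texts.append(" ".join(draft.tokens))

        # resolve to global offsets
        text = "\n".join(sentence_texts)
        concepts: list[ConceptMention] = []
        attributes: list[AttributeMention] = []
        relations: list[Relation] = []
        offset = 0
        tid = 0
        for s, draft in enumerate(drafts):
            # char offset of each token in this sentence
            starts: list[int] = []
            pos = offset
            for tok in draft.tokens:
                starts.append(pos)
                pos += len(tok) + 1
            def _span(lo_t: int, hi_t: int) -> Span:
                start = starts[lo_t]
                end = starts[hi_t - 1] + len(draft.tokens[hi_t - 1])
                return Span(start, end, text[start:end])

            # concepts first (attribute cues may precede their concept in
            # token order but must reference an already-assigned id)
            sent_concept_ids: dict[int, str] = {}
            for lo_t, hi_t, kind, mtype, linked in draft.mentions:
                if kind != "concept":
                    continue
                span = _span(lo_t, hi_t)
                tid += 1
                mid = f"T{tid}"
                sent_concept_ids[len(sent_concept_ids)] = mid
                concepts.append(
                    ConceptMention(mid, TASK_CONCEPT_TYPE[config.task], span)
                )
                ledger.append(LedgerEntry(
                    "concept", doc_id, span.start, span.end, span.text,
                    TASK_CONCEPT_TYPE[config.task], mention_id=mid))
            for lo_t, hi_t, kind, mtype, linked in draft.mentions:
                if kind == "concept":
                    continue
                span = _span(lo_t, hi_t)
                if kind == "attribute":
                    tid += 1
                    mid = f"T{tid}"
                    attributes.append(AttributeMention(mid, mtype, span))
                    linked_ids = tuple(sent_concept_ids[i] for i in linked)
                    for cid in linked_ids:
                        relations.append(Relation(cid, mid))
                    ledger.append(LedgerEntry(
                        "attribute", doc_id, span.start, span.end, span.text,
                        mtype, linked_to=linked_ids, mention_id=mid))
                else:  # distractor: present in text, deliberately unannotated
                    ledger.append(LedgerEntry(
                        "distractor", doc_id, span.start, span.end, span.text,
                        mtype))
            offset += len(sentence_texts[s]) + 1

        doc = build_document(doc_id, text, concepts, attributes, relations)
        docs.append(doc)
    return docs, ledger


def _realize_regular(
    draft: _SentenceDraft,
    config: GenConfig,
    n_concepts: int,
    attr_types: list[str],
    rng: np.random.Generator,
) -> None:
    draft.add(_fillers(rng, 1, 3))
    concept_slots: list[tuple[int, int]] = []
    attached: list[tuple[int, int, int, str]] = []  # (lo, hi, concept_idx, type)
    for ci in range(n_concepts):
        pre: list[tuple[str, list[str]]] = []
        post: list[tuple[str, list[str]]] = []
        for t in attr_types:
            if rng.random() < config.attach_prob[t]:
                side = pre if rng.random() < _PRE_PROB[t] else post
                side.append((t, _cue_tokens(t, rng)))
        for t, words in pre:
            lo, hi = draft.add(words)
            attached.append((lo, hi, ci, t))
        lo, hi = draft.add(
            CONCEPT_VOCAB[config.task][rng.integers(len(CONCEPT_VOCAB[config.task]))].split()
        )
        concept_slots.append((lo, hi))
        for t, words in post:
            lo, hi = draft.add(words)
            attached.append((lo, hi, ci, t))
        if ci < n_concepts - 1:
            draft.add(["and"] if rng.random() < 0.5 else _fillers(rng, 1, 2))
    if rng.random() < config.distractor_prob:
        t = attr_types[rng.integers(len(attr_types))]
        lo, hi = draft.add(_cue_tokens(t, rng))
        draft.mentions.append((lo, hi, "distractor", t, ()))
    draft.add(_fillers(rng, 1, 2) + ["."])

    for lo, hi in concept_slots:
        draft.mentions.append((lo, hi, "concept", "", ()))
    for lo, hi, ci, t in attached:
        linked = [ci]
        if (n_concepts >= 2
                and rng.random() < config.shared_attribute_prob):
            other = (ci + 1) % n_concepts
            linked.append(other)
        draft.mentions.append((lo, hi, "attribute", t, tuple(sorted(linked))))
    # mentions must appear in a stable order for id assignment: by token pos,
    # concepts before attributes at equal position
    draft.mentions.sort(key=lambda m: (m[0], m[2] != "concept"))


def _realize_crossing(
    draft: _SentenceDraft,
    config: GenConfig,
    attr_type: str,
    rng: np.random.Generator,
) -> None:
    """A1 C1 ... A2 C2 with A1->C2 and A2->C1 (each cue is adjacent to the
    concept it does NOT modify) — the hard case for proximity heuristics."""
    draft.add(_fillers(rng, 1, 2))
    a1_lo, a1_hi = draft.add(_cue_tokens(attr_type, rng))
    vocab = CONCEPT_VOCAB[config.task]
    c1_lo, c1_hi = draft.add(vocab[rng.integers(len(vocab))].split())
    draft.add(["and"])
    a2_lo, a2_hi = draft.add(_cue_tokens(attr_type, rng))
    c2_lo, c2_hi = draft.add(vocab[rng.integers(len(vocab))].split())
    draft.add(["."])
    draft.mentions.extend([
        (c1_lo, c1_hi, "concept", "", ()),
        (c2_lo, c2_hi, "concept", "", ()),
        (a1_lo, a1_hi, "attribute", attr_type, (1,)),
        (a2_lo, a2_hi, "attribute", attr_type, (0,)),
    ])
    draft.mentions.sort(key=lambda m: (m[0], m[2] != "concept"))


def corpus_stats(docs: Iterable[AnnotatedDocument]) -> dict[str, int]:
    """Counts table: target concepts, attribute mentions and relations per
    type (the shape of the usual corpus-statistics tables)."""
    stats: dict[str, int] = {"n_documents": 0, "n_sentences": 0,
                             "n_concepts": 0, "n_relations": 0}
    for doc in docs:
        stats["n_documents"] += 1
        stats["n_sentences"] += len(doc.sentences)
        stats["n_concepts"] += len(doc.concepts)
        stats["n_relations"] += len(doc.relations)
        for a in doc.attributes:
            stats[f"attr_{a.attr_type}"] = stats.get(f"attr_{a.attr_type}", 0) + 1
        for r in doc.relations:
            t = doc.attribute_by_id(r.attribute_id).attr_type
            stats[f"pair_{t}"] = stats.get(f"pair_{t}", 0) + 1
    return stats


def ledger_counts(ledger: Iterable[LedgerEntry]) -> dict[str, int]:
    out: dict[str, int] = {"n_concepts": 0, "n_relations": 0}
    for e in ledger:
        if e.kind == "concept":
            out["n_concepts"] += 1
        elif e.kind == "attribute":
            out[f"attr_{e.type}"] = out.get(f"attr_{e.type}", 0) + 1
            out["n_relations"] += len(e.linked_to)
    return out


def ledger_to_json(ledger: Iterable[LedgerEntry]) -> list[dict]:
    return [asdict(e) for e in ledger]
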