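"""Concept-aligned evaluation: strict P/R/F per attribute type and
concept-level accuracy, with 10-fold cross-validation and micro-averaging.

Gold and system output are aligned on the given concepts (offsets and
type).  A predicted (concept, attribute) pair is a true positive iff the
concept identity, the attribute character span (exact start/end) and the
attribute type all match a gold pair; an attribute mention associated with
multiple concepts is counted once per concept.  Concept-level accuracy for
an attribute type is the fraction of gold concepts whose *entire* predicted
attribute set of that type equals the gold set — a concept with no gold
attribute counts as correct only when nothing is predicted for it ("null"
must be matched too).

A relaxed mode (span overlap instead of exact offsets) is available but
off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .corpus import AnnotatedDocument, AttributeMention

#: System output: per doc_id, a list of (concept_id, predicted attribute).
Predictions = Mapping[str, Sequence[tuple[str, AttributeMention]]]


@dataclass(frozen=True)
class Pair:
    """One concept-attribute link, keyed by offsets for strict matching."""

    doc_id: str
    concept_start: int
    concept_end: int
    attr_type: str
    attr_start: int
    attr_end: int


def gold_pair_set(docs: Iterable[AnnotatedDocument]) -> set[Pair]:
    out: set[Pair] = set()
    for doc in docs:
        for rel in doc.relations:
            c = doc.concept_by_id(rel.concept_id)
            a = doc.attribute_by_id(rel.attribute_id)
            out.add(Pair(doc.doc_id, c.span.start, c.span.end,
                         a.attr_type, a.span.start, a.span.end))
    return out


def predicted_pair_set(
    docs: Iterable[AnnotatedDocument], predictions: Predictions
) -> set[Pair]:
    out: set[Pair] = set()
    for doc in docs:
        for concept_id, attr in predictions.get(doc.doc_id, ()):
            c = doc.concept_by_id(concept_id)
            out.add(Pair(doc.doc_id, c.span.start, c.span.end,
                         attr.attr_type, attr.span.start, attr.span.end))
    return out


@dataclass
class TypeCounts:
    """Raw counts for one attribute type (poolable across folds)."""

    tp: int = 0
    n_pred: int = 0
    n_gold: int = 0
    n_concepts: int = 0
    n_correct_concepts: int = 0

    def add(self, other: "TypeCounts") -> None:
        self.tp += other.tp
        self.n_pred += other.n_pred
        self.n_gold += other.n_gold
        self.n_concepts += other.n_concepts
        self.n_correct_concepts += other.n_correct_concepts

    @property
    def precision(self) -> float:
        return self.tp / self.n_pred if self.n_pred else 0.0

    @property
    def recall(self) -> float:
        return self.tp / self.n_gold if self.n_gold else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    @property
    def accuracy(self) -> float:
        return self.n_correct_concepts / self.n_concepts if self.n_concepts else 0.0


@dataclass
class EvalReport:
    """Per-attribute-type metrics plus fold bookkeeping."""

    per_type: dict[str, TypeCounts] = field(default_factory=dict)
    n_folds: int = 1

    def counts(self, attr_type: str) -> TypeCounts:
        return self.per_type.setdefault(attr_type, TypeCounts())

    def add(self, other: "EvalReport") -> None:
        for t, c in other.per_type.items():
            self.counts(t).add(c)

    def as_rows(self) -> list[dict[str, float | str | int]]:
        rows = []
        for t in sorted(self.per_type):
            c = self.per_type[t]
            rows.append({
                "attr_type": t, "tp": c.tp, "n_pred": c.n_pred,
                "n_gold": c.n_gold, "P": c.precision, "R": c.recall,
                "F": c.f1, "Acc": c.accuracy, "N": c.n_concepts,
            })
        return rows

    def to_tsv(self) -> str:
        rows = self.as_rows()
        header = ["attr_type", "tp", "n_pred", "n_gold", "P", "R", "F", "Acc", "N"]
        lines = ["\t".join(header)]
        for row in rows:
            lines.append("\t".join(
                f"{row[h]:.4f}" if isinstance(row[h], float) else str(row[h])
                for h in header
            ))
        return "\n".join(lines) + "\n"


def strict_prf(
    gold: set[Pair], pred: set[Pair], attr_type: str, relaxed: bool = False
) -> tuple[float, float, float]:
    """Precision, recall and F-measure for one attribute type."""
    c = _type_counts(gold, pred, attr_type, relaxed)
    return c.precision, c.recall, c.f1


def _match_relaxed(g: Pair, p: Pair) -> bool:
    return (g.doc_id == p.doc_id
            and (g.concept_start, g.concept_end) == (p.concept_start, p.concept_end)
            and g.attr_type == p.attr_type
            and g.attr_start < p.attr_end and p.attr_start < g.attr_end)


def _type_counts(
    gold: set[Pair], pred: set[Pair], attr_type: str, relaxed: bool = False
) -> TypeCounts:
    g = {x for x in gold if x.attr_type == attr_type}
    p = {x for x in pred if x.attr_type == attr_type}
    if relaxed:
        tp = sum(1 for pp in p if any(_match_relaxed(gg, pp) for gg in g))
    else:
        tp = len(g & p)
    return TypeCounts(tp=tp, n_pred=len(p), n_gold=len(g))


def concept_accuracy(
    docs: Iterable[AnnotatedDocument],
    gold: set[Pair],
    pred: set[Pair],
    attr_type: str,
) -> tuple[float, int, int]:
    """(Acc, N_correct_predict, N) over all gold concepts.

    A concept is correct iff its predicted attribute-span set for
    ``attr_type`` equals the gold set exactly, including both being empty.
    """
    n = n_correct = 0
    for doc in docs:
        by_concept_gold: dict[tuple[int, int], set] = {}
        by_concept_pred: dict[tuple[int, int], set] = {}
        for x, store in ((gold, by_concept_gold), (pred, by_concept_pred)):
            for pair in x:
                if pair.doc_id == doc.doc_id and pair.attr_type == attr_type:
                    store.setdefault(
                        (pair.concept_start, pair.concept_end), set()
                    ).add((pair.attr_start, pair.attr_end))
        for c in doc.concepts:
            key = (c.span.start, c.span.end)
            n += 1
            if by_concept_gold.get(key, set()) == by_concept_pred.get(key, set()):
                n_correct += 1
    return (n_correct / n if n else 0.0), n_correct, n


def evaluate(
    docs: Sequence[AnnotatedDocument],
    predictions: Predictions,
    attr_types: Sequence[str],
    relaxed: bool = False,
) -> EvalReport:
    """Full report over a document set for the given attribute types."""
    gold = gold_pair_set(docs)
    pred = predicted_pair_set(docs, predictions)
    report = EvalReport()
    for t in attr_types:
        c = _type_counts(gold, pred, t, relaxed)
        _, n_corr, n = concept_accuracy(docs, gold, pred, t)
        c.n_concepts, c.n_correct_concepts = n, n_corr
        report.per_type[t] = c
    return report


def make_folds(
    n_docs: int, k: int, seed: int
) -> list[np.ndarray]:
    """Partition document indices into k folds under a seed."""
    if n_docs < k:
        raise ValueError(f"need at least {k} documents for {k}-fold CV")
    idx = np.arange(n_docs)
    np.random.default_rng(seed).shuffle(idx)
    return [idx[i::k] for i in range(k)]


def cross_validate(
    docs: Sequence[AnnotatedDocument],
    system: Callable[[Sequence[AnnotatedDocument], Sequence[AnnotatedDocument]], Predictions],
    attr_types: Sequence[str],
    k: int = 10,
    seed: int = 0,
) -> tuple[EvalReport, list[EvalReport]]:
    """k-fold CV at document granularity; returns (micro, per-fold reports).

    ``system(train_docs, test_docs)`` returns predictions for the test
    documents.  Micro-averaging pools raw TP / predicted / gold counts (and
    the concept-accuracy numerators/denominators) across folds before
    computing ratios.
    """
    folds = make_folds(len(docs), k, seed)
    fold_reports: list[EvalReport] = []
    micro = EvalReport(n_folds=k)
    for fold_idx in folds:
        test = [docs[i] for i in fold_idx]
        train = [docs[i] for i in range(len(docs)) if i not in set(fold_idx)]
        preds = system(train, test)
        rep = evaluate(test, preds, attr_types)
        fold_reports.append(rep)
        micro.add(rep)
    return micro, fold_reports
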