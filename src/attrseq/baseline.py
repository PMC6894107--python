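"""Traditional two-step baseline: attribute NER, then relation classification.

Step 1 recognizes attribute mentions with a concept-blind Bi-LSTM-CRF (the
same stack as the target-aware tagger but without the concept-role channel,
input width 100).  Step 2 generates every attribute-concept pair within a
sentence as a candidate and classifies each pair as related or not with a
binary classifier per attribute type — either a linear margin classifier
(hinge loss, L2) over hashed bag-of-word/position features, or a Bi-LSTM
over the sentence with word + position embeddings feeding a softmax.

Relation classifiers are trained on gold mentions and applied to predicted
mentions (the standard cascade protocol), so NER errors propagate: a gold
pair whose attribute mention the NER step missed can never be recovered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from sklearn.feature_extraction import FeatureHasher
from sklearn.svm import LinearSVC

from . import autodiff as ad
from .autodiff import Parameter, Tensor
from .cfs import ConceptFocusedSequence, decode_cfs
from .corpus import (
    AnnotatedDocument,
    AttributeMention,
    ConceptMention,
    TASK_ATTR_TYPES,
    Token,
    align_span,
)
from .tagger import BiLstmCrfTagger, TaggerConfig, bio_label_set, train


# ---------------------------------------------------------------------------
# Step 1: concept-blind attribute NER
# ---------------------------------------------------------------------------

def ner_sequences(docs: Iterable[AnnotatedDocument]) -> list[ConceptFocusedSequence]:
    """One sequence per sentence; BIO labels over *all* attribute mentions,
    each labeled once regardless of how many concepts it relates to."""
    out: list[ConceptFocusedSequence] = []
    for doc in docs:
        for si, (sspan, tokens) in enumerate(doc.sentences):
            labels = ["O"] * len(tokens)
            for a in doc.attributes:
                if not a.span.overlaps(sspan):
                    continue
                lo, hi = align_span(a.span, tokens)
                for i in range(lo, hi):
                    labels[i] = ("B-" if i == lo else "I-") + a.attr_type
            out.append(ConceptFocusedSequence(
                doc_id=doc.doc_id, sentence_index=si, target_concept_id="",
                tokens=list(tokens), concept_tags=["Outside"] * len(tokens),
                labels=labels,
            ))
    return out


def ner_train(
    docs: Sequence[AnnotatedDocument], config: TaggerConfig
) -> tuple[BiLstmCrfTagger, list[float]]:
    """Train the attribute NER tagger (role channel removed)."""
    if not docs:
        raise ValueError("empty document list")
    if config.use_roles:
        raise ValueError("NER baseline must use use_roles=False")
    return train(ner_sequences(docs), config)


def ner_predict(
    model: BiLstmCrfTagger, docs: Sequence[AnnotatedDocument]
) -> dict[str, list[tuple[int, AttributeMention]]]:
    """Predicted attribute mentions per document as (sentence_index, mention)."""
    seqs = ner_sequences(docs)
    out: dict[str, list[tuple[int, AttributeMention]]] = {d.doc_id: [] for d in docs}
    for cfs, labels in zip(seqs, model.predict(seqs)):
        for mention, _ in decode_cfs(cfs, labels, id_prefix="N"):
            out[cfs.doc_id].append((cfs.sentence_index, mention))
    return out


def gold_mentions_by_sentence(
    docs: Sequence[AnnotatedDocument],
) -> dict[str, list[tuple[int, AttributeMention]]]:
    out: dict[str, list[tuple[int, AttributeMention]]] = {d.doc_id: [] for d in docs}
    for doc in docs:
        for a in doc.attributes:
            out[doc.doc_id].append((doc.sentence_index_of(a.span), a))
    return out


# ---------------------------------------------------------------------------
# Step 2: candidate pairs and relation classification
# ---------------------------------------------------------------------------

@dataclass
class CandidatePair:
    """One (concept, attribute) pair in one sentence."""

    doc_id: str
    sentence_index: int
    concept: ConceptMention
    attribute: AttributeMention
    tokens: list[Token]
    label: bool | None = None           # gold relatedness, when known
    provenance: Literal["gold", "predicted"] = "gold"


@dataclass
class PairFeatures:
    """The contextual/semantic feature bundle for one candidate pair."""

    before: list[str]
    between: list[str]
    after: list[str]
    inside_attr: list[str]
    inside_concept: list[str]
    signed_distance: int     # tokens between the pair; <0 when attr precedes
    overlap: bool

    def to_strings(self) -> list[str]:
        feats = [f"bef={w}" for w in self.before]
        feats += [f"btw={w}" for w in self.between]
        feats += [f"aft={w}" for w in self.after]
        feats += [f"attr={w}" for w in self.inside_attr]
        feats += [f"con={w}" for w in self.inside_concept]
        d = max(-15, min(15, self.signed_distance))
        feats.append(f"dist={d}")
        feats.append(f"dir={'L' if self.signed_distance < 0 else 'R' if self.signed_distance > 0 else 'O'}")
        if self.overlap:
            feats.append("overlap")
        return feats


def generate_candidates(
    doc: AnnotatedDocument,
    attributes: Sequence[tuple[int, AttributeMention]],
    provenance: Literal["gold", "predicted"] = "gold",
) -> list[CandidatePair]:
    """Cartesian product of concepts x attributes within each sentence.

    With gold provenance, labels mark pairs positive when a gold relation
    links them; predicted mentions get ``label=None``.
    """
    gold_links = {(r.concept_id, r.attribute_id) for r in doc.relations}
    out: list[CandidatePair] = []
    for si, (sspan, tokens) in enumerate(doc.sentences):
        concepts = [c for c in doc.concepts
                    if sspan.start <= c.span.start and c.span.end <= sspan.end]
        attrs = [a for s, a in attributes if s == si]
        for c in concepts:
            for a in attrs:
                label = None
                if provenance == "gold":
                    label = (c.id, a.id) in gold_links
                out.append(CandidatePair(
                    doc_id=doc.doc_id, sentence_index=si, concept=c,
                    attribute=a, tokens=list(tokens), label=label,
                    provenance=provenance,
                ))
    return out


def featurize_pair(pair: CandidatePair) -> PairFeatures:
    tokens = pair.tokens
    c_lo, c_hi = align_span(pair.concept.span, tokens)
    a_lo, a_hi = align_span(pair.attribute.span, tokens)
    words = [t.text.lower() for t in tokens]
    if a_lo >= c_hi:          # attribute strictly right of concept
        dist = a_lo - c_hi + 1
        between = words[c_hi:a_lo]
    elif a_hi <= c_lo:        # strictly left
        dist = -(c_lo - a_hi + 1)
        between = words[a_hi:c_lo]
    else:                     # overlapping mentions
        dist = 0
        between = []
    lo, hi = min(a_lo, c_lo), max(a_hi, c_hi)
    return PairFeatures(
        before=words[:lo], between=between, after=words[hi:],
        inside_attr=words[a_lo:a_hi], inside_concept=words[c_lo:c_hi],
        signed_distance=dist, overlap=(dist == 0),
    )


class MarginRelationClassifier:
    """Per-attribute-type linear margin classifier (hinge loss, L2, C=1).

    Feature strings are hashed into a fixed-width sparse space, so the
    model is deterministic and vocabulary-free.  A type whose training
    data contains a single class degenerates to a majority predictor
    (with a warning), as can happen for rare attributes.
    """

    def __init__(self, attr_types: Sequence[str], n_features: int = 2 ** 18,
                 C: float = 1.0, seed: int = 0):
        self.attr_types = tuple(attr_types)
        self.hasher = FeatureHasher(n_features=n_features, input_type="string")
        self.C = C
        self.seed = seed
        self.models: dict[str, LinearSVC | bool] = {}

    def fit(self, pairs: Sequence[CandidatePair]) -> "MarginRelationClassifier":
        for t in self.attr_types:
            sub = [p for p in pairs if p.attribute.attr_type == t]
            if not sub:
                self.models[t] = True  # no data: predict positive (majority
                # of candidate pools for attached attributes is positive)
                continue
            y = np.array([bool(p.label) for p in sub])
            if y.all() or not y.any():
                warnings.warn(
                    f"single-class training data for {t}; using constant predictor"
                )
                self.models[t] = bool(y[0])
                continue
            X = self.hasher.transform(
                [featurize_pair(p).to_strings() for p in sub]
            )
            clf = LinearSVC(C=self.C, random_state=self.seed)
            clf.fit(X, y)
            self.models[t] = clf
        return self

    def predict(self, pairs: Sequence[CandidatePair]) -> np.ndarray:
        out = np.zeros(len(pairs), dtype=bool)
        for t in self.attr_types:
            idx = [i for i, p in enumerate(pairs) if p.attribute.attr_type == t]
            if not idx:
                continue
            model = self.models.get(t, True)
            if isinstance(model, bool):
                out[idx] = model
                continue
            X = self.hasher.transform(
                [featurize_pair(pairs[i]).to_strings() for i in idx]
            )
            out[idx] = model.predict(X)
        return out


@dataclass
class PairLstmConfig:
    """Bi-LSTM pair-classifier hyperparameters (word + position embeddings,
    both randomly initialized)."""

    word_dim: int = 50
    pos_dim: int = 10
    hidden: int = 100
    learning_rate: float = 0.005
    epochs: int = 10
    seed: int = 0
    clip_norm: float = 5.0
    pos_clip: int = 15   # distance buckets clipped to +/- this many tokens


class LstmRelationClassifier:
    """Bi-LSTM + softmax over candidate pairs, one binary model per type.

    Each sentence token is embedded as word-embedding (+) bucketed-distance
    embedding to the concept (+) bucketed-distance embedding to the
    attribute; the final forward/backward LSTM states feed a 2-way softmax.
    """

    def __init__(self, attr_types: Sequence[str], config: PairLstmConfig | None = None):
        self.attr_types = tuple(attr_types)
        self.config = config or PairLstmConfig()
        self.word_index: dict[str, int] = {"<UNK>": 0}
        self.params_by_type: dict[str, dict[str, Parameter] | bool] = {}

    # -- internals ---------------------------------------------------------
    def _word_id(self, w: str) -> int:
        return self.word_index.get(w.lower(), 0)

    def _pos_bucket(self, t: int, lo: int, hi: int) -> int:
        c = self.config.pos_clip
        if lo <= t < hi:
            d = 0
        elif t >= hi:
            d = min(c, t - hi + 1)
        else:
            d = max(-c, t - lo)
        return d + c  # index in [0, 2c]

    def _init_params(self, rng: np.random.Generator) -> dict[str, Parameter]:
        c = self.config
        nb = 2 * c.pos_clip + 1

        def u(*shape: int) -> np.ndarray:
            s = np.sqrt(6.0 / sum(shape))
            return rng.uniform(-s, s, size=shape)

        d_in = c.word_dim + 2 * c.pos_dim
        p = {
            "E_word": Parameter(u(len(self.word_index), c.word_dim)),
            "E_pc": Parameter(u(nb, c.pos_dim)),
            "E_pa": Parameter(u(nb, c.pos_dim)),
            "W_out": Parameter(u(2 * c.hidden, 2)),
            "b_out": Parameter(np.zeros(2)),
        }
        for name in ("fwd", "bwd"):
            p[f"{name}.Wx"] = Parameter(u(d_in, 4 * c.hidden))
            p[f"{name}.Wh"] = Parameter(u(c.hidden, 4 * c.hidden))
            b = np.zeros(4 * c.hidden)
            b[c.hidden : 2 * c.hidden] = 1.0
            p[f"{name}.b"] = Parameter(b)
        return p

    def _lstm_pass(self, params: dict[str, Parameter], x: Tensor,
                   name: str, order: range) -> Tensor:
        H = self.config.hidden
        h = Tensor(np.zeros(H))
        c = Tensor(np.zeros(H))
        Wx, Wh, b = params[f"{name}.Wx"], params[f"{name}.Wh"], params[f"{name}.b"]
        for t in order:
            z = x[t] @ Wx + h @ Wh + b
            i, f, g, o = z[0:H], z[H:2 * H], z[2 * H:3 * H], z[3 * H:4 * H]
            c = ad.sigmoid(f) * c + ad.sigmoid(i) * ad.tanh(g)
            h = ad.sigmoid(o) * ad.tanh(c)
        return h

    def _logits(self, params: dict[str, Parameter], pair: CandidatePair) -> Tensor:
        tokens = pair.tokens
        c_lo, c_hi = align_span(pair.concept.span, tokens)
        a_lo, a_hi = align_span(pair.attribute.span, tokens)
        wid = np.array([self._word_id(t.text) for t in tokens], dtype=np.intp)
        pc = np.array([self._pos_bucket(t, c_lo, c_hi) for t in range(len(tokens))],
                      dtype=np.intp)
        pa = np.array([self._pos_bucket(t, a_lo, a_hi) for t in range(len(tokens))],
                      dtype=np.intp)
        x = ad.concat([ad.rows(params["E_word"], wid),
                       ad.rows(params["E_pc"], pc),
                       ad.rows(params["E_pa"], pa)], axis=1)
        T = len(tokens)
        hf = self._lstm_pass(params, x, "fwd", range(T))
        hb = self._lstm_pass(params, x, "bwd", range(T - 1, -1, -1))
        return ad.concat([hf, hb]) @ params["W_out"] + params["b_out"]

    # -- API ---------------------------------------------------------------
    def fit(self, pairs: Sequence[CandidatePair]) -> "LstmRelationClassifier":
        cfg = self.config
        for p in pairs:
            for tok in p.tokens:
                self.word_index.setdefault(tok.text.lower(), len(self.word_index))
        for t in self.attr_types:
            sub = [p for p in pairs if p.attribute.attr_type == t]
            if not sub:
                self.params_by_type[t] = True
                continue
            y = np.array([bool(p.label) for p in sub])
            if y.all() or not y.any():
                warnings.warn(
                    f"single-class training data for {t}; using constant predictor"
                )
                self.params_by_type[t] = bool(y[0])
                continue
            rng = np.random.default_rng(cfg.seed)
            params = self._init_params(rng)
            plist = list(params.values())
            idx = np.arange(len(sub))
            for _epoch in range(cfg.epochs):
                rng.shuffle(idx)
                for i in idx:
                    logits = self._logits(params, sub[i])
                    target = 1 if sub[i].label else 0
                    loss = ad.logsumexp(logits, axis=0) - logits[target]
                    loss.backward()
                    ad.sgd_step(plist, cfg.learning_rate, cfg.clip_norm)
            self.params_by_type[t] = params
        return self

    def predict(self, pairs: Sequence[CandidatePair]) -> np.ndarray:
        out = np.zeros(len(pairs), dtype=bool)
        for i, p in enumerate(pairs):
            model = self.params_by_type.get(p.attribute.attr_type, True)
            if isinstance(model, bool):
                out[i] = model
            else:
                logits = self._logits(model, p).data
                out[i] = bool(logits[1] > logits[0])
        return out


# ---------------------------------------------------------------------------
# The full cascade
# ---------------------------------------------------------------------------

class TwoStepSystem:
    """Attribute NER -> candidate generation -> relation classification."""

    def __init__(
        self,
        task: str,
        relation_mode: Literal["margin", "lstm"] = "margin",
        ner_config: TaggerConfig | None = None,
        pair_config: PairLstmConfig | None = None,
        seed: int = 0,
    ):
        self.task = task
        self.relation_mode = relation_mode
        attr_types = TASK_ATTR_TYPES[task]
        self.ner_config = ner_config or TaggerConfig(
            label_set=bio_label_set(attr_types), use_roles=False, seed=seed
        )
        if self.ner_config.use_roles:
            raise ValueError("two-step NER must not use the role channel")
        self.pair_config = pair_config or PairLstmConfig(seed=seed)
        self.seed = seed
        self.ner_model: BiLstmCrfTagger | None = None
        self.relation_model: MarginRelationClassifier | LstmRelationClassifier | None = None

    def fit(self, docs: Sequence[AnnotatedDocument]) -> "TwoStepSystem":
        self.ner_model, _ = ner_train(docs, self.ner_config)
        gold_pairs: list[CandidatePair] = []
        for doc in docs:
            gold_pairs.extend(generate_candidates(
                doc, gold_mentions_by_sentence([doc])[doc.doc_id], "gold"
            ))
        attr_types = TASK_ATTR_TYPES[self.task]
        if self.relation_mode == "margin":
            self.relation_model = MarginRelationClassifier(attr_types, seed=self.seed)
        else:
            self.relation_model = LstmRelationClassifier(attr_types, self.pair_config)
        self.relation_model.fit(gold_pairs)
        return self

    def predict(
        self,
        docs: Sequence[AnnotatedDocument],
        mentions: Mapping[str, Sequence[tuple[int, AttributeMention]]] | None = None,
    ) -> dict[str, list[tuple[str, AttributeMention]]]:
        """Predictions as {doc_id: [(concept_id, attribute mention), ...]}.

        ``mentions`` overrides the NER step (used e.g. to study error
        propagation by deleting a fraction of predicted mentions).
        """
        if self.ner_model is None or self.relation_model is None:
            raise RuntimeError("fit() must be called before predict()")
        if mentions is None:
            mentions = ner_predict(self.ner_model, docs)
        out: dict[str, list[tuple[str, AttributeMention]]] = {}
        for doc in docs:
            cands = generate_candidates(
                doc, mentions.get(doc.doc_id, ()), "predicted"
            )
            preds = self.relation_model.predict(cands) if cands else []
            out[doc.doc_id] = [
                (c.concept.id, c.attribute) for c, keep in zip(cands, preds) if keep
            ]
        return out
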