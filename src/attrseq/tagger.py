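"""Target-aware Bi-LSTM-CRF sequence tagger.

Each token of a concept-focused sequence is represented as the
concatenation of

* a word embedding (dim 50, lookup on the lowercased surface form),
* the final states of a character-level Bi-LSTM run over the token's
  characters (2 x 25), which sees the original case, and
* an embedding of the token's concept-role tag (Target / NotTarget /
  Outside, dim 10) — the only channel that distinguishes two sequences
  built from the same sentence for different target concepts.

The 110-dim inputs feed a word-level Bi-LSTM (hidden 100 per direction)
whose states are projected to per-label emission scores for a linear-chain
CRF.  Training is plain SGD (lr 0.005) on the negative log-likelihood, one
sequence per update, sequences shuffled every epoch under the config seed,
with dropout (p 0.5) on the word-LSTM input and output during training
only and gradient-norm clipping at 5.0.  All embeddings are randomly
initialized and learned from the data alone.

For the concept-blind attribute NER baseline the role channel is removed
(``use_roles=False``, input width 100); everything else is identical.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Parameter, Tensor
from .cfs import ConceptFocusedSequence, ROLE_TAGS
from .corpus import TASK_ATTR_TYPES
from .crf import (
    crf_log_likelihood,
    make_transitions,
    viterbi_decode,
)

CHECKPOINT_VERSION = "attrseq-tagger-v1"


def bio_label_set(attr_types: Sequence[str]) -> tuple[str, ...]:
    """Ordered BIO label set with O first (ties decode to O)."""
    labels = ["O"]
    for t in attr_types:
        labels += [f"B-{t}", f"I-{t}"]
    return tuple(labels)


def task_label_set(task: str) -> tuple[str, ...]:
    return bio_label_set(TASK_ATTR_TYPES[task])


@dataclass
class TaggerConfig:
    """Hyperparameters; defaults follow the published configuration."""

    label_set: tuple[str, ...]
    word_dim: int = 50
    char_dim: int = 25
    word_hidden: int = 100
    char_hidden: int = 25
    role_tag_dim: int = 10
    learning_rate: float = 0.005
    dropout_prob: float = 0.5
    epochs: int = 30
    seed: int = 0
    clip_norm: float = 5.0
    unk_threshold: int = 2   # train-time UNK substitution below this count
    unk_prob: float = 0.5
    use_roles: bool = True

    def __post_init__(self) -> None:
        if "O" not in self.label_set:
            raise ValueError("label set must contain O")
        if not (0.0 <= self.dropout_prob < 1.0):
            raise ValueError("dropout probability must be in [0, 1)")
        for name in ("word_dim", "char_dim", "word_hidden", "char_hidden",
                     "role_tag_dim"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def input_width(self) -> int:
        w = self.word_dim + 2 * self.char_hidden
        return w + self.role_tag_dim if self.use_roles else w


@dataclass
class Vocab:
    """Dense index maps for words, characters, roles and labels."""

    word_index: dict[str, int]
    char_index: dict[str, int]
    role_index: dict[str, int]
    label_index: dict[str, int]
    word_counts: dict[str, int] = field(default_factory=dict)

    UNK = "<UNK>"

    @classmethod
    def build(
        cls, sequences: Sequence[ConceptFocusedSequence], label_set: Sequence[str]
    ) -> "Vocab":
        wc: Counter[str] = Counter()
        chars: set[str] = set()
        for cfs in sequences:
            for tok in cfs.tokens:
                wc[tok.text.lower()] += 1
                chars.update(tok.text)
        word_index = {cls.UNK: 0}
        for w in sorted(wc):
            word_index[w] = len(word_index)
        char_index = {cls.UNK: 0}
        for c in sorted(chars):
            char_index[c] = len(char_index)
        role_index = {r: i for i, r in enumerate(ROLE_TAGS)}
        label_index = {l: i for i, l in enumerate(label_set)}
        return cls(word_index, char_index, role_index, label_index, dict(wc))

    def word_id(self, word: str) -> int:
        return self.word_index.get(word.lower(), 0)

    def char_ids(self, word: str) -> list[int]:
        return [self.char_index.get(c, 0) for c in word]

    @property
    def labels(self) -> list[str]:
        return [l for l, _ in sorted(self.label_index.items(), key=lambda kv: kv[1])]


def _init(rng: np.random.Generator, *shape: int) -> np.ndarray:
    scale = np.sqrt(6.0 / sum(shape)) if len(shape) > 1 else 0.0
    if len(shape) == 1:
        return np.zeros(shape)
    return rng.uniform(-scale, scale, size=shape)


class _LSTM:
    """One-direction LSTM cell parameters (input dim D, hidden H)."""

    def __init__(self, name: str, d: int, h: int, rng: np.random.Generator):
        self.h = h
        self.Wx = Parameter(_init(rng, d, 4 * h))
        self.Wh = Parameter(_init(rng, h, 4 * h))
        b = np.zeros(4 * h)
        b[h : 2 * h] = 1.0  # forget-gate bias
        self.b = Parameter(b)
        self.name = name

    def params(self) -> dict[str, Parameter]:
        return {f"{self.name}.Wx": self.Wx, f"{self.name}.Wh": self.Wh,
                f"{self.name}.b": self.b}

    def step(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        H = self.h
        z = x @ self.Wx + h @ self.Wh + self.b
        if z.data.ndim == 1:
            i, f, g, o = z[0:H], z[H : 2 * H], z[2 * H : 3 * H], z[3 * H : 4 * H]
        else:
            i, f, g, o = (z[:, 0:H], z[:, H : 2 * H],
                          z[:, 2 * H : 3 * H], z[:, 3 * H : 4 * H])
        c_new = ad.sigmoid(f) * c + ad.sigmoid(i) * ad.tanh(g)
        h_new = ad.sigmoid(o) * ad.tanh(c_new)
        return h_new, c_new


class BiLstmCrfTagger:
    """The trainable model: embeddings + char/word Bi-LSTMs + CRF."""

    def __init__(self, config: TaggerConfig, vocab: Vocab):
        self.config = config
        self.vocab = vocab
        rng = np.random.default_rng(config.seed)
        c = config
        self.E_word = Parameter(_init(rng, len(vocab.word_index), c.word_dim))
        self.E_char = Parameter(_init(rng, len(vocab.char_index), c.char_dim))
        self.E_role = Parameter(_init(rng, len(vocab.role_index), c.role_tag_dim))
        self.char_fwd = _LSTM("char_fwd", c.char_dim, c.char_hidden, rng)
        self.char_bwd = _LSTM("char_bwd", c.char_dim, c.char_hidden, rng)
        self.word_fwd = _LSTM("word_fwd", c.input_width, c.word_hidden, rng)
        self.word_bwd = _LSTM("word_bwd", c.input_width, c.word_hidden, rng)
        L = len(c.label_set)
        self.W_out = Parameter(_init(rng, 2 * c.word_hidden, L))
        self.b_out = Parameter(np.zeros(L))
        self.transitions = make_transitions(L, rng)
        self._rng = rng  # dropout / UNK substitution stream

    # -- parameter registry ------------------------------------------------
    def parameters(self) -> dict[str, Parameter]:
        out: dict[str, Parameter] = {
            "E_word": self.E_word, "E_char": self.E_char, "E_role": self.E_role,
            "W_out": self.W_out, "b_out": self.b_out,
            "transitions": self.transitions,
        }
        for lstm in (self.char_fwd, self.char_bwd, self.word_fwd, self.word_bwd):
            out.update(lstm.params())
        return out

    # -- forward pass ------------------------------------------------------
    def _char_states(self, words: list[str]) -> Tensor:
        """(T, 2*char_hidden) final char-BiLSTM states, batched over tokens."""
        H = self.config.char_hidden
        T = len(words)
        maxlen = max(len(w) for w in words)
        idx = np.zeros((T, maxlen), dtype=np.intp)
        mask = np.zeros((T, maxlen))
        for r, w in enumerate(words):
            ids = self.vocab.char_ids(w)
            idx[r, : len(ids)] = ids
            mask[r, : len(ids)] = 1.0
        outs = []
        for lstm, order in ((self.char_fwd, range(maxlen)),
                            (self.char_bwd, range(maxlen - 1, -1, -1))):
            h = Tensor(np.zeros((T, H)))
            c = Tensor(np.zeros((T, H)))
            for k in order:
                x = ad.rows(self.E_char, idx[:, k])
                h_new, c_new = lstm.step(x, h, c)
                m = Tensor(mask[:, k : k + 1])
                h = m * h_new + (1.0 - m) * h
                c = m * c_new + (1.0 - m) * c
            outs.append(h)
        return ad.concat(outs, axis=1)

    def _inputs(self, cfs: ConceptFocusedSequence, training: bool) -> Tensor:
        words = [t.text for t in cfs.tokens]
        word_ids = np.array([self.vocab.word_id(w) for w in words], dtype=np.intp)
        if training and self.config.unk_threshold > 0:
            rare = np.array([
                self.vocab.word_counts.get(w.lower(), 0) < self.config.unk_threshold
                for w in words
            ])
            drop = self._rng.random(len(words)) < self.config.unk_prob
            word_ids = np.where(rare & drop, 0, word_ids)
        parts = [ad.rows(self.E_word, word_ids), self._char_states(words)]
        if self.config.use_roles:
            role_ids = np.array(
                [self.vocab.role_index[r] for r in cfs.concept_tags], dtype=np.intp
            )
            parts.append(ad.rows(self.E_role, role_ids))
        return ad.concat(parts, axis=1)

    def emissions(self, cfs: ConceptFocusedSequence, training: bool = False) -> Tensor:
        """(T, |labels|) emission scores."""
        x = self._inputs(cfs, training)
        x = ad.dropout_mask(x, self.config.dropout_prob, self._rng, training)
        H = self.config.word_hidden
        T = len(cfs.tokens)
        states: dict[str, list[Tensor]] = {"f": [], "b": []}
        for key, lstm, order in (("f", self.word_fwd, range(T)),
                                 ("b", self.word_bwd, range(T - 1, -1, -1))):
            h = Tensor(np.zeros(H))
            c = Tensor(np.zeros(H))
            for t in order:
                h, c = lstm.step(x[t], h, c)
                states[key].append(h)
        states["b"].reverse()
        Hmat = ad.concat([ad.stack(states["f"]), ad.stack(states["b"])], axis=1)
        Hmat = ad.dropout_mask(Hmat, self.config.dropout_prob, self._rng, training)
        return Hmat @ self.W_out + self.b_out

    def embed_sequence(self, cfs: ConceptFocusedSequence) -> np.ndarray:
        """Per-token input vectors (dropout disabled); width 110 with roles."""
        return self._inputs(cfs, training=False).data

    # -- training / inference ---------------------------------------------
    def loss(self, cfs: ConceptFocusedSequence, training: bool = True) -> Tensor:
        gold = np.array(
            [self.vocab.label_index[l] for l in cfs.labels], dtype=np.intp
        )
        e = self.emissions(cfs, training=training)
        return -1.0 * crf_log_likelihood(e, self.transitions, gold)

    def predict(
        self, sequences: Sequence[ConceptFocusedSequence]
    ) -> list[list[str]]:
        """Viterbi labels per sequence; deterministic given parameters."""
        labels = self.vocab.labels
        out = []
        for cfs in sequences:
            e = self.emissions(cfs, training=False)
            path, _ = viterbi_decode(e, self.transitions)
            out.append([labels[i] for i in path])
        return out

    # -- checkpointing -----------------------------------------------------
    def save(self, path: str | Path) -> Path:
        path = Path(path)
        meta = {
            "version": CHECKPOINT_VERSION,
            "config": {**asdict(self.config), "label_set": list(self.config.label_set)},
            "vocab": {
                "word_index": self.vocab.word_index,
                "char_index": self.vocab.char_index,
                "role_index": self.vocab.role_index,
                "label_index": self.vocab.label_index,
                "word_counts": self.vocab.word_counts,
            },
        }
        arrays = {k: p.data for k, p in self.parameters().items()}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)
        return path if path.suffix == ".npz" else Path(str(path) + ".npz")

    @classmethod
    def load(cls, path: str | Path) -> "BiLstmCrfTagger":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"].tobytes()).decode())
            if meta["version"] != CHECKPOINT_VERSION:
                raise ValueError(f"unsupported checkpoint version {meta['version']}")
            cfg_d = meta["config"]
            cfg_d["label_set"] = tuple(cfg_d["label_set"])
            config = TaggerConfig(**cfg_d)
            vocab = Vocab(
                word_index=meta["vocab"]["word_index"],
                char_index=meta["vocab"]["char_index"],
                role_index=meta["vocab"]["role_index"],
                label_index=meta["vocab"]["label_index"],
                word_counts=meta["vocab"]["word_counts"],
            )
            model = cls(config, vocab)
            for k, p in model.parameters().items():
                p.data = z[k].copy()
        return model


def train(
    sequences: Sequence[ConceptFocusedSequence],
    config: TaggerConfig,
    vocab: Vocab | None = None,
    log_every: int = 0,
) -> tuple[BiLstmCrfTagger, list[float]]:
    """SGD training; returns the model and the per-epoch mean loss trace.

    Sequences are shuffled each epoch under ``config.seed``; with
    ``epochs=0`` the randomly initialized model is returned untrained.
    """
    if len(sequences) == 0:
        raise ValueError("training set is empty")
    if vocab is None:
        vocab = Vocab.build(sequences, config.label_set)
    model = BiLstmCrfTagger(config, vocab)
    params = list(model.parameters().values())
    order_rng = np.random.default_rng(config.seed + 1)
    trace: list[float] = []
    idx = np.arange(len(sequences))
    for epoch in range(config.epochs):
        order_rng.shuffle(idx)
        total = 0.0
        for i in idx:
            loss = model.loss(sequences[i], training=True)
            loss.backward()
            ad.sgd_step(params, config.learning_rate, config.clip_norm)
            total += float(loss.data)
        trace.append(total / len(sequences))
        if log_every and (epoch + 1) % log_every == 0:
            print(f"epoch {epoch + 1}: mean NLL {trace[-1]:.4f}")
    return model, trace
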