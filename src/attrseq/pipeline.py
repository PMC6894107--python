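"""End-to-end systems sharing one prediction interface.

Both the one-step sequence-labeling system and the two-step cascade map a
document set to ``{doc_id: [(concept_id, AttributeMention), ...]}`` so the
evaluation module can score them identically.
"""

from __future__ import annotations

from typing import Sequence

from .cfs import decode_cfs, expand_corpus
from .corpus import AnnotatedDocument, TASK_ATTR_TYPES
from .evaluation import Predictions
from .tagger import BiLstmCrfTagger, TaggerConfig, task_label_set, train


class OneStepSystem:
    """Concept-focused sequence labeling with the target-aware tagger.

    Every (sentence, target concept) pair becomes one sequence; the tagger
    labels the target's attributes directly, so no separate relation
    classification step exists and attribute-NER errors cannot propagate.
    """

    def __init__(self, task: str, config: TaggerConfig | None = None, seed: int = 0):
        self.task = task
        self.config = config or TaggerConfig(label_set=task_label_set(task), seed=seed)
        if not self.config.use_roles:
            raise ValueError("the one-step tagger requires the role channel")
        self.model: BiLstmCrfTagger | None = None
        self.loss_trace: list[float] = []

    @classmethod
    def from_model(cls, task: str, model: BiLstmCrfTagger) -> "OneStepSystem":
        system = cls(task, config=model.config)
        system.model = model
        return system

    def fit(self, docs: Sequence[AnnotatedDocument]) -> "OneStepSystem":
        sequences = expand_corpus(docs)
        self.model, self.loss_trace = train(sequences, self.config)
        return self

    def predict(self, docs: Sequence[AnnotatedDocument]) -> Predictions:
        if self.model is None:
            raise RuntimeError("fit() must be called before predict()")
        sequences = expand_corpus(docs)
        out: dict[str, list] = {d.doc_id: [] for d in docs}
        for cfs, labels in zip(sequences, self.model.predict(sequences)):
            for mention, rel in decode_cfs(cfs, labels):
                out[cfs.doc_id].append((rel.concept_id, mention))
        return out

    @property
    def attr_types(self) -> tuple[str, ...]:
        return TASK_ATTR_TYPES[self.task]
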