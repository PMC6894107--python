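# attrseq — one-step detection of medical-concept attributes

Clinical narratives qualify nearly every medical concept they mention:
disorders come with negation cues, severity modifiers and body locations
("Denied any **chest pain**"), medications carry signature information
("**insulin Lente** 12 units subcu q p.m."), lab tests have values
("**blood pressure** 134/75").  Extracting these concept–attribute pairs is
classically done in two steps — attribute named-entity recognition followed
by relation classification over every intra-sentence candidate pair — a
cascade that is complicated to build, propagates NER errors into the
relation step, and is undermined by *omitted annotations*: attribute-like
words are left unannotated in gold corpora whenever they modify no concept,
which poisons the NER training signal.

`attrseq` implements the alternative: attribute detection for a *given*
concept as a single sequence-labeling pass.

## The method

Each sentence is expanded into one **concept-focused sequence (CFS)** per
target concept.  In the CFS of target *c*:

* every token carries a concept-role tag — `Target` on the tokens of *c*,
  `NotTarget` on tokens of other concept mentions, `Outside` elsewhere;
* tokens of attributes **related to c** are labeled with the BIO scheme
  (`B-NEG`, `I-BDL`, ...); attributes of other concepts, and unassociated
  attribute-like spans, are plain `O`.

A Bi-LSTM-CRF tags each CFS.  The per-token input concatenates a word
embedding (50), the final states of a character-level Bi-LSTM (2 × 25) and
an embedding of the role tag (10) — 110 dimensions, all randomly
initialized and learned from the data.  A word-level Bi-LSTM (hidden 100
per direction) feeds emission scores to a linear-chain CRF trained by the
forward algorithm and decoded with Viterbi.  Because the role channel is
part of the input, entity recognition and relation assignment happen in
the same step, and decoded B–I runs attach directly to the target concept.

For comparison the package includes the traditional cascade — a
concept-blind attribute NER (the same stack minus the role channel) plus
per-attribute-type binary relation classifiers (a linear margin classifier
over hashed contextual features, or a Bi-LSTM with word and position
embeddings) — and the concept-aligned evaluation: strict P/R/F per
attribute type (an attribute linked to *k* concepts counts *k* times) and
concept-level accuracy

    Acc = N_correct_predict / N

where a concept is correct only if its entire predicted attribute set for
a type — possibly empty — equals gold.

The real corpora for these tasks are restricted by data-use agreements, so
the package ships a seeded generator of clinical-style synthetic corpora
reproducing their structure: 0–3 target concepts per sentence, per-type
attribute attachment rates, attributes shared between concepts,
unannotated distractor cues, and on-demand *crossing* sentences in which
each cue modifies the farther of two concepts (the case that defeats
proximity heuristics).  The neural stack runs on a small numpy
reverse-mode autodiff core included in the package; no deep-learning
framework is required.

## Worked example

`python examples/cfs_worked_example.py` builds the two-disorder sentence
*"Abdominal CT showed markedly enlarged R kidney but no air fluid level in
small bowel ."* and prints both of its concept-focused sequences.  For the
target `enlarged R kidney` it prints (abridged):

```
=== CFS for target C1: 'enlarged R kidney' ===
token       role        label
Abdominal   Outside     O
CT          Outside     O
showed      Outside     O
markedly    Outside     B-SEV
enlarged    Target      O
R           Target      B-BDL
kidney      Target      I-BDL
but         Outside     O
no          Outside     O
air         NotTarget   O
fluid       NotTarget   O
level       NotTarget   O
in          Outside     O
small       Outside     O
bowel       Outside     O
.           Outside     O
```

Only the target's own modifiers (`markedly`, and `R kidney`, which nests
inside the target span itself) are labeled; the other disorder's cues
(`no`, `small bowel`) are `O`, and in the second sequence the labeling
flips.  `Abdominal` is attribute-like but modifies nothing — precisely the
token that breaks concept-blind NER training.

Other examples: `examples/generate_corpus.py` (the synthetic generator and
its audit ledger), `examples/train_one_step.py` (training and held-out
evaluation on a lab-test corpus), `examples/compare_two_step.py` (one-step
vs. cascade).

A thin CLI covers the same ground for shell use:

```bash
attrseq generate --task disorder --seed 7 --n-documents 20 -o corpus/
attrseq validate corpus/
attrseq train --corpus corpus/ --task disorder -o model.npz
attrseq predict --model model.npz --corpus corpus/ -o pred/
attrseq evaluate --gold corpus/ --pred pred/ --task disorder
```

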