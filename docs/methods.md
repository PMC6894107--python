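# Methods

## The task and the model

Given clinical text with *gold* concept mentions (disorders, medications,
or lab tests), the task is to find each concept's attribute mentions and
their types: for disorders, negation (NEG), subject (SUB), conditional
(CON), severity (SEV), course (COU), uncertainty (UNC) and body location
(BDL); for medications, dosage (DOS), mode (MOD), frequency (FRE),
duration (DUR) and reason (REA); for lab tests, the value (VAL).  Output
is a set of (concept, attribute-span, attribute-type) pairs.

The one-step formulation rewrites the task as sequence labeling.  Every
(sentence, target concept) pair becomes a concept-focused sequence: a
per-token role channel (`Target` / `NotTarget` / `Outside`) tells the
model which concept is in focus, and BIO labels mark only the attributes
related to that concept.  The tagger is a standard hierarchical
Bi-LSTM-CRF: character Bi-LSTM final states capture word shape
(capitalization, digits, "134/75"-style compounds), word embeddings are
looked up on the lowercased form, the role-tag embedding carries the
target information, and a linear-chain CRF scores label sequences with
learned transitions plus virtual START/STOP states.

Assumptions inherited from the task design:

* relations are intra-sentential — relations whose endpoints fall in
  different sentences are dropped with a warning at CFS expansion;
* mentions are contiguous — discontiguous (disjoint) standoff mentions
  are rejected at load, matching the usual pre-processing of the shared
  tasks;
* attribute spans may overlap or nest inside concept spans; roles and
  BIO labels are independent channels and never veto each other.

## Hyperparameters

| parameter | default | note |
|---|---|---|
| word embedding dim | 50 | random init, learned |
| char embedding dim | 25 | random init, learned |
| word LSTM hidden / dir | 100 | emissions read the 200-dim concat |
| char LSTM hidden / dir | 25 | final states only (50 total) |
| role-tag embedding dim | 10 | the only target-dependent input |
| optimizer | plain SGD, lr 0.005 | one sequence per update |
| dropout | 0.5 | word-LSTM input and output, training only |
| epochs | 30 | no early stopping |
| gradient clip (global norm) | 5.0 | stabilizes batch-1 SGD |
| train-time UNK substitution | words with corpus count < 2, p = 0.5 | trains the UNK vector |

The first seven rows are the published configuration of the system this
package implements; the last three are choices the publication leaves
open, fixed here and configurable in `TaggerConfig`.

**Step-size scaling.** The published rate (0.005) is calibrated for
corpora of hundreds of clinical notes, i.e. hundreds of thousands of SGD
updates.  On desk-scale synthetic corpora (tens to hundreds of sentences)
that schedule barely moves the parameters: on a 10-sentence corpus the
loss plateaus far from the optimum within 30 epochs at lr 0.005, while
the identical model reaches training F1 = 1.0 at lr 0.3, and on the
~500-sentence study corpus lr 0.1 with 12 epochs converges cleanly
(per-epoch mean NLL 5.7 → 0.6).  The package therefore keeps the
published value as the default and uses an explicit "desk-scale" schedule
(lr 0.1–0.3, 12–30 epochs) in its tests, examples and acceptance script.
This is a statement about optimization budget, not about the model.  The
overfit *capacity* check additionally disables dropout: it asks whether
the architecture can represent and fit the training mapping, and
dropout's gradient noise is irrelevant to that question (with dropout on,
the check becomes seed-sensitive on a 10-sentence corpus).

Dropout placement (word-LSTM input and output) and the batch size (1)
are further open details fixed here; both are conventional for
Bi-LSTM-CRF taggers.

## The two-step baselines

Step 1 is the same tagger without the role channel (input width 100),
trained on whole sentences with every attribute mention labeled once.
Step 2 classifies every intra-sentence (concept, attribute) pair:

* **margin classifier** — one binary linear hinge-loss model (L2, C = 1)
  per attribute type over hashed string features: bags of words before /
  between / after the pair, words inside each mention, the signed token
  distance (clipped to ±15) and its direction, and an overlap flag.
  scikit-learn's `LinearSVC` and `FeatureHasher` stand behind this
  surface.
* **Bi-LSTM classifier** — per-token word embedding ⊕ bucketed-distance
  embeddings to the concept and to the attribute (buckets ±15, dim 10
  each), a Bi-LSTM (hidden 100/dir) whose final states feed a 2-way
  softmax; one model per attribute type.

Relation classifiers are trained on gold mentions and applied to
predicted mentions (standard cascade protocol).  A type whose training
pairs are single-class degenerates to a constant predictor with a
warning — this mirrors the real bias of rare attributes, whose candidate
pools are dominated by positives.

## Evaluation

Strict matching: a predicted pair is correct iff the concept (offsets),
the attribute span (exact start/end) and the type all agree with gold; an
attribute linked to *k* concepts is counted *k* times.  Concept-level
accuracy per type counts a concept correct iff its full predicted span
set for that type equals gold, including the empty ("null") set — so a
system that predicts nothing still gets credit on concepts with no gold
attribute, and one spurious prediction breaks an otherwise perfect
concept.  Cross-validation folds at document granularity (to avoid
within-note leakage) and micro-averages by pooling raw TP/predicted/gold
counts — and the accuracy numerators/denominators — across folds before
computing ratios.  A relaxed span-overlap mode exists but is off by
default.

## The synthetic generator

Template-based realization: filler tokens + concept surface forms +
attribute cue phrases drawn from fixed per-type lexicons, joined with
single spaces, one sentence per line, so character offsets are exact and
the package tokenizer reproduces the generation tokens.  Study-condition
defaults: 0–3 concepts per sentence (probabilities 0.1/0.5/0.3/0.1), 3–6
sentences per document, per-type attachment rates roughly matching the
relative frequencies of the real corpora (BDL 0.40, NEG 0.30, SEV 0.25
... for disorders; DOS 0.50, MOD 0.40, FRE 0.45 ... for medications; VAL
0.80), shared-attribute probability 0.1, distractor probability 0.2.
Distractors are attribute-like cues placed in the text and deliberately
left unannotated — the omitted-annotation phenomenon that corrupts
concept-blind NER training.  Crossing sentences (`A1 C1 and A2 C2` with
A1→C2, A2→C1, each cue adjacent to the concept it does *not* modify) are
planted at a configurable rate to defeat proximity heuristics.  Lab-test
values come in numeric ("134/75", "7.2") and categorical ("NEG",
"trace") flavors.

Every planted item is recorded in a generation ledger; tests assert the
emitted standoff annotations equal the ledger exactly, and empirical
attachment rates sit within binomial bounds of the configured ones.

What the generator does **not** emulate: real clinical vocabulary
diversity and misspellings, long-range and cross-sentence relations,
discontiguous mentions, section structure, annotation noise beyond the
planted distractors.  Passing tests on this corpus therefore demonstrate
that the implementation is correct and that the one-step formulation
beats the cascade *under the structural conditions that motivate it* —
not that the absolute scores transfer to restricted clinical corpora.

## Numerical choices

* CRF forward recursion and Viterbi use log-sum-exp / max with explicit
  stabilization; Viterbi ties break toward the lower label index
  (O is index 0), so decoding is deterministic.
* Transitions into START and out of STOP are masked with a finite −1e4
  rather than −inf: masked entries receive no gradient and never move,
  while true −inf would produce NaNs in the log-sum-exp backward pass.
* The autodiff core is reverse-mode over numpy arrays; every op and the
  full tagger loss are checked against central finite differences
  (tolerances 1e-6–1e-7) in the test suite.
* A dangling `I-t` in decoded output (no preceding `B-t`) is repaired by
  treating it as `B-t`.
* LSTM forget-gate biases initialize to 1; other weights are uniform
  Glorot-style; all randomness flows from explicit seeds
  (`numpy.random.default_rng`), and training is bit-reproducible for a
  fixed seed.

## Design decisions that were genuinely open

* **Role vocabulary**: the published description names only `Target` and
  `NotTarget`; an `Outside` role is added so every token has a role, its
  embedding learned like the others.
* **Tokenizer**: unstated in the publication.  Whitespace split, then
  leading/trailing punctuation split into separate tokens; dotted
  abbreviations ("p.m.", "q.a.m.") keep their final period; slash/digit
  compounds stay whole.  Sentences are newline-delimited by default
  (clinical notes are line-oriented), with an opt-in rule-based splitter.
* **Fold unit**: the document, to avoid train/test leakage within a note.
* **Accuracy scope**: computed per attribute type (matching the per-type
  result tables of the original evaluation), not over the joint set.
* **Checkpoint format**: one `.npz` archive holding a versioned JSON
  header (config + vocab) and the parameter tensors.

## Problem sizes used in the shipped experiments

The acceptance script and the end-to-end tests use a 111-document
(~500-sentence, ~700-concept) disorder corpus with an 80/20 document
split, 12-epoch lr-0.1 training for both taggers, 8-epoch lr-0.05
training for the pair Bi-LSTM, a 10-sentence corpus for the overfit
capacity check, and 100–120 random instances (T ≤ 4, ≤ 4 labels) for the
CRF-vs-enumeration oracle.

## Known limitations

* No pretrained or contextual embeddings (explicitly out of scope) and
  no hyperparameter search.
* Rare attribute types (SUB-like, < 10 training mentions) are learned
  poorly by every system here, as they are in the original evaluation —
  the synthetic corpus reproduces the phenomenon.
* The numpy implementation is CPU-bound and batch-1; it is sized for
  corpora of hundreds of sentences, not hundreds of notes.
* `attrseq validate` enforces the package's own standoff dialect; XML
  dialects of the original challenge distributions are not read.
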