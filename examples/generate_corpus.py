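"""Generate a synthetic medication corpus and inspect its statistics.

The generator plants target concepts (drug names), signature attributes
(dosage, mode, frequency, duration, reason), shared attributes, and
unannotated distractor cues, and records everything in a ledger.  Counts
from the emitted documents always agree with the ledger.
"""

from attrseq import GenConfig, corpus_stats, generate_corpus
from attrseq.synthetic import ledger_counts

config = GenConfig(task="medication", n_documents=10, seed=7,
                   distractor_prob=0.2, shared_attribute_prob=0.1)
docs, ledger = generate_corpus(config)

print("First document:")
print(docs[0].text)
print("\nAnnotations:")
for c in docs[0].concepts:
    print(f"  {c.id} {c.concept_type:<11} {c.span.start}-{c.span.end} {c.span.text!r}")
for a in docs[0].attributes:
    linked = [r.concept_id for r in docs[0].relations if r.attribute_id == a.id]
    print(f"  {a.id} {a.attr_type:<11} {a.span.start}-{a.span.end} "
          f"{a.span.text!r} -> {','.join(linked)}")

print("\nCorpus statistics (mirrors the ledger of planted items):")
stats = corpus_stats(docs)
for key in sorted(stats):
    print(f"  {key:<16}{stats[key]}")
assert all(stats.get(k, 0) == v for k, v in ledger_counts(ledger).items())
print("\nledger and emitted annotations agree; distractor cues appear in the"
      "\ntext but are deliberately left unannotated (omitted annotations).")
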