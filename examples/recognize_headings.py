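"""Train the CRF tagger on synthetic notes and tag an unseen note.

Builds a small seeded corpus, fits the tagger on its training split, then
prints every heading span recovered from one held-out note next to the gold
annotation.  Each line of output is a character interval plus the heading
surface; the final line is the exact-span P/R/F over the whole test split.
"""

from clinsections import (
    FeatureConfig, SynthConfig, aggregate, chunk_prf, default_lexicon,
    generate_corpus, tag_document,
)
from clinsections.crf import train_on_documents

notes, splits = generate_corpus(SynthConfig(n_docs=60, seed=42))
by_id = {n.doc.doc_id: n for n in notes}
train_notes = [by_id[i] for i in splits["train"]]
test_notes = [by_id[i] for i in splits["test"]]
lexicon = default_lexicon()

model = train_on_documents(
    [(n.doc, list(n.gold)) for n in train_notes], lexicon, FeatureConfig(), max_iter=100
)
print(f"trained on {len(train_notes)} notes "
      f"({model.metadata['n_features']} features, {model.metadata['iterations']} iterations)\n")

note = test_notes[0]
pred = tag_document(model, note.doc, lexicon)
gold_set = {s.interval() for s in note.gold}
print(f"predicted headings in {note.doc.doc_id}:")
for s in pred:
    mark = "=" if s.interval() in gold_set else "!"  # ! = not an exact gold match
    print(f"  {mark} [{s.start:4d},{s.end:4d})  {s.text!r}")

total = aggregate([
    chunk_prf(list(n.gold), tag_document(model, n.doc, lexicon)) for n in test_notes
])
print(f"\ntest split ({len(test_notes)} notes): "
      f"P={total.precision:.3f} R={total.recall:.3f} F={total.f:.3f}")
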