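"""Effect of the blank-line layout features on held-out recognition.

Trains two CRF models on the same split — one with all feature families,
one without the layout family — and prints the signed P/R/F differences.
Layout indicators mainly help on headings absent from the training
vocabulary, whose only reliable cue is that they open a paragraph.
"""

from clinsections import (
    FeatureConfig, SynthConfig, aggregate, chunk_prf, compare_runs,
    default_lexicon, generate_corpus, tag_document,
)
from clinsections.crf import train_on_documents

notes, splits = generate_corpus(SynthConfig(n_docs=80, seed=3))
train_notes = [n for n in notes if n.doc.doc_id in set(splits["train"])]
test_notes = [n for n in notes if n.doc.doc_id in set(splits["test"])]
pairs = [(n.doc, list(n.gold)) for n in train_notes]
lexicon = default_lexicon()

full = train_on_documents(pairs, lexicon, FeatureConfig(), max_iter=100)
ablated = train_on_documents(pairs, lexicon, FeatureConfig(layout=False), max_iter=100)

score = lambda model, cfg: aggregate(
    [chunk_prf(list(n.gold), tag_document(model, n.doc, lexicon, cfg)) for n in test_notes]
)
with_layout = score(full, FeatureConfig())
without = score(ablated, FeatureConfig(layout=False))
delta = compare_runs(with_layout, without)

print(f"with layout    P={with_layout.precision:.3f} R={with_layout.recall:.3f} F={with_layout.f:.3f}")
print(f"without layout P={without.precision:.3f} R={without.recall:.3f} F={without.f:.3f}")
print(f"delta          P={delta.dp:+.3f} R={delta.dr:+.3f} F={delta.df:+.3f}")
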