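"""Dictionary maximum matching, with and without the paragraph filter.

Shows the term-variant expansion for one heading, then scores both
dictionary methods on a synthetic test split.  Method 1 matches anywhere in
a line (good recall, poor precision: content words collide with heading
terms); method 2 keeps only matches that open a paragraph (precision up,
recall down — every inline heading is lost).
"""

from clinsections import (
    ExpandedDictionary, SynthConfig, aggregate, chunk_prf, default_lexicon,
    expand_term, filter_paragraph_initial, generate_corpus, max_match,
)

print("expand_term('DISCHARGE MEDICATIONS') includes:")
for v in sorted(expand_term("DISCHARGE MEDICATIONS"))[:10]:
    print(f"  {v!r}")
print("  ...\n")

notes, splits = generate_corpus(SynthConfig(n_docs=60, seed=42))
test_notes = [n for n in notes if n.doc.doc_id in set(splits["test"])]
dictionary = ExpandedDictionary.from_terms([e.heading for e in default_lexicon().entries])
print(f"dictionary: {len(dictionary)} expanded forms\n")

for name, predict in [
    ("method 1 (max match)", lambda n: max_match(n.doc, dictionary)),
    ("method 2 (paragraph-initial only)",
     lambda n: filter_paragraph_initial(max_match(n.doc, dictionary), n.doc)),
]:
    total = aggregate([chunk_prf(list(n.gold), predict(n)) for n in test_notes])
    print(f"{name:36s} P={total.precision:.3f} R={total.recall:.3f} F={total.f:.3f}")
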