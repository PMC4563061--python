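"""Generate a synthetic annotated corpus and report its structure.

Prints the opening of one note, then checks the corpus against the
structural parameters it was generated from: mean sections per document and
the fraction of headings embedded inline with other content.
"""

from clinsections import SynthConfig, generate_corpus

cfg = SynthConfig(n_docs=200, seed=7)
notes, splits = generate_corpus(cfg)

note = notes[0]
print(f"--- {note.doc.doc_id} (first 12 lines) ---")
for line in note.doc.lines[:12]:
    print(line.text)
print("...\n")
print("gold headings:", [s.text for s in note.gold[:5]], "...\n")

counts = [len(n.gold) for n in notes]
inline = sum(1 for n in notes for p in n.provenance if p["placement"] == "inline")
fused = sum(1 for n in notes for p in n.provenance if p["fused"])
print(f"notes: {len(notes)}  (splits: "
      + ", ".join(f"{k}={len(v)}" for k, v in splits.items()) + ")")
print(f"mean sections/doc: {sum(counts) / len(counts):.2f}  (configured {cfg.mean_sections_per_doc})")
print(f"inline heading fraction: {inline / sum(counts):.3f}  (configured {cfg.inline_heading_rate})")
print(f"headings fused to the preceding token: {fused} ({fused / sum(counts):.1%})")
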