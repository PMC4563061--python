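"""Seeded generator of synthetic discharge-summary-like notes.

The real corpora this tooling targets are access-restricted, so the
generator emulates the *structure* such notes are reported to have: about
10.7 sections per document; a bit over half of all headings embedded inline
in a line that also carries other content (the rest opening a paragraph
after a blank line); heading variants with abbreviations, capitalization
changes, colons and parenthetical supplements like "(Updated 7/20)"; and an
occasional transcription artifact that fuses a heading's first token onto
the preceding word ("...monitorHabits...").  Content lines are template
filler over pseudo-clinical word lists — the generator makes no attempt at
linguistic fidelity, only at the layout and surface statistics the
recognizers actually depend on.

Everything is driven by one numpy Generator, so a fixed seed reproduces a
corpus byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .textmodel import Document, HeadingSpan, read_brat, write_brat
from .vocab import CONTENT_WORDS, MEDICATION_WORDS, NOVEL_HEADINGS, VOCABULARY, HeadingTemplate, default_lexicon

#: Split proportions mirroring a 521/269/514 train/dev/test partition.
SPLIT_WEIGHTS = (521, 269, 514)


@dataclass(frozen=True)
class SynthConfig:
    n_docs: int = 100
    mean_sections_per_doc: float = 10.7
    #: Probability a heading is embedded mid-line, flush against content.
    inline_heading_rate: float = 0.556
    #: Probability a paragraph-initial heading comes from outside the
    #: vocabulary (and hence outside any dictionary or lexicon).
    novel_heading_rate: float = 0.08
    #: Probability of a parenthetical supplement, e.g. "Meds (Updated 7/20)".
    supplemental_insert_rate: float = 0.10
    #: Probability an inline heading is fused to the preceding token.
    tokenization_noise_rate: float = 0.02
    heading_vocabulary: tuple[HeadingTemplate, ...] = VOCABULARY
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("inline_heading_rate", "novel_heading_rate",
                     "supplemental_insert_rate", "tokenization_noise_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_docs < 1:
            raise ValueError("n_docs must be >= 1")
        if not self.heading_vocabulary:
            raise ValueError("heading vocabulary must be non-empty")


@dataclass(frozen=True)
class SynthNote:
    doc: Document
    gold: tuple[HeadingSpan, ...]
    provenance: tuple[dict, ...]


def _content_line(rng: np.random.Generator) -> str:
    """One filler content line; always ends in '.' so inline attachment has a
    clean token boundary unless noise deliberately removes it."""
    if rng.random() < 0.15:
        med = MEDICATION_WORDS[rng.integers(len(MEDICATION_WORDS))]
        return f"{med} {int(rng.integers(1, 8)) * 25} mg {'daily' if rng.random() < 0.5 else 'twice daily'}."
    n = int(rng.integers(4, 12))
    words = [CONTENT_WORDS[rng.integers(len(CONTENT_WORDS))] for _ in range(n)]
    if rng.random() < 0.5:
        words[0] = words[0].capitalize()
    return " ".join(words) + "."


def _render_heading(tmpl: HeadingTemplate, rng: np.random.Generator, cfg: SynthConfig) -> tuple[str, str]:
    """Render one vocabulary heading; returns (surface, variant label)."""
    r = rng.random()
    if tmpl.abbreviations and r < 0.30:
        name = tmpl.abbreviations[rng.integers(len(tmpl.abbreviations))]
        variant = "abbrev"
    elif r < 0.55:
        name, variant = tmpl.canonical.upper(), "upper"
    else:
        name, variant = tmpl.canonical, "canonical"
    if rng.random() < cfg.supplemental_insert_rate:
        kind = ("Updated", "confirmed with patient", "per chart")[rng.integers(3)]
        name += f" ({kind} {int(rng.integers(1, 13))}/{int(rng.integers(1, 29))})"
        variant += "+supplement"
    if rng.random() < 0.7:
        name += ":"
    return name, variant


def generate_note(config: SynthConfig, rng: np.random.Generator, doc_id: str = "note") -> SynthNote:
    """Build one note line by line, recording gold heading offsets.

    Inline headings attach flush to the end of the previous content line
    (generating one if the note is still empty); paragraph-initial headings
    follow a blank line.  Novel-vocabulary headings are only ever placed
    paragraph-initially — their recognizability is supposed to come from
    layout, not from the lexicon.  Gold offsets are computed after any
    token-fusion corruption, so they always index the final text.
    """
    lines: list[str] = []
    marks: list[tuple[int, int, int]] = []  # (line_idx, col_start, col_end)
    prov: list[dict] = []
    n_sections = max(1, int(rng.poisson(config.mean_sections_per_doc)))
    for _ in range(n_sections):
        inline = rng.random() < config.inline_heading_rate
        if inline:
            tmpl = config.heading_vocabulary[rng.integers(len(config.heading_vocabulary))]
            heading, variant = _render_heading(tmpl, rng, config)
            if not lines or not lines[-1].strip():
                lines.append(_content_line(rng))
            base = lines[-1]
            fused = (
                rng.random() < config.tokenization_noise_rate
                and base.endswith(".")
                and heading[0].isalpha()
            )
            if fused:
                base = base[:-1]  # drop the final period: letter meets letter
            start = len(base)
            line = base + heading
            if rng.random() < 0.8:
                line += " " + _content_line(rng)
            lines[-1] = line
            marks.append((len(lines) - 1, start, start + len(heading)))
            prov.append({"heading": heading, "template": tmpl.normalized,
                         "variant": variant, "placement": "inline", "fused": fused})
        else:
            if rng.random() < config.novel_heading_rate:
                heading = NOVEL_HEADINGS[rng.integers(len(NOVEL_HEADINGS))]
                if rng.random() < 0.5:
                    heading += ":"
                template, variant = "<novel>", "novel"
            else:
                tmpl = config.heading_vocabulary[rng.integers(len(config.heading_vocabulary))]
                heading, variant = _render_heading(tmpl, rng, config)
                template = tmpl.normalized
            if lines:
                lines.append("")
            line = heading
            if rng.random() < 0.35:
                line += " " + _content_line(rng)
            lines.append(line)
            marks.append((len(lines) - 1, 0, len(heading)))
            prov.append({"heading": heading, "template": template,
                         "variant": variant, "placement": "paragraph", "fused": False})
        for _ in range(int(rng.integers(1, 4))):
            lines.append(_content_line(rng))

    raw = "\n".join(lines) + "\n"
    starts = []
    pos = 0
    for ln in lines:
        starts.append(pos)
        pos += len(ln) + 1
    gold = tuple(
        sorted(
            HeadingSpan(starts[i] + s, starts[i] + e, raw[starts[i] + s : starts[i] + e])
            for i, s, e in marks
        )
    )
    return SynthNote(Document.from_text(doc_id, raw), gold, tuple(prov))


def split_sizes(n_docs: int) -> tuple[int, int, int]:
    """Train/dev/test sizes at the 521/269/514 proportions, scaled."""
    total = sum(SPLIT_WEIGHTS)
    train = round(n_docs * SPLIT_WEIGHTS[0] / total)
    dev = round(n_docs * SPLIT_WEIGHTS[1] / total)
    return train, dev, n_docs - train - dev


def generate_corpus(config: SynthConfig) -> tuple[list[SynthNote], dict[str, list[str]]]:
    """Generate n_docs notes and partition their ids into train/dev/test."""
    rng = np.random.default_rng(config.seed)
    notes = [generate_note(config, rng, f"note{i:04d}") for i in range(config.n_docs)]
    n_train, n_dev, _ = split_sizes(config.n_docs)
    ids = [n.doc.doc_id for n in notes]
    splits = {
        "train": ids[:n_train],
        "dev": ids[n_train : n_train + n_dev],
        "test": ids[n_train + n_dev :],
    }
    return notes, splits


def write_corpus(
    notes: list[SynthNote],
    splits: dict[str, list[str]],
    outdir: str | Path,
    config: SynthConfig | None = None,
) -> Path:
    """Emit .txt/.ann pairs, the terminology TSV, and a JSON manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for note in notes:
        (out / f"{note.doc.doc_id}.txt").write_text(note.doc.raw_text, encoding="utf-8")
        (out / f"{note.doc.doc_id}.ann").write_text(
            write_brat(note.doc, list(note.gold)), encoding="utf-8"
        )
    (out / "lexicon.tsv").write_text(default_lexicon().to_tsv(), encoding="utf-8")
    manifest = {
        "n_docs": len(notes),
        "splits": splits,
        "config": None if config is None else {
            k: getattr(config, k)
            for k in ("n_docs", "mean_sections_per_doc", "inline_heading_rate",
                      "novel_heading_rate", "supplemental_insert_rate",
                      "tokenization_noise_rate", "seed")
        },
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return path


def read_corpus(
    corpus_dir: str | Path, split: str | None = None
) -> list[tuple[Document, list[HeadingSpan]]]:
    """Load .txt/.ann pairs back; restrict to one manifest split if named."""
    d = Path(corpus_dir)
    manifest_path = d / "manifest.json"
    if split is not None:
        manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
        try:
            ids = manifest["splits"][split]
        except KeyError:
            raise KeyError(f"manifest has no split {split!r}") from None
    else:
        ids = sorted(p.stem for p in d.glob("*.txt"))
    out = []
    for doc_id in ids:
        txt = (d / f"{doc_id}.txt").read_text(encoding="utf-8")
        ann_path = d / f"{doc_id}.ann"
        ann = ann_path.read_text(encoding="utf-8") if ann_path.exists() else ""
        doc, gold = read_brat(txt, ann, doc_id=doc_id)
        out.append((doc, gold))
    return out
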