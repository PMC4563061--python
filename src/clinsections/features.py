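"""Token features for the section-heading tagger.

Six families, each individually toggleable so ablations (notably dropping
the layout family) retrain cleanly:

* word      — normalized surface in a five-token window (w[-2]..w[+2])
* affix     — 2-character prefix and suffix, case preserved
* ortho     — ALLCAPS / CAPSMIX / INITCAP / PUNCTUATION writing-style flags
* lexicon   — substring match against a section-heading terminology, with the
              matched entry's hierarchy level, normalized concept, and a
              3-bit first/middle/last occurrence code per token
* semantic  — a per-line physician-marker flag ("M.D.", "Dr.", "PCP") that
              separates carbon-copy recipient lines from chief-complaint ones
* layout    — blank-line indicators over a window of surrounding lines

All features are presence-encoded: the feature *name* carries the value
("w[-1]=of", "ALLCAPS=1", "occ=001", "blank[-1]=1") and every emitted name
maps to 1.  A ``FeatureSet`` is therefore just a set of names.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path

from .textmodel import Document, Line, tokenize_text

FeatureSet = set[str]

_DIGIT_RUN_RE = re.compile(r"\d+")
_ALLCAPS_RE = re.compile(r"^[A-Z]+$")
_LETTERS_RE = re.compile(r"^[A-Za-z]+$")
_LOWER_UPPER_RE = re.compile(r"[a-z][A-Z]")
_UPPER_LOWER_RE = re.compile(r"[A-Z][a-z]")
# Physician-marker pattern: an "M.D."-like credential, a "Dr."-like title, or
# "PCP", searched anywhere in the line.
MD_LINE_RE = re.compile(r"M\s?\.?\s?D\s?\.?|Dr\s?\.?|PCP")

SENTINEL_LEFT = "<S>"
SENTINEL_RIGHT = "</S>"


def normalize_word(w: str) -> str:
    """Lowercase and collapse every maximal digit run to the single char "1"."""
    return _DIGIT_RUN_RE.sub("1", w.lower())


@dataclass(frozen=True)
class LexiconEntry:
    heading: str
    normalized: str
    level: int


@dataclass(frozen=True)
class Lexicon:
    """A section-heading terminology: surface strings with normalized concept
    names and hierarchy levels (level 1 = topmost)."""

    entries: tuple[LexiconEntry, ...]

    def __post_init__(self) -> None:
        for e in self.entries:
            if not e.heading:
                raise ValueError("lexicon headings must be non-empty")
            if e.level < 1:
                raise ValueError(f"lexicon level must be >= 1, got {e.level} for {e.heading!r}")

    @property
    def headings(self) -> list[str]:
        return [e.heading for e in self.entries]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Lexicon":
        """Load a 3-column TSV (heading, normalized, level); '#' comments allowed."""
        entries = []
        for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns")
            entries.append(LexiconEntry(parts[0], parts[1], int(parts[2])))
        return cls(tuple(entries))

    def to_tsv(self) -> str:
        header = "# heading\tnormalized\tlevel\n"
        return header + "".join(f"{e.heading}\t{e.normalized}\t{e.level}\n" for e in self.entries)


def build_occurrence_table(lexicon: Lexicon) -> dict[str, str]:
    """Per-token first/middle/last membership over all terminology headings.

    Each heading string is tokenized and normalized; a token is marked as
    occurring in first, middle and/or last position.  The 3-character code
    reads (last, middle, first): "001" = first-only, "100" = last-only,
    "101" = first and last.  A single-token heading marks its token as both
    first and last.  Tokens absent from every heading code "000" (handled by
    lookup default, not stored).
    """
    first: set[str] = set()
    middle: set[str] = set()
    last: set[str] = set()
    for entry in lexicon.entries:
        toks = [normalize_word(t.surface) for t in tokenize_text(entry.heading)]
        if not toks:
            continue
        first.add(toks[0])
        last.add(toks[-1])
        middle.update(toks[1:-1])
    table: dict[str, str] = {}
    for tok in first | middle | last:
        table[tok] = f"{int(tok in last)}{int(tok in middle)}{int(tok in first)}"
    return table


def occurrence_code(token_surface: str, occ: dict[str, str]) -> str:
    return occ.get(normalize_word(token_surface), "000")


@dataclass(frozen=True)
class FeatureConfig:
    """Which feature families to extract, plus their window sizes."""

    word: bool = True
    affix: bool = True
    ortho: bool = True
    lexicon: bool = True
    semantic: bool = True
    layout: bool = True
    word_window: int = 2  # tokens on each side, i.e. a 5-token content window
    layout_block: int = 6  # lines considered around the current one (even)

    def without(self, *families: str) -> "FeatureConfig":
        return replace(self, **{f: False for f in families})

    @classmethod
    def from_file(cls, path: str | Path) -> "FeatureConfig":
        """Load a flat key=value config ('#' comments; booleans true/false/1/0)."""
        bool_keys = {"word", "affix", "ortho", "lexicon", "semantic", "layout"}
        int_keys = {"word_window", "layout_block"}
        kwargs: dict = {}
        for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip().lower()
            if key in bool_keys:
                if value not in {"true", "false", "1", "0"}:
                    raise ValueError(f"{path}:{lineno}: {key} must be boolean, got {value!r}")
                kwargs[key] = value in {"true", "1"}
            elif key in int_keys:
                kwargs[key] = int(value)
            else:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
        return cls(**kwargs)


def word_features(surfaces: list[str], i: int, window: int = 2) -> FeatureSet:
    """Normalized words at offsets -window..+window; sequence edges emit sentinels."""
    feats: FeatureSet = set()
    for k in range(-window, window + 1):
        j = i + k
        if j < 0:
            val = SENTINEL_LEFT
        elif j >= len(surfaces):
            val = SENTINEL_RIGHT
        else:
            val = normalize_word(surfaces[j])
        name = f"w[{k:+d}]" if k else "w[0]"
        feats.add(f"{name}={val}")
    return feats


def affix_features(surface: str) -> FeatureSet:
    if len(surface) < 2:
        return {f"p2={surface}", f"s2={surface}"}
    return {f"p2={surface[:2]}", f"s2={surface[-2:]}"}


def orthographic_features(surface: str) -> FeatureSet:
    """Writing-style flags capturing capitalization and heading punctuation.

    CAPSMIX means mixed case *beyond* simple initial capitalization, so
    "SocHx" fires but "Date" does not.
    """
    allcaps = bool(_ALLCAPS_RE.match(surface))
    capsmix = bool(
        _LETTERS_RE.match(surface)
        and (_LOWER_UPPER_RE.search(surface) or _UPPER_LOWER_RE.search(surface[1:]))
    )
    initcap = bool(surface and "A" <= surface[0] <= "Z")
    punct = surface in (".", ":")
    return {
        f"ALLCAPS={int(allcaps)}",
        f"CAPSMIX={int(capsmix)}",
        f"INITCAP={int(initcap)}",
        f"PUNCTUATION={int(punct)}",
    }


def lexicon_features(surface: str, lexicon: Lexicon, occ: dict[str, str]) -> FeatureSet:
    """Terminology features for one token.

    The match flag is 1 iff the token surface is a case-insensitive substring
    of any heading string; the best match (longest heading, ties broken
    lexicographically) contributes its hierarchy level and normalized concept.
    The occurrence code is emitted unconditionally.
    """
    feats: FeatureSet = {f"occ={occurrence_code(surface, occ)}"}
    needle = surface.lower()
    best: LexiconEntry | None = None
    for entry in lexicon.entries:
        if needle in entry.heading.lower():
            if (
                best is None
                or len(entry.heading) > len(best.heading)
                or (len(entry.heading) == len(best.heading) and entry.heading < best.heading)
            ):
                best = entry
    if best is None:
        feats.add("lex=0")
    else:
        feats.add("lex=1")
        feats.add(f"lexlevel={best.level}")
        feats.add(f"lexnorm={best.normalized}")
    return feats


def semantic_feature(line: Line) -> int:
    """1 iff the line carries a physician marker (M.D. / Dr. / PCP)."""
    return int(bool(MD_LINE_RE.search(line.text)))


def layout_features(doc: Document, line_index: int, block: int = 6) -> FeatureSet:
    """Blank-line indicators for the block//2 lines before and after.

    ``blank[k]=1`` means the line at relative offset k exists and is blank;
    lines beyond the document edge count as not blank.
    """
    if block % 2:
        raise ValueError("layout block size must be even")
    half = block // 2
    feats: FeatureSet = set()
    for k in list(range(-half, 0)) + list(range(1, half + 1)):
        j = line_index + k
        blank = 0 <= j < len(doc.lines) and doc.lines[j].is_blank
        feats.add(f"blank[{k:+d}]={int(blank)}")
    return feats


def extract_line(
    doc: Document,
    line_index: int,
    lexicon: Lexicon | None,
    occ: dict[str, str] | None,
    config: FeatureConfig,
) -> list[FeatureSet]:
    """Feature sets for every token of one line."""
    tokens = doc.tokens_by_line[line_index]
    surfaces = [t.surface for t in tokens]
    line = doc.lines[line_index]
    shared: FeatureSet = set()
    if config.semantic:
        shared.add(f"mdline={semantic_feature(line)}")
    if config.layout:
        shared |= layout_features(doc, line_index, config.layout_block)
    out: list[FeatureSet] = []
    for i, tok in enumerate(tokens):
        feats: FeatureSet = set(shared)
        if config.word:
            feats |= word_features(surfaces, i, config.word_window)
        if config.affix:
            feats |= affix_features(tok.surface)
        if config.ortho:
            feats |= orthographic_features(tok.surface)
        if config.lexicon and lexicon is not None:
            feats |= lexicon_features(tok.surface, lexicon, occ if occ is not None else {})
        out.append(feats)
    return out


def extract_all(
    doc: Document,
    lexicon: Lexicon | None = None,
    occ: dict[str, str] | None = None,
    config: FeatureConfig = FeatureConfig(),
) -> list[list[FeatureSet]]:
    """Per-line, per-token feature sets for a whole document.

    Blank (token-less) lines yield empty lists so line indexing is preserved;
    extraction is a pure function of (doc, lexicon, config).
    """
    if config.lexicon and lexicon is not None and occ is None:
        occ = build_occurrence_table(lexicon)
    return [extract_line(doc, i, lexicon, occ, config) for i in range(len(doc.lines))]
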