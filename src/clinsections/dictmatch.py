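"""Dictionary-based section-heading recognizers (the two baselines).

Method 1 is greedy leftmost-longest maximum matching of an expanded heading
dictionary against each line, aligned to token boundaries.  Method 2 applies
the same matcher and then keeps only candidates that open a paragraph —
i.e. start at the first non-whitespace character of a line whose nearest
preceding line is blank (or which is the first non-blank line of the note).
Method 2's output is therefore always a subset of method 1's.

Term-variant expansion widens the dictionary's coverage: case variants, a
de-pluralized base form, stop-word-free variants, and every variant suffixed
with ":" or ".".
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .textmodel import Document, HeadingSpan, tokenize_text

#: Default stop words dropped by the expansion; overridable per call.
DEFAULT_STOP_WORDS = frozenset({"and", "of", "the", "for", "at", "on", "in"})


def _singularize(word: str) -> str:
    """Naive final-token de-pluralization: strip a trailing 's' unless 'ss'."""
    if len(word) > 1 and word.endswith("s") and not word.endswith("ss"):
        return word[:-1]
    return word


def _title_case(term: str) -> str:
    return " ".join(w[:1].upper() + w[1:].lower() for w in term.split(" "))


def _sentence_case(term: str) -> str:
    low = term.lower()
    return low[:1].upper() + low[1:]


def expand_term(term: str, stop_words: frozenset[str] | set[str] = DEFAULT_STOP_WORDS) -> set[str]:
    """All matching variants generated for one dictionary term.

    Case variants (original, Title Case, Sentence case, lowercase), the base
    form of each (final word singularized), stop-word-free variants of all of
    those, and finally every variant with ":" and "." attached.
    """
    if not term:
        raise ValueError("cannot expand an empty term")
    variants = {term, _title_case(term), _sentence_case(term), term.lower()}
    for v in list(variants):
        words = v.split(" ")
        variants.add(" ".join(words[:-1] + [_singularize(words[-1])]))
    for v in list(variants):
        kept = [w for w in v.split(" ") if w.lower() not in stop_words]
        if kept:
            variants.add(" ".join(kept))
    variants |= {v + ":" for v in variants} | {v + "." for v in variants}
    return variants


@dataclass(frozen=True)
class ExpandedDictionary:
    """Expanded surface forms, each linked back to its source term."""

    forms: dict[str, str]         # surface form -> source term
    max_form_tokens: int

    def __post_init__(self) -> None:
        if any(not f for f in self.forms):
            raise ValueError("expanded dictionary contains an empty form")

    @classmethod
    def from_terms(
        cls,
        terms: list[str],
        stop_words: frozenset[str] | set[str] = DEFAULT_STOP_WORDS,
    ) -> "ExpandedDictionary":
        forms: dict[str, str] = {}
        for term in terms:
            for v in expand_term(term, stop_words):
                forms.setdefault(v, term)
        max_tokens = max((len(tokenize_text(f)) for f in forms), default=0)
        return cls(forms, max_tokens)

    @classmethod
    def from_files(
        cls,
        paths: list[str | Path],
        stop_words: frozenset[str] | set[str] = DEFAULT_STOP_WORDS,
    ) -> "ExpandedDictionary":
        """Union of plain-text term files (one term per line, '#' comments)."""
        terms: list[str] = []
        for p in paths:
            for line in Path(p).read_text(encoding="utf-8").splitlines():
                line = line.strip()
                if line and not line.startswith("#"):
                    terms.append(line)
        return cls.from_terms(terms, stop_words)

    def __contains__(self, form: str) -> bool:
        return form in self.forms

    def __len__(self) -> int:
        return len(self.forms)


def max_match(doc: Document, dictionary: ExpandedDictionary) -> list[HeadingSpan]:
    """Method 1: leftmost-longest dictionary matching, per line.

    At every token-start position the longest token-boundary-aligned slice
    that exactly equals an expanded form is emitted; scanning resumes after
    it, so emitted spans never overlap.
    """
    spans: list[HeadingSpan] = []
    for toks in doc.tokens_by_line:
        i = 0
        n = len(toks)
        while i < n:
            matched = False
            for j in range(min(i + dictionary.max_form_tokens, n) - 1, i - 1, -1):
                cand = doc.raw_text[toks[i].start : toks[j].end]
                if cand in dictionary:
                    spans.append(HeadingSpan(toks[i].start, toks[j].end, cand))
                    i = j + 1
                    matched = True
                    break
            if not matched:
                i += 1
    return spans


def paragraph_initial_lines(doc: Document) -> set[int]:
    """Line indices that open a paragraph: the first non-blank line of the
    note, or any non-blank line immediately preceded by a blank one."""
    out: set[int] = set()
    seen_nonblank = False
    for ln in doc.lines:
        if ln.is_blank:
            continue
        if not seen_nonblank or doc.lines[ln.index - 1].is_blank:
            out.add(ln.index)
        seen_nonblank = True
    return out


def filter_paragraph_initial(spans: list[HeadingSpan], doc: Document) -> list[HeadingSpan]:
    """Method 2's filter: keep only candidates that open a paragraph."""
    initial = paragraph_initial_lines(doc)
    kept: list[HeadingSpan] = []
    for span in spans:
        for idx in initial:
            line = doc.lines[idx]
            first_char = line.start + (len(line.text) - len(line.text.lstrip()))
            if span.start == first_char:
                kept.append(span)
                break
    return kept
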