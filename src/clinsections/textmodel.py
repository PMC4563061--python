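"""Document representation for clinical notes.

A note is plain text whose physical line structure is meaningful: section
headings in discharge summaries are anchored to lines, and blank lines mark
paragraph boundaries that both the layout features and the paragraph-initial
dictionary filter rely on.  Everything here therefore preserves the original
line breaks and works in 0-based, half-open character offsets into the raw
text — the same convention the brat standoff format uses.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from functools import cached_property

logger = logging.getLogger(__name__)

# Maximal alphabetic runs, maximal digit runs, or a single non-space symbol.
# Whitespace is consumed and never emitted as a token.
_TOKEN_RE = re.compile(r"[^\W\d_]+|\d+|[^\w\s]|_")

# A line body followed by its terminator; \n, \r\n and bare \r all accepted.
_LINE_RE = re.compile(r"([^\r\n]*)(\r\n|\r|\n)|([^\r\n]+)$")


class BratParseError(ValueError):
    """A .ann line does not follow the brat text-bound format."""


class BratIntegrityError(ValueError):
    """A .ann span's recorded text disagrees with the .txt contents."""


class AlignmentError(ValueError):
    """A gold span covers no token (tokenization/annotation mismatch)."""


@dataclass(frozen=True)
class Line:
    """One physical line: ``text == raw_text[start:end]`` (terminator excluded)."""

    index: int
    start: int
    end: int
    text: str

    @property
    def is_blank(self) -> bool:
        return not self.text.strip()


@dataclass(frozen=True)
class Token:
    surface: str
    line_index: int
    start: int
    end: int


@dataclass(frozen=True, order=True)
class HeadingSpan:
    """A gold or predicted section-heading chunk as a character interval."""

    start: int
    end: int
    text: str = field(compare=False, default="")

    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


#: IOB2 tags: B opens every heading chunk, I continues it, O is outside.
IOB_TAGS = ("B", "I", "O")


def split_lines(raw_text: str) -> list[Line]:
    """Split text into physical lines with exact character offsets.

    Every line is returned, including blank ones; terminators (``\\n``,
    ``\\r\\n``, ``\\r``) are excluded from the line text but accounted for in
    the offsets, so concatenating line texts with their original terminators
    reconstructs the input exactly.
    """
    lines: list[Line] = []
    for m in _LINE_RE.finditer(raw_text):
        body = m.group(1) if m.group(2) is not None else m.group(3)
        start = m.start()
        lines.append(Line(index=len(lines), start=start, end=start + len(body), text=body))
    return lines


def tokenize_text(text: str, offset: int = 0, line_index: int = 0) -> list[Token]:
    """Tokenize a string into alphabetic runs, digit runs and single symbols."""
    return [
        Token(surface=m.group(), line_index=line_index, start=offset + m.start(), end=offset + m.end())
        for m in _TOKEN_RE.finditer(text)
    ]


def tokenize_line(line: Line, raw_text: str) -> list[Token]:
    """Deterministic tokenization of one line; offsets index into ``raw_text``."""
    if raw_text[line.start : line.end] != line.text:
        raise ValueError(f"line {line.index} offsets disagree with raw_text")
    return tokenize_text(line.text, offset=line.start, line_index=line.index)


@dataclass(frozen=True)
class Document:
    doc_id: str
    raw_text: str
    lines: tuple[Line, ...]

    @classmethod
    def from_text(cls, doc_id: str, raw_text: str) -> "Document":
        return cls(doc_id=doc_id, raw_text=raw_text, lines=tuple(split_lines(raw_text)))

    @cached_property
    def tokens_by_line(self) -> tuple[tuple[Token, ...], ...]:
        return tuple(tuple(tokenize_line(ln, self.raw_text)) for ln in self.lines)

    @cached_property
    def tokens(self) -> tuple[Token, ...]:
        return tuple(t for toks in self.tokens_by_line for t in toks)

    def span_text(self, start: int, end: int) -> str:
        return self.raw_text[start:end]


def align_annotations(
    tokens: list[Token] | tuple[Token, ...],
    gold: list[HeadingSpan],
    lenient: bool = False,
) -> list[str]:
    """Project gold heading spans onto tokens as IOB2 tags.

    A token whose start offset equals a span's start gets B; a token whose
    start falls strictly inside a span gets I; everything else O.  Assigning
    by the token's *start* offset keeps the mapping total when a span boundary
    cuts through a token (a tokenization-noise case).  A span covering no
    token raises :class:`AlignmentError`, or is logged and skipped when
    ``lenient`` is true.
    """
    tags = ["O"] * len(tokens)
    for span in sorted(gold):
        covered = [i for i, t in enumerate(tokens) if span.start <= t.start < span.end]
        if not covered:
            if lenient:
                logger.warning("gold span %d:%d covers no token; skipped", span.start, span.end)
                continue
            raise AlignmentError(f"gold span {span.start}:{span.end} ({span.text!r}) covers no token")
        for k, i in enumerate(covered):
            tags[i] = "B" if k == 0 and tokens[i].start == span.start else "I"
        # Span starting mid-token: the first covered token still opens the chunk.
        if tokens[covered[0]].start != span.start:
            tags[covered[0]] = "B"
    return tags


def decode_iob(tokens: list[Token] | tuple[Token, ...], tags: list[str], raw_text: str = "") -> list[HeadingSpan]:
    """Inverse of :func:`align_annotations`: maximal ``B I*`` runs become spans.

    An orphan I (after O or at sequence start) is repaired as B, the standard
    chunking convention, so decoding is total over any tag sequence a decoder
    may emit.
    """
    if len(tokens) != len(tags):
        raise ValueError("tokens and tags must have equal length")
    spans: list[HeadingSpan] = []
    run_start: int | None = None
    run_end = 0
    for tok, tag in zip(tokens, tags):
        if tag == "O":
            if run_start is not None:
                spans.append(HeadingSpan(run_start, run_end, raw_text[run_start:run_end]))
                run_start = None
        elif tag == "B" or run_start is None:  # orphan I repaired as B
            if run_start is not None:
                spans.append(HeadingSpan(run_start, run_end, raw_text[run_start:run_end]))
            run_start, run_end = tok.start, tok.end
        else:
            run_end = tok.end
    if run_start is not None:
        spans.append(HeadingSpan(run_start, run_end, raw_text[run_start:run_end]))
    return spans


def align_document(doc: Document, gold: list[HeadingSpan], lenient: bool = False) -> list[list[str]]:
    """Per-line IOB tag lists for a whole document.

    Alignment runs over the document's full token stream so that span-coverage
    errors are judged globally, then the tags are split back per line (the CRF
    labels one line at a time).
    """
    flat = align_annotations(doc.tokens, gold, lenient=lenient)
    out: list[list[str]] = []
    i = 0
    for toks in doc.tokens_by_line:
        out.append(flat[i : i + len(toks)])
        i += len(toks)
    return out


# ---------------------------------------------------------------------------
# brat standoff I/O (single annotation type "SectionHeading")

_ANN_TYPE = "SectionHeading"
_BRAT_LINE_RE = re.compile(r"^(T\d+)\t(\S+) (\d+) (\d+)\t(.*)$")


def read_brat(txt: str, ann: str, doc_id: str = "doc") -> tuple[Document, list[HeadingSpan]]:
    """Parse a .txt/.ann pair into a document plus gold heading spans.

    Only text-bound annotations are supported; discontinuous spans
    (``;``-separated offset fragments) are rejected.  Each span's recorded
    text is cross-checked against the raw text (brat flattens newlines to
    spaces in the text column, which is honoured in the comparison).
    """
    doc = Document.from_text(doc_id, txt)
    spans: list[HeadingSpan] = []
    for lineno, raw in enumerate(ann.splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.split("\t")
        if len(fields) >= 2 and ";" in fields[1]:
            raise BratParseError(f"line {lineno}: discontinuous spans are not supported")
        m = _BRAT_LINE_RE.match(raw)
        if not m:
            raise BratParseError(f"line {lineno}: not a text-bound annotation: {raw!r}")
        tid, _atype, s, e, text = m.group(1), m.group(2), int(m.group(3)), int(m.group(4)), m.group(5)
        if not (0 <= s < e <= len(txt)):
            raise BratIntegrityError(f"annotation {tid}: offsets {s}:{e} out of bounds")
        actual = txt[s:e]
        if actual.replace("\n", " ").replace("\r", " ") != text:
            raise BratIntegrityError(
                f"annotation {tid}: text mismatch, .ann has {text!r} but .txt has {actual!r}"
            )
        spans.append(HeadingSpan(s, e, actual))
    return doc, sorted(spans)


def write_brat(doc: Document, spans: list[HeadingSpan]) -> str:
    """Serialize spans as brat text-bound annotations; inverse of :func:`read_brat`."""
    out = []
    for i, span in enumerate(sorted(spans), start=1):
        if not (0 <= span.start < span.end <= len(doc.raw_text)):
            raise ValueError(f"span {span.start}:{span.end} out of document bounds")
        text = doc.raw_text[span.start : span.end].replace("\n", " ").replace("\r", " ")
        out.append(f"T{i}\t{_ANN_TYPE} {span.start} {span.end}\t{text}")
    return "\n".join(out) + ("\n" if out else "")


def strip_blank_lines(raw_text: str, spans: list[HeadingSpan]) -> tuple[str, list[HeadingSpan]]:
    """Remove blank lines and remap span offsets (the no-layout scenario).

    Emulates clinical text delivered without its visual paragraph structure:
    every blank line is deleted and the remaining lines rejoined with ``\\n``.
    """
    lines = split_lines(raw_text)
    kept = [ln for ln in lines if not ln.is_blank]
    new_text = "\n".join(ln.text for ln in kept)
    # Offset map: for each kept line, its old start -> new start.
    new_spans: list[HeadingSpan] = []
    pos = 0
    shifts: list[tuple[int, int, int]] = []  # (old_start, old_end, new_start)
    for ln in kept:
        shifts.append((ln.start, ln.end, pos))
        pos += len(ln.text) + 1
    for span in spans:
        for old_s, old_e, new_s in shifts:
            if old_s <= span.start and span.end <= old_e:
                ns = new_s + (span.start - old_s)
                ne = ns + (span.end - span.start)
                new_spans.append(HeadingSpan(ns, ne, new_text[ns:ne]))
                break
        # Spans crossing a line boundary (none are produced by this package)
        # are dropped silently: they no longer denote a contiguous region.
    return new_text, sorted(new_spans)
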