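"""Line/token segmentation, IOB alignment, and brat standoff round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clinsections import (
    AlignmentError,
    BratIntegrityError,
    BratParseError,
    Document,
    HeadingSpan,
    align_annotations,
    decode_iob,
    read_brat,
    split_lines,
    strip_blank_lines,
    tokenize_line,
    write_brat,
)
from conftest import span_over


class TestSplitLines:
    def test_blank_lines_are_kept(self):
        lines = split_lines("A\n\nB")
        assert [(l.text, l.is_blank) for l in lines] == [("A", False), ("", True), ("B", False)]

    def test_empty_input(self):
        assert split_lines("") == []

    @pytest.mark.parametrize("text", ["a\r\nb\rc\nd", "x\n", "\n\n", "no newline", "\r\n"])
    def test_reconstruction_and_offsets(self, text):
        lines = split_lines(text)
        for ln in lines:
            assert text[ln.start : ln.end] == ln.text
        rebuilt = "".join(
            text[ln.start : lines[i + 1].start] if i + 1 < len(lines) else text[ln.start :]
            for i, ln in enumerate(lines)
        )
        assert rebuilt == text

    @settings(derandomize=True, max_examples=200)
    @given(st.text(alphabet=st.sampled_from("ab \n\r\t:"), max_size=40))
    def test_reconstruction_property(self, text):
        lines = split_lines(text)
        assert all(text[l.start : l.end] == l.text for l in lines)
        # line intervals are ordered and disjoint
        for a, b in zip(lines, lines[1:]):
            assert a.end <= b.start

    def test_sample_note_blank_context(self, sample_doc):
        """The header block has no blank line before "Name:", but the chief
        complaint line follows a blank separator."""
        by_text = {l.text.split(":")[0]: l.index for l in sample_doc.lines if ":" in l.text}
        assert not sample_doc.lines[by_text["Name"] - 1].is_blank
        assert sample_doc.lines[by_text["CC"] - 1].is_blank


class TestTokenize:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("Date of Admission: 7/2/88", ["Date", "of", "Admission", ":", "7", "/", "2", "/", "88"]),
            ("FHx:", ["FHx", ":"]),
            ("Meds (Updated 7/20)", ["Meds", "(", "Updated", "7", "/", "20", ")"]),
            ("", []),
            ("   ", []),
        ],
    )
    def test_rule_tokenizer(self, text, expected):
        doc = Document.from_text("d", text)
        surfaces = [t.surface for t in doc.tokens]
        assert surfaces == expected

    def test_offsets_are_exact(self, sample_doc):
        for tok in sample_doc.tokens:
            assert sample_doc.raw_text[tok.start : tok.end] == tok.surface
            assert tok.surface and not tok.surface.isspace()

    def test_no_token_crosses_a_line(self, sample_doc):
        for line, toks in zip(sample_doc.lines, sample_doc.tokens_by_line):
            for t in toks:
                assert line.start <= t.start < t.end <= line.end

    def test_tokenize_line_checks_offsets(self):
        doc = Document.from_text("d", "ab\ncd")
        from clinsections.textmodel import Line

        with pytest.raises(ValueError):
            tokenize_line(Line(index=0, start=0, end=2, text="xx"), doc.raw_text)


class TestIob:
    def test_worked_example(self):
        doc = Document.from_text("d", "Date of Admission: 7/2/88")
        gold = [span_over(doc, "Date of Admission:")]
        tags = align_annotations(list(doc.tokens), gold)
        assert tags == ["B", "I", "I", "I", "O", "O", "O", "O", "O"]
        assert decode_iob(list(doc.tokens), tags, doc.raw_text) == gold

    def test_no_gold_gives_all_o(self, sample_doc):
        assert set(align_annotations(list(sample_doc.tokens), [])) == {"O"}

    def test_adjacent_spans_each_start_with_b(self):
        doc = Document.from_text("d", "PMH:\nCAD:")
        gold = [span_over(doc, "PMH:"), span_over(doc, "CAD:")]
        tags = align_annotations(list(doc.tokens), gold)
        assert tags == ["B", "I", "B", "I"]

    def test_span_covering_no_token_raises(self):
        doc = Document.from_text("d", "abc def")
        # span strictly inside the first token: no token *starts* in it
        with pytest.raises(AlignmentError):
            align_annotations(list(doc.tokens), [HeadingSpan(1, 3, "bc")])
        assert align_annotations(list(doc.tokens), [HeadingSpan(1, 3, "bc")], lenient=True) == [
            "O",
            "O",
        ]

    def test_mid_token_span_start_still_opens_chunk(self):
        # tokenization-noise case: the span starts inside a merged token
        doc = Document.from_text("d", "monitorHabits Tobacco")
        toks = list(doc.tokens)
        s = doc.raw_text.index("Habits")
        span = HeadingSpan(s, len(doc.raw_text), "Habits Tobacco")
        # the first token the span covers does not start it; B is still assigned
        assert align_annotations(toks, [span]) == ["O", "B"]
        # a span wholly inside the merged token covers no token start at all
        with pytest.raises(AlignmentError):
            align_annotations(toks, [HeadingSpan(s, s + len("Habits"), "Habits")])

    def test_orphan_i_is_repaired(self):
        doc = Document.from_text("d", "a b c")
        toks = list(doc.tokens)
        spans = decode_iob(toks, ["O", "I", "I"], doc.raw_text)
        assert spans == [HeadingSpan(2, 5, "b c")]
        assert decode_iob(toks, ["I", "O", "I"], doc.raw_text) == [
            HeadingSpan(0, 1, "a"),
            HeadingSpan(4, 5, "c"),
        ]

    def test_align_decode_identity_on_random_token_aligned_spans(self):
        rng = np.random.default_rng(0)
        doc = Document.from_text("d", "Date of Admission: 7/2/88 CC: dizzy vertigo nausea")
        toks = list(doc.tokens)
        for _ in range(200):
            n_spans = rng.integers(0, 4)
            cut = sorted(rng.choice(len(toks), size=2 * n_spans, replace=False)) if n_spans else []
            spans = []
            for a, b in zip(cut[::2], cut[1::2]):
                spans.append(HeadingSpan(toks[a].start, toks[b].end,
                                         doc.raw_text[toks[a].start : toks[b].end]))
            tags = align_annotations(toks, spans)
            assert decode_iob(toks, tags, doc.raw_text) == sorted(spans)


class TestBrat:
    def test_basic_parse(self):
        txt = "Date of Admission: 7/2/88"
        ann = "T1\tSectionHeading 0 18\tDate of Admission:\n"
        doc, spans = read_brat(txt, ann)
        assert spans == [HeadingSpan(0, 18, "Date of Admission:")]

    def test_empty_ann(self):
        doc, spans = read_brat("abc", "")
        assert spans == [] and doc.raw_text == "abc"

    def test_text_mismatch_names_annotation(self):
        with pytest.raises(BratIntegrityError, match="T7"):
            read_brat("abcdef", "T7\tSectionHeading 0 3\txyz\n")

    def test_malformed_line_reports_line_number(self):
        with pytest.raises(BratParseError, match="line 2"):
            read_brat("abcdef", "T1\tSectionHeading 0 3\tabc\nnot-a-brat-line\n")

    def test_discontinuous_span_rejected(self):
        with pytest.raises(BratParseError, match="discontinuous"):
            read_brat("abcdef", "T1\tSectionHeading 0 2;4 6\tab ef\n")

    def test_out_of_bounds_write_raises(self):
        doc = Document.from_text("d", "abc")
        with pytest.raises(ValueError):
            write_brat(doc, [HeadingSpan(0, 10, "abc")])

    def test_round_trip_random(self):
        rng = np.random.default_rng(1)
        alphabet = "ab :\n"
        for _ in range(300):
            text = "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=30))
            if not text.strip():
                continue
            doc = Document.from_text("d", text)
            cuts = sorted(set(rng.integers(0, len(text) + 1, size=6)))
            spans = [
                HeadingSpan(a, b, text[a:b]) for a, b in zip(cuts[::2], cuts[1::2]) if a < b
            ]
            doc2, spans2 = read_brat(text, write_brat(doc, spans))
            assert doc2.raw_text == doc.raw_text
            assert [s.interval() for s in spans2] == [s.interval() for s in sorted(spans)]


class TestStripBlankLines:
    def test_blank_lines_removed_and_spans_remapped(self, sample_doc):
        gold = [span_over(sample_doc, "CC:"), span_over(sample_doc, "FHx:")]
        text, spans = strip_blank_lines(sample_doc.raw_text, gold)
        assert "\n\n" not in text
        assert [s.text for s in spans] == ["CC:", "FHx:"]
        for s in spans:
            assert text[s.start : s.end] == s.text

    def test_no_blank_lines_is_identity_modulo_endings(self):
        text, spans = strip_blank_lines("a\nb\nc", [HeadingSpan(2, 3, "b")])
        assert text == "a\nb\nc"
        assert spans == [HeadingSpan(2, 3, "b")]
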