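"""Shared fixtures: a synthetic sample discharge summary and a tiny lexicon.

The sample note is a hand-written synthetic stand-in reproducing the layout
conventions of a de-identified discharge summary: header lines without blank
separation, blank lines before most sections, a heading with a parenthetical
supplement, and abbreviation headings (CC, HPI, ROS, PMH, FHx, SocHx, PE,
ALL).  No real patient data.
"""

import pytest

from clinsections import Document, HeadingSpan, Lexicon, LexiconEntry

SAMPLE_NOTE = """\
Record date: 2088-07-03
Name: Younger, T Eugene
Date of Admission: 7/2/88

CC: Lightheadedness, vertigo, and presyncopal sx several episodes

HPI: 64 yoM w/significant PMH for CAD, HTN, GERD presents w/6 hour history of vertiginous symptoms. The pt recalls feeling dizzy.

ROS: +tinnitus, -weakness/change in sensation, ataxia

PMH:
CAD: 2075 PTCA w/Angioplasty to LAD, Cath (5/88): 3v disease

Meds (Updated 7/20)
Atenolol 25/50 mg qAM/qPM
ASA 325 mg qD
ALL: NKDA, Intolerance to Inderal

FHx:
+HTN: mother/brother
SocHx: Lives by himself separated.

PE:
VS:
Gen: Well-nourished male, NAD

LABS:
Sodium 140 135-145 mmol/L
EKG: Sinus brady @ 60

Impression: 64 yo male w/significant CAD presents w/sx
Plan:
(1) Vertigo: fall precautions
Betty Kaitlin Wood, MD
"""


@pytest.fixture(scope="session")
def sample_doc() -> Document:
    return Document.from_text("sample", SAMPLE_NOTE)


def line_index_of(doc: Document, prefix: str) -> int:
    for ln in doc.lines:
        if ln.text.startswith(prefix):
            return ln.index
    raise AssertionError(f"no line starts with {prefix!r}")


def span_over(doc: Document, text: str) -> HeadingSpan:
    start = doc.raw_text.index(text)
    return HeadingSpan(start, start + len(text), text)


# A 12-entry lexicon whose tokens jointly realize all eight occurrence codes
# (first/middle/last membership is hand-derivable; see test_features).
TINY_LEXICON_ENTRIES = [
    ("family history", "family_history", 1),
    ("social history", "social_history", 1),
    ("review of systems", "review_of_systems", 1),
    ("date of admission", "date_of_admission", 1),
    ("medical history", "medical_history", 1),
    ("past medical history", "past_medical_history", 1),
    ("chief complaint", "chief_complaint", 1),
    ("patient complaint history", "patient_complaint_history", 2),
    ("data", "data", 1),
    ("exam findings", "exam_findings", 2),
    ("physical exam", "physical_exam", 1),
    ("physical exam findings", "physical_exam_findings", 2),
]


@pytest.fixture(scope="session")
def tiny_lexicon() -> Lexicon:
    return Lexicon(tuple(LexiconEntry(h, n, l) for h, n, l in TINY_LEXICON_ENTRIES))
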