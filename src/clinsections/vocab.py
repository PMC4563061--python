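"""Section-heading vocabulary and filler text for the synthetic generator.

The vocabulary covers the section categories found in discharge summaries —
chief complaint, present illness, the personal/family history group,
physical exam, laboratory and radiology data, impression/plan, and the large
"other" tail of administrative labels — plus the short abbreviations that
clinicians actually write (CC, HPI, ROS, PMH, FHx, SocHx, PE, ALL).  A small
separate pool of vocabulary-external headings ("novel" headings) lets the
generator emit sections that no dictionary or training set has seen, which
is what the layout features are supposed to rescue.
"""

from __future__ import annotations

from dataclasses import dataclass

from .features import Lexicon, LexiconEntry


@dataclass(frozen=True)
class HeadingTemplate:
    canonical: str               # Title-case canonical surface
    normalized: str              # concept id, lowercase_underscored
    level: int                   # hierarchy level, 1 = topmost
    abbreviations: tuple[str, ...] = ()


VOCABULARY: tuple[HeadingTemplate, ...] = tuple(
    HeadingTemplate(c, n, l, tuple(a))
    for c, n, l, a in [
        ("Chief Complaint", "chief_complaint", 1, ["CC"]),
        ("History of Present Illness", "present_illness", 1, ["HPI"]),
        ("Past Medical History", "past_medical_history", 1, ["PMH"]),
        ("Past Surgical History", "past_surgical_history", 1, ["PSurHx"]),
        ("Family History", "family_history", 1, ["FHx"]),
        ("Social History", "social_history", 1, ["SocHx"]),
        ("Review of Systems", "review_of_systems", 1, ["ROS"]),
        ("Physical Examination", "physical_examination", 1, ["PE"]),
        ("Allergies", "allergies", 1, ["ALL"]),
        ("Medications", "medications", 1, ["Meds"]),
        ("Discharge Medications", "discharge_medications", 1, []),
        ("Admission Medications", "admission_medications", 1, []),
        ("Laboratory Examinations", "laboratory_examinations", 1, ["LABS"]),
        ("Laboratory Data", "laboratory_data", 1, []),
        ("Radiology Reports", "radiology_reports", 1, []),
        ("Imaging", "imaging", 1, []),
        ("Impression", "impression", 1, []),
        ("Assessment and Plan", "assessment_and_plan", 1, []),
        ("Plan", "plan", 1, []),
        ("Recommendations", "recommendations", 1, []),
        ("Hospital Course", "hospital_course", 1, []),
        ("Diagnosis", "diagnosis", 1, []),
        ("Discharge Diagnosis", "discharge_diagnosis", 1, []),
        ("Admission Diagnosis", "admission_diagnosis", 1, []),
        ("Vital Signs", "vital_signs", 2, ["VS"]),
        ("Habits", "habits", 1, []),
        ("Tobacco Use", "tobacco_use", 2, []),
        ("Alcohol Use", "alcohol_use", 2, []),
        ("Immunizations", "immunizations", 1, []),
        ("Problem List", "problem_list", 1, []),
        ("Reason for Encounter", "chief_complaint", 1, []),
        ("Presenting Complaints", "chief_complaint", 1, []),
        ("Presenting Problems", "chief_complaint", 1, []),
        ("Date of Admission", "date_of_admission", 1, []),
        ("Date of Discharge", "date_of_discharge", 1, []),
        ("Record Date", "record_date", 1, []),
        ("Name", "patient_name", 1, []),
        ("Attending Physician", "attending_physician", 1, []),
        ("Primary Care Physician", "primary_care_physician", 1, ["PCP"]),
        ("Data", "data", 1, []),
        ("EKG", "ekg", 2, []),
        ("Chest X-ray", "chest_xray", 2, ["CXR"]),
        ("Microbiology", "microbiology", 1, []),
        ("Pathology", "pathology", 1, []),
        ("Consultations", "consultations", 1, []),
        ("Procedures", "procedures", 1, []),
        ("Operative Note", "operative_note", 1, []),
        ("Disposition", "disposition", 1, []),
        ("Follow Up", "follow_up", 1, []),
        ("Diet", "diet", 2, []),
        ("Activity", "activity", 2, []),
        ("Code Status", "code_status", 1, []),
        ("Neurological Examination", "neurological_examination", 2, []),
        ("Cardiac Examination", "cardiac_examination", 2, []),
        ("Discharge Instructions", "discharge_instructions", 1, []),
        ("Condition at Discharge", "condition_at_discharge", 1, []),
        ("Substance Use", "substance_use", 2, []),
        ("Marital Status", "marital_status", 2, []),
        ("Identification", "identification", 1, ["ID"]),
        ("Hospital Name", "hospital_name", 1, []),
    ]
)

#: Headings kept out of the terminology and the training vocabulary; the
#: generator places them with clear paragraph layout so only layout-aware
#: models have a handle on them.
NOVEL_HEADINGS: tuple[str, ...] = (
    "HCP/FAMILY CONTACT",
    "INDICATIONS FOR TPN",
    "Allergies or adverse reactions",
    "Course on floor",
    "Oncology CONSULTATION NOTE",
)


def default_lexicon() -> Lexicon:
    """Terminology built from the vocabulary: canonical surfaces and their
    abbreviations, each carrying the normalized concept and hierarchy level."""
    entries: list[LexiconEntry] = []
    seen: set[str] = set()
    for t in VOCABULARY:
        for surface in (t.canonical, *t.abbreviations):
            if surface not in seen:
                seen.add(surface)
                entries.append(LexiconEntry(surface, t.normalized, t.level))
    return Lexicon(tuple(entries))


# Filler vocabulary for pseudo-clinical content lines.  Deliberately includes
# words that collide with single-word heading terms ("data", "plan", "diet",
# "habits") so dictionary matching shows its real precision behaviour.
CONTENT_WORDS: tuple[str, ...] = (
    "patient", "denies", "reports", "mild", "severe", "intermittent", "chronic",
    "dizziness", "nausea", "vomiting", "fever", "chills", "cough", "dyspnea",
    "chest", "pain", "palpitations", "edema", "fatigue", "headache", "vertigo",
    "stable", "improved", "unchanged", "resolved", "continue", "monitor",
    "daily", "twice", "oral", "tablet", "capsule", "dose", "data", "plan",
    "diet", "habits", "states", "without", "with", "history", "significant",
    "negative", "positive", "bilateral", "lungs", "clear", "auscultation",
    "abdomen", "soft", "nontender", "alert", "oriented", "afebrile",
)

MEDICATION_WORDS: tuple[str, ...] = (
    "atenolol", "lisinopril", "metformin", "aspirin", "simvastatin",
    "omeprazole", "furosemide", "warfarin", "insulin", "albuterol",
)
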