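import datetime as dt

import pytest

from adhf_phenotype import (
    ClinicalNote,
    MatchOptions,
    NoteSection,
    TermDictionary,
    segment_note,
)

SCOPED = frozenset(
    {"principal_diagnosis", "secondary_diagnoses", "chief_complaint",
     "brief_hospital_course"}
)


def make_note(text: str, note_id: str = "N1", admission_id: str = "A1",
              hour: int = 8) -> ClinicalNote:
    """Build a ClinicalNote from raw text using the default segmenter."""
    return ClinicalNote(
        note_id=note_id,
        admission_id=admission_id,
        timestamp=dt.datetime(2010, 6, 1, hour),
        raw_text=text,
        sections=tuple(segment_note(text)),
    )


def make_section(text: str, name: str = "principal_diagnosis") -> NoteSection:
    return NoteSection(name=name, text=text, start_offset=0, end_offset=len(text))


@pytest.fixture
def basic_dictionary() -> TermDictionary:
    """Small fully-known dictionary used wherever exactness matters."""
    return TermDictionary(
        inclusion_terms=("acute decompensated heart failure", "adhf", "acute chf"),
        exclusion_terms=("prior", "rule out", "negative for"),
        scoped_sections=SCOPED,
        match_options=MatchOptions(),
    )
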