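"""Domain records for an admission-level EHR corpus.

The unit of analysis throughout the package is the *hospital admission*:
clinical notes attach to admissions, ICD-9 diagnosis codes are billed per
admission, and the reference standard labels admissions as acute
decompensated heart failure (ADHF) yes/no.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field
from enum import Enum

__all__ = [
    "Patient",
    "HospitalAdmission",
    "NoteSection",
    "ClinicalNote",
    "ReferenceLabel",
    "LabelSource",
    "CohortFlow",
    "ICD9_CODE_RE",
    "is_valid_icd9",
]

# ICD-9-CM diagnosis code shapes: 3 digits, or V + 2 digits, or E + 3 digits,
# each optionally followed by a decimal point and 1-2 further digits.
ICD9_CODE_RE = re.compile(r"^(?:\d{3}|V\d{2}|E\d{3})(?:\.\d{1,2})?$")


def is_valid_icd9(code: str) -> bool:
    """True if ``code`` has the syntactic shape of an ICD-9-CM diagnosis code."""
    return bool(ICD9_CODE_RE.match(code.strip().upper()))


@dataclass(frozen=True)
class Patient:
    """A patient with the two attributes the eligibility flow needs."""

    patient_id: str
    birth_date: _dt.date
    research_authorization: bool = True

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be a non-empty string")

    def age_at(self, reference: _dt.date) -> int:
        """Age in completed years at ``reference``."""
        years = reference.year - self.birth_date.year
        if (reference.month, reference.day) < (self.birth_date.month, self.birth_date.day):
            years -= 1
        return years


@dataclass(frozen=True)
class HospitalAdmission:
    """One hospital stay and its billed ICD-9 diagnosis codes."""

    admission_id: str
    patient_id: str
    admit_date: _dt.date
    discharge_date: _dt.date
    icd9_codes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.admission_id:
            raise ValueError("admission_id must be a non-empty string")
        if self.admit_date > self.discharge_date:
            raise ValueError(
                f"admission {self.admission_id!r}: admit_date {self.admit_date} "
                f"is after discharge_date {self.discharge_date}"
            )
        object.__setattr__(self, "icd9_codes", tuple(self.icd9_codes))
        for code in self.icd9_codes:
            if not is_valid_icd9(code):
                raise ValueError(
                    f"admission {self.admission_id!r}: {code!r} is not a valid ICD-9 code"
                )


@dataclass(frozen=True)
class NoteSection:
    """A named span of a clinical note.

    Offsets are 0-based, half-open character positions into the parent note's
    ``raw_text``. ``text`` always equals ``raw_text[start_offset:end_offset]``.
    """

    name: str
    text: str
    start_offset: int
    end_offset: int

    def __post_init__(self) -> None:
        if not (0 <= self.start_offset <= self.end_offset):
            raise ValueError(
                f"section {self.name!r}: invalid offsets "
                f"[{self.start_offset}, {self.end_offset})"
            )
        if len(self.text) != self.end_offset - self.start_offset:
            raise ValueError(
                f"section {self.name!r}: text length {len(self.text)} does not match "
                f"span [{self.start_offset}, {self.end_offset})"
            )


@dataclass(frozen=True)
class ClinicalNote:
    """A timestamped clinical note split into named sections."""

    note_id: str
    admission_id: str
    timestamp: _dt.datetime
    raw_text: str
    sections: tuple[NoteSection, ...] = ()
    patient_id: str | None = None

    def __post_init__(self) -> None:
        if not self.note_id:
            raise ValueError("note_id must be a non-empty string")
        if not self.admission_id:
            raise ValueError(f"note {self.note_id!r}: admission_id missing")
        object.__setattr__(self, "sections", tuple(self.sections))
        prev_end = 0
        for sec in self.sections:
            if sec.start_offset < prev_end:
                raise ValueError(
                    f"note {self.note_id!r}: sections overlap or are out of order "
                    f"at {sec.name!r}"
                )
            if sec.end_offset > len(self.raw_text):
                raise ValueError(
                    f"note {self.note_id!r}: section {sec.name!r} extends past raw_text"
                )
            if self.raw_text[sec.start_offset : sec.end_offset] != sec.text:
                raise ValueError(
                    f"note {self.note_id!r}: section {sec.name!r} text does not match "
                    "its raw_text span"
                )
            prev_end = sec.end_offset


class LabelSource(str, Enum):
    """Provenance of a reference label.

    ``manual_review`` stands for expert chart review (the gold standard);
    ``synthetic_truth`` marks labels emitted by the simulator, so the two are
    never conflated in reports.
    """

    MANUAL_REVIEW = "manual_review"
    SYNTHETIC_TRUTH = "synthetic_truth"


@dataclass(frozen=True)
class ReferenceLabel:
    admission_id: str
    adhf: bool
    source: LabelSource = LabelSource.MANUAL_REVIEW

    def __post_init__(self) -> None:
        if not self.admission_id:
            raise ValueError("admission_id must be a non-empty string")
        object.__setattr__(self, "source", LabelSource(self.source))


@dataclass(frozen=True)
class CohortFlow:
    """Counts for the patient-eligibility flow.

    Patients are excluded first by age (< minimum at the reference date), then
    by missing research authorization, so the two exclusion counts partition
    the excluded set and ``n_eligible = n_patients - n_excluded_age -
    n_excluded_auth``.
    """

    n_admissions: int
    n_patients: int
    n_excluded_age: int
    n_excluded_auth: int
    n_eligible: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.n_eligible < 0:
            object.__setattr__(
                self,
                "n_eligible",
                self.n_patients - self.n_excluded_age - self.n_excluded_auth,
            )
        counts = (
            self.n_admissions,
            self.n_patients,
            self.n_excluded_age,
            self.n_excluded_auth,
            self.n_eligible,
        )
        if any(c < 0 for c in counts):
            raise ValueError(f"cohort flow counts must be non-negative, got {counts}")
        if self.n_eligible != self.n_patients - self.n_excluded_age - self.n_excluded_auth:
            raise ValueError(
                "n_eligible must equal n_patients - n_excluded_age - n_excluded_auth"
            )

    @classmethod
    def from_counts(
        cls,
        n_patients: int,
        n_excluded_age: int,
        n_excluded_auth: int,
        n_admissions: int = 0,
    ) -> "CohortFlow":
        """Build a flow from aggregate counts, deriving the eligible count."""
        return cls(
            n_admissions=n_admissions,
            n_patients=n_patients,
            n_excluded_age=n_excluded_age,
            n_excluded_auth=n_excluded_auth,
        )
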