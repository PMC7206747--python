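"""Synthetic EHR cohort generator.

Emulates the data regime the phenotype was built for: hospital admissions
whose sectioned notes document acute decompensated heart failure with high
but imperfect fidelity, true-negative admissions that sometimes carry
negated or historical mentions ("rule out ...", "prior ..."), mentions that
occasionally land only in out-of-scope sections (family history), and an
ICD-9 coding process that records an *acute* HF code for only about half of
true cases while chronic/unspecified HF codes are common and unspecific.

Ground truth is drawn *before* any text is rendered, and every admission's
truth record states what kind of mention (if any) was planted, so tests can
enumerate exactly which admissions a given dictionary must hit or miss. The
note language is deliberately templated — the engine operates on surface
forms and sections, not discourse — with several templates per slot so tests
cannot accidentally overfit to one string.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dictionary import MatchOptions, TermDictionary
from .records import ClinicalNote, HospitalAdmission, Patient
from .sections import segment_note

__all__ = [
    "SyntheticCohortSpec",
    "SyntheticTruth",
    "SyntheticCohort",
    "generate_cohort",
    "generator_manifest",
    "matched_dictionary",
]

# Surface forms planted by the generator; a matched dictionary contains all
# of them. Kept to clinically standard ADHF spellings.
SURFACE_FORMS: tuple[str, ...] = (
    "acute decompensated heart failure",
    "acute on chronic heart failure",
    "decompensated heart failure",
    "acute heart failure",
    "heart failure exacerbation",
    "adhf",
)

# Cues rendered before a mention to mark it negated/historical.
NEGATION_CUES: tuple[str, ...] = ("prior", "rule out", "negative for")

PLACEMENT_SECTIONS: tuple[str, ...] = (
    "principal_diagnosis",
    "secondary_diagnoses",
    "chief_complaint",
    "brief_hospital_course",
)

_HEADERS = {
    "chief_complaint": "Chief Complaint:",
    "principal_diagnosis": "Principal Diagnosis:",
    "secondary_diagnoses": "Secondary Diagnoses:",
    "brief_hospital_course": "Brief Hospital Course:",
    "family_history": "Family History:",
    "medications": "Medications:",
}

_FILLERS: dict[str, tuple[str, ...]] = {
    "chief_complaint": (
        "Shortness of breath.",
        "Chest discomfort on exertion.",
        "Fatigue and lower extremity swelling.",
    ),
    "principal_diagnosis": (
        "Community acquired pneumonia.",
        "Urinary tract infection.",
        "Atrial fibrillation with rapid rates.",
    ),
    "secondary_diagnoses": (
        "Hypertension; type 2 diabetes mellitus.",
        "Chronic kidney disease stage 3.",
        "Hyperlipidemia; obstructive sleep apnea.",
    ),
    "brief_hospital_course": (
        "Clinical status improved and the patient was discharged home.",
        "Treated with intravenous antibiotics with good response.",
        "Supportive care was provided throughout the stay.",
    ),
    "family_history": (
        "Mother with hypertension.",
        "Father with coronary artery disease.",
        "Noncontributory.",
    ),
    "medications": (
        "Lisinopril, metformin.",
        "Aspirin, atorvastatin.",
        "Furosemide, carvedilol.",
    ),
}

_AFFIRMED_TEMPLATES: tuple[str, ...] = (
    "Patient admitted with {form}.",
    "Assessment is consistent with {form}.",
    "Findings indicate {form} on arrival.",
)

# cue -> sentence templates; the cue shares the mention's sentence
_CUED_TEMPLATES: dict[str, tuple[str, ...]] = {
    "prior": (
        "Prior {form}, currently stable.",
        "Notable for prior {form} last year.",
    ),
    "rule out": (
        "Rule out {form}.",
        "Plan to rule out {form} with BNP testing.",
    ),
    "negative for": (
        "Workup negative for {form}.",
        "Negative for {form} on this admission.",
    ),
}

_OUT_OF_SCOPE_TEMPLATES: tuple[str, ...] = (
    "Father with {form}.",
    "Mother treated for {form} years ago.",
)

ACUTE_HF_CODES: tuple[str, ...] = (
    "428.21", "428.23", "428.31", "428.33", "428.41", "428.43",
)
CHRONIC_HF_CODES: tuple[str, ...] = ("428.0", "428.1", "428.22", "428.32", "428.9")
DISTRACTOR_CODES: tuple[str, ...] = ("401.9", "250.00", "414.01", "585.3", "486")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Knobs of the generative model; defaults mirror the target data regime
    (ADHF prevalence ~40% of the evaluated admissions, near-complete
    documentation of true cases, acute-HF coding for roughly half of them)."""

    n_patients: int = 200
    prevalence: float = 0.40
    p_document: float = 0.98
    p_negated_mention: float = 0.15
    p_out_of_scope_mention: float = 0.05
    p_acute_code_given_case: float = 0.475
    p_anyhf_code_given_case: float = 0.96
    p_anyhf_code_given_control: float = 0.13
    minor_fraction: float = 0.14
    unauthorized_fraction: float = 0.05
    seed: int = 0
    admissions_per_patient: int = 1

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.admissions_per_patient < 1:
            raise ValueError("admissions_per_patient must be >= 1")
        for name in (
            "prevalence",
            "p_document",
            "p_negated_mention",
            "p_out_of_scope_mention",
            "p_acute_code_given_case",
            "p_anyhf_code_given_case",
            "p_anyhf_code_given_control",
            "minor_fraction",
            "unauthorized_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
        if self.p_acute_code_given_case > self.p_anyhf_code_given_case:
            raise ValueError(
                "p_acute_code_given_case cannot exceed p_anyhf_code_given_case: "
                "an acute HF code is itself a heart-failure code"
            )


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth record, fixed before the note text is rendered."""

    admission_id: str
    adhf: bool
    mention_kind: str  # affirmed | negated | historical | out_of_scope | none

    def __post_init__(self) -> None:
        kinds = ("affirmed", "negated", "historical", "out_of_scope", "none")
        if self.mention_kind not in kinds:
            raise ValueError(f"mention_kind must be one of {kinds}")
        if self.adhf and self.mention_kind in ("negated", "historical"):
            raise ValueError("true cases are never rendered as negated mentions")


@dataclass(frozen=True)
class SyntheticCohort:
    spec: SyntheticCohortSpec
    patients: tuple[Patient, ...]
    admissions: tuple[HospitalAdmission, ...]
    notes: tuple[ClinicalNote, ...]
    truths: tuple[SyntheticTruth, ...]

    @property
    def truth_labels(self) -> dict[str, bool]:
        return {t.admission_id: t.adhf for t in self.truths}


def _pick(rng: np.random.Generator, items: tuple[str, ...]) -> str:
    return items[int(rng.integers(len(items)))]


def _render_note(
    rng: np.random.Generator,
    mention_kind: str,
    cue: str | None,
) -> str:
    """Render one note's raw text; the mention sentence (if any) is appended
    to a uniformly drawn slot."""
    form = _pick(rng, SURFACE_FORMS)
    target = _pick(rng, PLACEMENT_SECTIONS)
    extra: dict[str, str] = {}
    if mention_kind == "affirmed":
        extra[target] = _pick(rng, _AFFIRMED_TEMPLATES).format(form=form)
    elif mention_kind in ("negated", "historical"):
        assert cue is not None
        extra[target] = _pick(rng, _CUED_TEMPLATES[cue]).format(form=form)
    elif mention_kind == "out_of_scope":
        extra["family_history"] = _pick(rng, _OUT_OF_SCOPE_TEMPLATES).format(form=form)

    parts = ["Admission note."]
    for name in (
        "chief_complaint",
        "principal_diagnosis",
        "secondary_diagnoses",
        "brief_hospital_course",
        "family_history",
        "medications",
    ):
        body = _pick(rng, _FILLERS[name])
        if name in extra:
            body = f"{body} {extra[name]}"
        parts.append(f"{_HEADERS[name]} {body}")
    return "\n".join(parts) + "\n"


def _draw_codes(rng: np.random.Generator, spec: SyntheticCohortSpec, case: bool) -> list[str]:
    codes: list[str] = []
    if case:
        # one uniform draw couples the two coding arms: acute implies any-HF,
        # and both marginal rates equal their spec probabilities
        u = rng.random()
        if u < spec.p_acute_code_given_case:
            codes.append(_pick(rng, ACUTE_HF_CODES))
        elif u < spec.p_anyhf_code_given_case:
            codes.append(_pick(rng, CHRONIC_HF_CODES))
    else:
        if rng.random() < spec.p_anyhf_code_given_control:
            codes.append(_pick(rng, CHRONIC_HF_CODES))
    n_distract = int(rng.integers(1, 4))
    codes.extend(_pick(rng, DISTRACTOR_CODES) for _ in range(n_distract))
    return codes


def generate_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Draw a fully reproducible synthetic cohort from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    study_start = _dt.date(2006, 1, 1)

    patients: list[Patient] = []
    admissions: list[HospitalAdmission] = []
    notes: list[ClinicalNote] = []
    truths: list[SyntheticTruth] = []

    adm_counter = 0
    for i in range(spec.n_patients):
        pid = f"P{i:05d}"
        minor = rng.random() < spec.minor_fraction
        age = int(rng.integers(1, 18)) if minor else int(rng.integers(20, 91))
        authorized = rng.random() >= spec.unauthorized_fraction

        first_admit = study_start + _dt.timedelta(days=int(rng.integers(0, 3287)))
        birth_date = first_admit - _dt.timedelta(days=age * 365 + 200)
        patients.append(Patient(pid, birth_date, research_authorization=authorized))

        for _k in range(spec.admissions_per_patient):
            adm_counter += 1
            aid = f"A{adm_counter:05d}"
            admit = first_admit + _dt.timedelta(days=_k * 60)
            discharge = admit + _dt.timedelta(days=int(rng.integers(1, 15)))

            case = rng.random() < spec.prevalence
            cue: str | None = None
            if case:
                if rng.random() < spec.p_document:
                    kind = "affirmed"
                elif rng.random() < spec.p_out_of_scope_mention:
                    kind = "out_of_scope"
                else:
                    kind = "none"
            else:
                if rng.random() < spec.p_negated_mention:
                    cue = _pick(rng, NEGATION_CUES)
                    kind = "historical" if cue == "prior" else "negated"
                else:
                    kind = "none"
            truths.append(SyntheticTruth(admission_id=aid, adhf=case, mention_kind=kind))

            raw = _render_note(rng, kind, cue)
            note = ClinicalNote(
                note_id=f"N{adm_counter:05d}",
                admission_id=aid,
                patient_id=pid,
                timestamp=_dt.datetime.combine(admit, _dt.time(int(rng.integers(0, 24)))),
                raw_text=raw,
                sections=tuple(segment_note(raw)),
            )
            notes.append(note)

            admissions.append(
                HospitalAdmission(
                    admission_id=aid,
                    patient_id=pid,
                    admit_date=admit,
                    discharge_date=discharge,
                    icd9_codes=tuple(_draw_codes(rng, spec, case)),
                )
            )

    return SyntheticCohort(
        spec=spec,
        patients=tuple(patients),
        admissions=tuple(admissions),
        notes=tuple(notes),
        truths=tuple(truths),
    )


def generator_manifest(spec: SyntheticCohortSpec) -> dict:
    """Machine-readable description of what the generator plants, so tests
    and the refinement loop can build matched or deliberately impoverished
    dictionaries."""
    return {
        "surface_forms": list(SURFACE_FORMS),
        "negation_cues": list(NEGATION_CUES),
        "placement_sections": list(PLACEMENT_SECTIONS),
        "out_of_scope_sections": ["family_history"],
        "section_headers": dict(_HEADERS),
        "acute_hf_codes": list(ACUTE_HF_CODES),
        "chronic_hf_codes": list(CHRONIC_HF_CODES),
        "spec": {
            f: getattr(spec, f)
            for f in (
                "n_patients",
                "prevalence",
                "p_document",
                "p_negated_mention",
                "p_out_of_scope_mention",
                "p_acute_code_given_case",
                "p_anyhf_code_given_case",
                "p_anyhf_code_given_control",
                "minor_fraction",
                "unauthorized_fraction",
                "seed",
                "admissions_per_patient",
            )
        },
    }


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write a generated cohort in the package's interchange formats:
    notes JSONL, admissions/codes/patients/truth CSVs, and the manifest."""
    import json

    from . import io as _io
    from .records import LabelSource, ReferenceLabel

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "notes": out / "notes.jsonl",
        "admissions": out / "admissions.csv",
        "codes": out / "codes.csv",
        "patients": out / "patients.csv",
        "truth": out / "truth.csv",
        "manifest": out / "manifest.json",
    }
    _io.write_note_corpus(cohort.notes, paths["notes"])
    _io.write_admissions(cohort.admissions, paths["admissions"], paths["codes"])
    _io.write_patients(cohort.patients, paths["patients"])
    _io.write_labels(
        [
            ReferenceLabel(t.admission_id, t.adhf, LabelSource.SYNTHETIC_TRUTH)
            for t in cohort.truths
        ],
        paths["truth"],
    )
    paths["manifest"].write_text(json.dumps(generator_manifest(cohort.spec), indent=2) + "\n")
    return paths


def matched_dictionary(
    spec: SyntheticCohortSpec | None = None,
    drop_forms: int = 0,
    include_cues: bool = True,
) -> TermDictionary:
    """A dictionary matched to the generator's manifest.

    ``drop_forms`` removes the last N surface forms (an impoverished starting
    dictionary for the refinement loop); ``include_cues=False`` omits the
    exclusion cues.
    """
    forms = SURFACE_FORMS[: len(SURFACE_FORMS) - drop_forms]
    if not forms:
        raise ValueError("cannot drop every surface form")
    return TermDictionary(
        inclusion_terms=forms,
        exclusion_terms=NEGATION_CUES if include_cues else (),
        scoped_sections=frozenset(PLACEMENT_SECTIONS),
        match_options=MatchOptions(),
    )
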