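"""Readers and writers for the package's plain-text interchange formats.

* Note corpus: JSON Lines, one note per line, fields ``note_id``,
  ``admission_id``, ``patient_id`` (optional), ``timestamp`` (ISO-8601),
  ``text`` and optional pre-segmented ``sections``. When a record supplies
  raw text only, sections are populated by the segmenter.
* Admissions: CSV ``admission_id, patient_id, admit_date, discharge_date``;
  codes in a separate CSV ``admission_id, icd9_code`` (one row per code).
* Patients: CSV ``patient_id, birth_date, research_authorization``.
* Reference labels: CSV ``admission_id, adhf (0/1), source``.
* Verdicts: CSV ``admission_id, adhf, n_kept, n_suppressed``; full evidence
  as JSON Lines.
"""

from __future__ import annotations

import datetime as _dt
import json
from collections.abc import Iterable, Mapping
from pathlib import Path

import pandas as pd

from .engine import PhenotypeVerdict, TermMatch
from .records import (
    ClinicalNote,
    HospitalAdmission,
    LabelSource,
    NoteSection,
    Patient,
    ReferenceLabel,
)
from .sections import DEFAULT_SECTION_PATTERNS, SectionPattern, segment_note

__all__ = [
    "read_note_corpus",
    "write_note_corpus",
    "read_patients",
    "write_patients",
    "read_admissions",
    "write_admissions",
    "read_code_lists",
    "read_labels",
    "write_labels",
    "write_verdicts",
    "read_predictions",
    "write_evidence",
    "write_discordances",
]

_REQUIRED_NOTE_FIELDS = ("note_id", "admission_id", "timestamp", "text")


def read_note_corpus(
    path: str | Path,
    section_patterns: Iterable[SectionPattern] = DEFAULT_SECTION_PATTERNS,
) -> list[ClinicalNote]:
    """Read a JSON Lines note corpus, preserving input order.

    Records without pre-segmented sections are segmented from the raw text.
    Malformed records raise with the offending line number; duplicate note
    ids raise.
    """
    path = Path(path)
    notes: list[ClinicalNote] = []
    seen: set[str] = set()
    with path.open() as fh:
        for line_num, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path} line {line_num}: invalid JSON ({exc})") from exc
            missing = [f for f in _REQUIRED_NOTE_FIELDS if f not in rec]
            if missing:
                raise ValueError(
                    f"{path} line {line_num}: record missing field(s) {missing}"
                )
            if rec["note_id"] in seen:
                raise ValueError(
                    f"{path} line {line_num}: duplicate note_id {rec['note_id']!r}"
                )
            seen.add(rec["note_id"])
            raw = rec["text"]
            if "sections" in rec and rec["sections"]:
                sections = tuple(
                    NoteSection(
                        name=s["name"],
                        text=raw[s["start_offset"] : s["end_offset"]],
                        start_offset=s["start_offset"],
                        end_offset=s["end_offset"],
                    )
                    for s in rec["sections"]
                )
            else:
                sections = tuple(segment_note(raw, tuple(section_patterns)))
            notes.append(
                ClinicalNote(
                    note_id=rec["note_id"],
                    admission_id=rec["admission_id"],
                    patient_id=rec.get("patient_id"),
                    timestamp=_dt.datetime.fromisoformat(rec["timestamp"]),
                    raw_text=raw,
                    sections=sections,
                )
            )
    return notes


def write_note_corpus(notes: Iterable[ClinicalNote], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for note in notes:
            rec = {
                "note_id": note.note_id,
                "admission_id": note.admission_id,
                "patient_id": note.patient_id,
                "timestamp": note.timestamp.isoformat(),
                "text": note.raw_text,
                "sections": [
                    {
                        "name": s.name,
                        "start_offset": s.start_offset,
                        "end_offset": s.end_offset,
                    }
                    for s in note.sections
                ],
            }
            fh.write(json.dumps(rec) + "\n")


def read_patients(path: str | Path) -> list[Patient]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    return [
        Patient(
            patient_id=row.patient_id,
            birth_date=_dt.date.fromisoformat(str(row.birth_date)),
            research_authorization=bool(int(row.research_authorization)),
        )
        for row in df.itertuples(index=False)
    ]


def write_patients(patients: Iterable[Patient], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "birth_date": p.birth_date.isoformat(),
                "research_authorization": int(p.research_authorization),
            }
            for p in patients
        ]
    ).to_csv(path, index=False)


def read_admissions(
    admissions_path: str | Path, codes_path: str | Path | None = None
) -> list[HospitalAdmission]:
    df = pd.read_csv(admissions_path, dtype={"admission_id": str, "patient_id": str})
    codes: dict[str, list[str]] = {}
    if codes_path is not None:
        codes = read_code_lists(codes_path)
    return [
        HospitalAdmission(
            admission_id=row.admission_id,
            patient_id=row.patient_id,
            admit_date=_dt.date.fromisoformat(str(row.admit_date)),
            discharge_date=_dt.date.fromisoformat(str(row.discharge_date)),
            icd9_codes=tuple(codes.get(row.admission_id, ())),
        )
        for row in df.itertuples(index=False)
    ]


def write_admissions(
    admissions: Iterable[HospitalAdmission],
    admissions_path: str | Path,
    codes_path: str | Path | None = None,
) -> None:
    admissions = list(admissions)
    pd.DataFrame(
        [
            {
                "admission_id": a.admission_id,
                "patient_id": a.patient_id,
                "admit_date": a.admit_date.isoformat(),
                "discharge_date": a.discharge_date.isoformat(),
            }
            for a in admissions
        ]
    ).to_csv(admissions_path, index=False)
    if codes_path is not None:
        rows = [
            {"admission_id": a.admission_id, "icd9_code": c}
            for a in admissions
            for c in a.icd9_codes
        ]
        pd.DataFrame(rows, columns=["admission_id", "icd9_code"]).to_csv(
            codes_path, index=False
        )


def read_code_lists(path: str | Path) -> dict[str, list[str]]:
    """Per-admission ICD-9 code lists from CSV ``admission_id, icd9_code``."""
    df = pd.read_csv(path, dtype=str)
    missing = {"admission_id", "icd9_code"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.admission_id, []).append(row.icd9_code)
    return out


def read_labels(path: str | Path) -> list[ReferenceLabel]:
    df = pd.read_csv(path, dtype={"admission_id": str})
    labels = [
        ReferenceLabel(
            admission_id=row.admission_id,
            adhf=bool(int(row.adhf)),
            source=LabelSource(getattr(row, "source", "manual_review")),
        )
        for row in df.itertuples(index=False)
    ]
    ids = [l.admission_id for l in labels]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate admission_id in labels")
    return labels


def write_labels(labels: Iterable[ReferenceLabel], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "admission_id": l.admission_id,
                "adhf": int(l.adhf),
                "source": l.source.value,
            }
            for l in labels
        ]
    ).to_csv(path, index=False)


def labels_to_mapping(labels: Iterable[ReferenceLabel]) -> dict[str, bool]:
    return {l.admission_id: l.adhf for l in labels}


def write_verdicts(verdicts: Mapping[str, PhenotypeVerdict], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "admission_id": adm_id,
                "adhf": int(v.adhf),
                "n_kept": len(v.kept_matches),
                "n_suppressed": len(v.suppressed_matches),
            }
            for adm_id, v in verdicts.items()
        ]
    ).to_csv(path, index=False)


def read_predictions(path: str | Path) -> dict[str, bool]:
    """Admission-level boolean predictions from a verdicts-style CSV."""
    df = pd.read_csv(path, dtype={"admission_id": str})
    return {row.admission_id: bool(int(row.adhf)) for row in df.itertuples(index=False)}


def _match_to_dict(m: TermMatch) -> dict:
    return {
        "term": m.term,
        "section_name": m.section_name,
        "start": m.start,
        "end": m.end,
        "sentence_index": m.sentence_index,
        "suppressed_by": m.suppressed_by,
        "note_id": m.note_id,
    }


def write_evidence(verdicts: Mapping[str, PhenotypeVerdict], path: str | Path) -> None:
    """Full evidence trail, one JSON object per admission."""
    with Path(path).open("w") as fh:
        for adm_id, v in verdicts.items():
            fh.write(
                json.dumps(
                    {
                        "admission_id": adm_id,
                        "adhf": v.adhf,
                        "kept_matches": [_match_to_dict(m) for m in v.kept_matches],
                        "suppressed_matches": [
                            _match_to_dict(m) for m in v.suppressed_matches
                        ],
                    }
                )
                + "\n"
            )


def write_discordances(discordances, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for d in discordances:
            evidence = d.evidence
            if isinstance(evidence, PhenotypeVerdict):
                evidence = {
                    "kept_matches": [_match_to_dict(m) for m in evidence.kept_matches],
                    "suppressed_matches": [
                        _match_to_dict(m) for m in evidence.suppressed_matches
                    ],
                }
            fh.write(
                json.dumps(
                    {
                        "admission_id": d.admission_id,
                        "predicted": d.predicted,
                        "reference_label": d.reference_label,
                        "evidence": evidence,
                    }
                )
                + "\n"
            )
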