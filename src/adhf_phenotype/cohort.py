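"""Patient-eligibility filtering.

Mirrors the study-population flow: start from all patients with hospital
admissions in the window, exclude minors first (age at a reference date below
the minimum), then exclude patients without research authorization, so the
two exclusion counts partition the excluded set.
"""

from __future__ import annotations

import datetime as _dt
from collections.abc import Iterable

from .records import CohortFlow, HospitalAdmission, Patient

__all__ = ["filter_eligible", "REFERENCE_DATE_RULES"]

REFERENCE_DATE_RULES = ("first_admission", "last_admission")


def filter_eligible(
    patients: Iterable[Patient],
    admissions: Iterable[HospitalAdmission],
    min_age_years: float = 18,
    require_authorization: bool = True,
    reference_date_rule: str = "first_admission",
) -> tuple[set[str], CohortFlow]:
    """Apply the age and research-authorization exclusions.

    Returns the eligible patient-id set and the :class:`CohortFlow` counts.
    Age is evaluated at the patient's first (or last) admission date. Every
    admission must reference a known patient, and every patient must have at
    least one admission (otherwise the age reference date is undefined).
    """
    if min_age_years < 0:
        raise ValueError("min_age_years must be >= 0")
    if reference_date_rule not in REFERENCE_DATE_RULES:
        raise ValueError(
            f"reference_date_rule must be one of {REFERENCE_DATE_RULES}, "
            f"got {reference_date_rule!r}"
        )

    patients = list(patients)
    admissions = list(admissions)
    by_id = {p.patient_id: p for p in patients}
    if len(by_id) != len(patients):
        raise ValueError("duplicate patient_id in cohort")

    ref_date: dict[str, _dt.date] = {}
    pick = min if reference_date_rule == "first_admission" else max
    for adm in admissions:
        if adm.patient_id not in by_id:
            raise ValueError(
                f"admission {adm.admission_id!r} references unknown patient "
                f"{adm.patient_id!r}"
            )
        cur = ref_date.get(adm.patient_id)
        ref_date[adm.patient_id] = (
            adm.admit_date if cur is None else pick(cur, adm.admit_date)
        )

    missing = [p.patient_id for p in patients if p.patient_id not in ref_date]
    if missing:
        raise ValueError(
            f"patients without admissions have no age reference date: {missing[:5]}"
        )

    eligible: set[str] = set()
    n_age = n_auth = 0
    for p in patients:
        if p.age_at(ref_date[p.patient_id]) < min_age_years:
            n_age += 1
        elif require_authorization and not p.research_authorization:
            n_auth += 1
        else:
            eligible.add(p.patient_id)

    flow = CohortFlow(
        n_admissions=len(admissions),
        n_patients=len(patients),
        n_excluded_age=n_age,
        n_excluded_auth=n_auth,
    )
    return eligible, flow
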