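"""Domain types shared by every stage of the case-finding pipeline.

The unit of analysis is a :class:`PatientRecord`: one rostered primary-care
patient with their free-text EMR documents, outpatient billing claims, and
hospital (discharge / emergency / day-surgery) records, plus — when the cohort
is synthetic or chart-abstracted — a gold-standard NF1 status label.

Dates are ISO-8601 calendar dates; every record interval is treated as the
closed interval ``[record_start, record_end]``.
"""

from __future__ import annotations

import datetime as _dt
from enum import Enum

from pydantic import BaseModel, Field, NonNegativeFloat, NonNegativeInt, field_validator

#: First fiscal date on which hospital databases switched to ICD-10 coding.
ICD10_CUTOVER = _dt.date(2002, 4, 1)


class DocType(str, Enum):
    """Section / document kind within the EMR chart."""

    cpp_problem_list = "cpp_problem_list"
    cpp_past_medical_history = "cpp_past_medical_history"
    cpp_family_history = "cpp_family_history"
    progress_note = "progress_note"
    specialist_letter = "specialist_letter"
    discharge_summary = "discharge_summary"
    lab_or_other = "lab_or_other"


#: Document types consulted by the CPP classification algorithm.
CPP_CLASSIFIER_DOC_TYPES = frozenset(
    {DocType.cpp_problem_list, DocType.cpp_past_medical_history}
)


class HospitalSource(str, Enum):
    """Hospital data source: discharge abstracts, emergency visits, day surgery."""

    DAD = "DAD"
    NACRS_ED = "NACRS_ED"
    SDS = "SDS"


class Sex(str, Enum):
    F = "F"
    M = "M"


class TrueStatus(str, Enum):
    """Chart-abstraction label.

    ``confirmed`` — documented diagnosis meeting clinical criteria;
    ``possible`` — an NF1 mention or a single criterion without enough
    evidence to confirm; ``not_nf1`` — explicitly ruled out; ``blank`` —
    the chart never mentions NF1.  In binary evaluation only ``confirmed``
    counts as positive.
    """

    confirmed = "confirmed"
    possible = "possible"
    not_nf1 = "not_nf1"
    blank = "blank"


#: Closed provider-specialty vocabulary for outpatient claims.
SPECIALTIES = frozenset(
    {
        "family_medicine",
        "neurology",
        "neurosurgery",
        "pediatrics",
        "genetics",
        "plastic_surgery",
        "general_surgery",
        "dermatology",
        "other",
    }
)


class EmrDocument(BaseModel):
    doc_type: DocType
    date: _dt.date
    text: str = ""


class OutpatientClaim(BaseModel):
    """One outpatient billing claim: a 3-digit diagnostic code, a service
    date, and the billing provider's specialty."""

    code: str = Field(pattern=r"^[0-9]{3}$")
    date: _dt.date
    specialty: str

    @field_validator("specialty")
    @classmethod
    def _known_specialty(cls, v: str) -> str:
        if v not in SPECIALTIES:
            raise ValueError(f"unknown specialty {v!r}; known: {sorted(SPECIALTIES)}")
        return v


class HospitalRecord(BaseModel):
    """A hospital encounter carrying one or more ICD diagnosis codes."""

    source: HospitalSource
    icd_version: int
    codes: list[str] = Field(min_length=1)
    date: _dt.date

    @field_validator("icd_version")
    @classmethod
    def _icd_9_or_10(cls, v: int) -> int:
        if v not in (9, 10):
            raise ValueError("icd_version must be 9 or 10")
        return v


class PatientRecord(BaseModel):
    patient_id: str
    age_years: NonNegativeFloat
    sex: Sex
    emr_documents: list[EmrDocument] = Field(default_factory=list)
    outpatient_claims: list[OutpatientClaim] = Field(default_factory=list)
    hospital_records: list[HospitalRecord] = Field(default_factory=list)
    record_start: _dt.date
    record_end: _dt.date
    true_status: TrueStatus | None = None

    def cpp_documents(self) -> list[EmrDocument]:
        """Documents in the sections the CPP classifier consults."""
        return [d for d in self.emr_documents if d.doc_type in CPP_CLASSIFIER_DOC_TYPES]

    @property
    def is_confirmed(self) -> bool:
        return self.true_status is TrueStatus.confirmed


class ConfusionMatrix(BaseModel):
    """2x2 tabulation of algorithm decisions against abstracted truth."""

    tp: NonNegativeInt
    fp: NonNegativeInt
    tn: NonNegativeInt
    fn: NonNegativeInt

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


class Violation(BaseModel):
    """One invariant failure found in a cohort, reported not raised."""

    patient_id: str
    rule: str
    detail: str = ""


def validate_cohort(records: list[PatientRecord]) -> list[Violation]:
    """Check cross-field cohort invariants and return one entry per breach.

    Rules checked: unique patient ids; ``record_start <= record_end``; every
    document, claim and hospital date inside the closed record span; the
    synthetic-data ICD convention (version 9 before the 2002-04-01 cutover,
    10 on/after).  Field-level invariants (code format, enums) are enforced
    at construction time by the models themselves.
    """
    violations: list[Violation] = []
    seen: set[str] = set()
    for rec in records:
        pid = rec.patient_id
        if pid in seen:
            violations.append(Violation(patient_id=pid, rule="unique_patient_id"))
        seen.add(pid)
        if rec.record_start > rec.record_end:
            violations.append(
                Violation(
                    patient_id=pid,
                    rule="record_span_ordered",
                    detail=f"{rec.record_start} > {rec.record_end}",
                )
            )
            continue
        span = (rec.record_start, rec.record_end)
        for kind, dates in (
            ("document", (d.date for d in rec.emr_documents)),
            ("claim", (c.date for c in rec.outpatient_claims)),
            ("hospital_record", (h.date for h in rec.hospital_records)),
        ):
            for d in dates:
                if not (span[0] <= d <= span[1]):
                    violations.append(
                        Violation(
                            patient_id=pid,
                            rule="date_within_record_span",
                            detail=f"{kind} dated {d} outside [{span[0]}, {span[1]}]",
                        )
                    )
        for h in rec.hospital_records:
            expected = 9 if h.date < ICD10_CUTOVER else 10
            if h.icd_version != expected:
                violations.append(
                    Violation(
                        patient_id=pid,
                        rule="icd_version_matches_date",
                        detail=f"version {h.icd_version} on {h.date}",
                    )
                )
    return violations
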