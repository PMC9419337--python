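"""Boolean rule engine over outpatient billing and hospital diagnosis codes.

An administrative algorithm is a boolean expression tree whose leaves are
:class:`CodeCountAtom`\\ s — "at least *k* qualifying events within any
*w*-year window" — evaluated against one patient's claims and hospital
records.  The built-in catalogue reproduces the candidate algorithms a
practitioner would test for NF1 in Ontario data: hospital (DAD / NACRS
emergency / same-day surgery) ICD codes 237.7, 237.71 and Q85.0, and
outpatient OHIP diagnostic codes 192, 216, 225, 709 and 758, optionally
restricted to specialties that commonly care for NF1 patients.

There is no NF1-specific outpatient code, which is why the outpatient
algorithms drown in false positives; the engine exists to quantify that.
"""

from __future__ import annotations

import datetime as _dt
from typing import Literal, Union

from pydantic import BaseModel, Field, PositiveInt, model_validator

from .data_model import SPECIALTIES, HospitalSource, PatientRecord

__all__ = [
    "CodeCountAtom",
    "BoolNode",
    "ClaimsAlgorithm",
    "count_in_window",
    "eval_atom",
    "eval_algorithm",
    "builtin_algorithms",
    "NF_ICD_CODES",
    "NF_OHIP_CODES",
    "NF_SPECIALTIES",
]

DAYS_PER_YEAR = 365.25

#: Hospital diagnosis codes for neurofibromatosis (ICD-9 237.7 "NF
#: unspecified", 237.71 "NF1"; ICD-10 Q85.0).
NF_ICD_CODES = frozenset({"237.7", "237.71", "Q85.0"})

#: Outpatient diagnostic codes commonly billed for confirmed NF1 patients.
NF_OHIP_CODES = frozenset({"192", "216", "225", "709", "758"})

#: Specialties used by the starred (specialty-restricted) OHIP atoms.
NF_SPECIALTIES = frozenset(
    {"neurology", "neurosurgery", "pediatrics", "genetics", "plastic_surgery", "general_surgery"}
)

EventSource = Literal["OHIP", "DAD", "NACRS_ED", "SDS"]


class CodeCountAtom(BaseModel):
    """Leaf predicate: >= ``min_count`` qualifying events in some window.

    ``window_years`` is a number of years or the string ``"ever"``.  A
    hospital event qualifies if *any* code on the record is in
    ``code_set``.  ``specialty_set`` restricts OHIP claims by billing
    provider and is meaningless (hence forbidden) for hospital sources.
    """

    source: EventSource
    code_set: set[str] = Field(min_length=1)
    min_count: PositiveInt = 1
    window_years: float | Literal["ever"] = "ever"
    specialty_set: set[str] | None = None
    icd_prefix_match: bool = True

    @model_validator(mode="after")
    def _check(self) -> "CodeCountAtom":
        if self.specialty_set is not None:
            if self.source != "OHIP":
                raise ValueError("specialty_set is only valid for OHIP atoms")
            unknown = self.specialty_set - SPECIALTIES
            if unknown:
                raise ValueError(f"unknown specialties: {sorted(unknown)}")
        if self.window_years != "ever" and self.window_years <= 0:
            raise ValueError("window_years must be positive or 'ever'")
        return self


class BoolNode(BaseModel):
    """Internal AND/OR node of an algorithm expression tree."""

    op: Literal["and", "or"]
    children: list[Union["BoolNode", CodeCountAtom]] = Field(min_length=1)


BoolNode.model_rebuild()


class ClaimsAlgorithm(BaseModel):
    name: str
    expr: BoolNode | CodeCountAtom


def count_in_window(
    dates: list[_dt.date], window_years: float | Literal["ever"]
) -> int:
    """Maximum number of events inside any closed window of
    ``window_years * 365.25`` days anchored at an observed event date;
    ``"ever"`` counts everything."""
    if window_years == "ever":
        return len(dates)
    if window_years <= 0:
        raise ValueError("window_years must be positive")
    if not dates:
        return 0
    dates = sorted(dates)
    width = _dt.timedelta(days=window_years * DAYS_PER_YEAR)
    best = 0
    j = 0
    for i, anchor in enumerate(dates):
        if j < i:
            j = i
        while j < len(dates) and dates[j] - anchor <= width:
            j += 1
        best = max(best, j - i)
    return best


def _norm_icd(code: str) -> str:
    return code.replace(".", "").upper()


def _event_dates(patient: PatientRecord, atom: CodeCountAtom) -> list[_dt.date]:
    if atom.source == "OHIP":
        return [
            c.date
            for c in patient.outpatient_claims
            if c.code in atom.code_set
            and (atom.specialty_set is None or c.specialty in atom.specialty_set)
        ]
    source = HospitalSource(atom.source)
    if atom.icd_prefix_match:
        wanted = {_norm_icd(c) for c in atom.code_set}

        def hit(code: str) -> bool:
            n = _norm_icd(code)
            return any(n == w or n.startswith(w) for w in wanted)

    else:

        def hit(code: str) -> bool:
            return code in atom.code_set

    return [
        h.date
        for h in patient.hospital_records
        if h.source is source and any(hit(c) for c in h.codes)
    ]


def eval_atom(patient: PatientRecord, atom: CodeCountAtom) -> bool:
    """True iff the patient's qualifying events reach ``min_count`` within
    the atom's window."""
    dates = _event_dates(patient, atom)
    if len(dates) < atom.min_count:  # cheap reject; also handles "ever"
        return False
    return count_in_window(dates, atom.window_years) >= atom.min_count


def eval_algorithm(patient: PatientRecord, alg: ClaimsAlgorithm) -> bool:
    """Evaluate the boolean expression tree (short-circuiting)."""

    def ev(node: BoolNode | CodeCountAtom) -> bool:
        if isinstance(node, CodeCountAtom):
            return eval_atom(patient, node)
        if node.op == "and":
            return all(ev(c) for c in node.children)
        return any(ev(c) for c in node.children)

    return ev(alg.expr)


def _hosp(source: EventSource) -> CodeCountAtom:
    return CodeCountAtom(source=source, code_set=set(NF_ICD_CODES))


def builtin_algorithms() -> dict[str, ClaimsAlgorithm]:
    """The shipped catalogue of administrative algorithms.

    "CIHI" denotes hospitalizations only (DAD discharge abstracts); the
    broader variant adds emergency (NACRS) and same-day surgery records.
    Starred OHIP atoms are restricted to :data:`NF_SPECIALTIES`.
    """
    ohip = lambda n, w, spec=None: CodeCountAtom(  # noqa: E731
        source="OHIP",
        code_set=set(NF_OHIP_CODES),
        min_count=n,
        window_years=w,
        specialty_set=set(NF_SPECIALTIES) if spec else None,
    )
    algs = [
        ClaimsAlgorithm(name="cihi", expr=_hosp("DAD")),
        ClaimsAlgorithm(
            name="cihi_nacrs_sds",
            expr=BoolNode(op="or", children=[_hosp("DAD"), _hosp("NACRS_ED"), _hosp("SDS")]),
        ),
        ClaimsAlgorithm(name="ohip_1_ever", expr=ohip(1, "ever")),
        ClaimsAlgorithm(
            name="cihi_or_2ohip_spec_ever",
            expr=BoolNode(op="or", children=[_hosp("DAD"), ohip(2, "ever", spec=True)]),
        ),
        ClaimsAlgorithm(
            name="cihi_or_4ohip_3y",
            expr=BoolNode(op="or", children=[_hosp("DAD"), ohip(4, 3.0)]),
        ),
        ClaimsAlgorithm(
            name="ohip225_and_758spec_ever",
            expr=BoolNode(
                op="and",
                children=[
                    CodeCountAtom(source="OHIP", code_set={"225"}),
                    CodeCountAtom(
                        source="OHIP", code_set={"758"}, specialty_set=set(NF_SPECIALTIES)
                    ),
                ],
            ),
        ),
    ]
    return {a.name: a for a in algs}
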