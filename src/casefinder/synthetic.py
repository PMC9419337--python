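"""Synthetic primary-care cohort generator.

Emulates the statistical structure the case-finding algorithms assume in a
rostered primary-care EMR population of ~273k patients with an NF1
prevalence near 1 in 3,850:

* **Documentation** — a confirmed case carries an NF1 term in the
  problem-list / past-medical-history sections of its cumulative patient
  profile (CPP) with probability ``p_cpp_documented`` (default 60/71); all
  confirmed cases carry NF1 clinical detail in progress notes, so
  undocumented cases are recoverable by the liberal flag search but not by
  the CPP classifier.
* **Confusable text** — non-cases receive, at configurable rates, the
  mention types that defeat naive searches: bare "NF" as a province
  abbreviation or health-card verification code, isolated café-au-lait
  findings, family-history phrasing, rule-out phrasing, NF2, and the rare
  unvetoed spurious CPP mention.
* **Claims behaviour** — there is no NF1-specific outpatient code, so
  cases bill generic codes (no-diagnosis 999 dominating, skin codes,
  etc.); only ~31% of confirmed cases ever receive an NF-specific hospital
  (ICD) code, split between discharge abstracts and emergency/day-surgery
  records.

Text is template-based (deterministic, auditable), ICD version follows the
2002-04-01 cutover, and identical seeds give byte-identical cohorts.
"""

from __future__ import annotations

import datetime as _dt
import math

import numpy as np
from pydantic import BaseModel, Field, model_validator

from . import claims_rules, text_search
from .data_model import (
    ICD10_CUTOVER,
    DocType,
    EmrDocument,
    HospitalRecord,
    HospitalSource,
    OutpatientClaim,
    PatientRecord,
    Sex,
    TrueStatus,
)
from .validation_metrics import DiagnosticReport, confusion_matrix, diagnostic_report

__all__ = ["SyntheticConfig", "generate_cohort", "end_to_end_report", "truth_labels"]

_EXTRACTION_DATE = _dt.date(2016, 3, 31)

# ---------------------------------------------------------------------------
# Phrase banks.  CPP templates are problem-list style entries; progress-note
# templates are free prose.  Vetoed templates are co-designed with the
# default exclusion rules (tested: every one of them is actually vetoed).

CPP_NF1_TEMPLATES = [
    "NF1",
    "Neurofibromatosis type 1",
    "neurofibromatosis",
    "NF1, seen in genetics",
    "von Recklinghausen disease",
    "Neurofibiromatosis",  # misspelling seen in charts
    "neurofibomatosis",
    "Neuro Fibromatosis",
]

CASE_NOTE_TEMPLATES = [
    "multiple café-au-lait macules and axillary freckling on exam",
    "Lisch nodules noted on slit-lamp examination",
    "plexiform neurofibroma of the left orbit, stable",
    "numerous cutaneous neurofibromas over trunk",
    "MRI brain: optic glioma, stable since last scan",
    "follow-up of NF1 in neurofibromatosis clinic",
]

POSSIBLE_UNVETOED_CPP = [
    "NF1",
    "neurofibromatosis",
]

POSSIBLE_VETOED_CPP = [
    "family history of neurofibromatosis",
    "child of parent with NF1 - FMHx",
    "?early NF1",
    "possible neurofibromatosis",
]

CONFOUNDER_TEMPLATES = {
    "bare_nf": [
        "Moved here from NF in 1998, records requested",
        "health card verification code NF",
        "Family relocated to NF last spring",
    ],
    "cafe_au_lait_only": [
        "single café-au-lait macule on left shoulder, no other findings",
        "two cafe au lait spots noted at well-baby visit",
    ],
    "family_history": [
        "family history of neurofibromatosis",
        "FMHx neurofibromatosis, patient unaffected",
        "sister with NF1",
    ],
    "rule_out": [
        "rule out NF1",
        "r/o neurofibromatosis",
        "screen for NF1 - unconfirmed",
    ],
    "nf2": [
        "NF2 (bilateral vestibular schwannomas)",
        "neurofibromatosis 2 - NF2, followed by ENT",
    ],
    "unvetoed_mention": [
        "neurofibromatosis",
        "NF1",
    ],
}

#: Outpatient code shares billed by confirmed cases: no-diagnosis (999)
#: dominates, drug dependence (304) and the skin codes (709/216/173)
#: follow, then assorted neuro/genetic codes; the remainder is spread over
#: generic primary-care codes.
CASE_OHIP_DISTRIBUTION = {
    "999": 0.346,
    "304": 0.043,
    "709": 0.0145,
    "216": 0.0097,
    "173": 0.0047,
    "787": 0.021,
    "781": 0.013,
    "300": 0.012,
    "192": 0.010,
    "349": 0.009,
    "401": 0.009,
    "758": 0.005,
    "225": 0.004,
    "191": 0.003,
    "759": 0.003,
    "313": 0.002,
    "315": 0.002,
    # generic filler for the unprinted long tail
    "460": 0.155,
    "780": 0.155,
    "917": 0.1791,
}

#: Non-case shares: mostly generic primary care; a few percent fall on the
#: NF-candidate codes (skin, hypertension-adjacent misuse), which is what
#: sinks the outpatient algorithms' PPV.
NONCASE_OHIP_DISTRIBUTION = {
    "999": 0.35,
    "401": 0.08,
    "300": 0.07,
    "460": 0.06,
    "780": 0.05,
    "787": 0.03,
    "781": 0.03,
    "709": 0.02,
    "216": 0.01,
    "650": 0.02,
    "917": 0.28,
}

#: Background (non-NF) hospital diagnosis codes by ICD version.
_BACKGROUND_ICD = {9: ["401.9", "486", "540.9"], 10: ["I10", "J18.9", "K35.8"]}


class EncounterRates(BaseModel):
    """Mean outpatient encounters per patient-year, by case status.

    The case rate is high: confirmed cases average several hundred
    encounters over ~7 years of follow-up.  Counts are negative-binomial
    (dispersion ``nb_dispersion``) around rate x follow-up.
    """

    case: float = 56.0
    non_case: float = 4.0
    nb_dispersion: float = 1.5


class ConfounderRates(BaseModel):
    """Per-patient probabilities of each confusable-mention type among
    non-cases."""

    bare_nf: float = 0.003
    cafe_au_lait_only: float = 0.0012
    sheath_tumour_only: float = 0.0003
    family_history: float = 0.0018
    rule_out: float = 0.0006
    nf2: float = 0.0001
    unvetoed_mention: float = 7 / 273332


class SyntheticConfig(BaseModel):
    """All generator knobs.  Defaults reproduce the reference primary-care
    cohort conditions (prevalences, documentation and hospital-coding
    probabilities, billing-code shares)."""

    n_patients: int = Field(default=20000, ge=1)
    prevalence_confirmed: float = 71 / 273440
    prevalence_possible: float = 37 / 273440
    p_cpp_documented: float = 60 / 71
    p_cpp_documented_possible: float = 8 / 37
    p_hospital_coded: float = 22 / 71
    p_dad_given_coded: float = 15 / 22
    p_hospital_nf_noncase_dad: float = 6 / 273369
    p_hospital_nf_noncase_other: float = 4 / 273369
    p_background_hospitalization: float = 0.3
    confounder_rates: ConfounderRates = Field(default_factory=ConfounderRates)
    ohip_case_distribution: dict[str, float] = Field(
        default_factory=lambda: dict(CASE_OHIP_DISTRIBUTION)
    )
    ohip_noncase_distribution: dict[str, float] = Field(
        default_factory=lambda: dict(NONCASE_OHIP_DISTRIBUTION)
    )
    encounters_per_patient_year: EncounterRates = Field(default_factory=EncounterRates)
    generate_claims: bool = True
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SyntheticConfig":
        probs = [
            self.prevalence_confirmed,
            self.prevalence_possible,
            self.p_cpp_documented,
            self.p_cpp_documented_possible,
            self.p_hospital_coded,
            self.p_dad_given_coded,
            self.p_hospital_nf_noncase_dad,
            self.p_hospital_nf_noncase_other,
            self.p_background_hospitalization,
        ] + list(self.confounder_rates.model_dump().values())
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.prevalence_confirmed + self.prevalence_possible > 1:
            raise ValueError("prevalences sum past 1")
        for name, dist in (
            ("ohip_case_distribution", self.ohip_case_distribution),
            ("ohip_noncase_distribution", self.ohip_noncase_distribution),
        ):
            if dist and not math.isclose(sum(dist.values()), 1.0, abs_tol=1e-6):
                raise ValueError(f"{name} must sum to 1")
        return self


# Demographic moments by status group: (age mean, age sd, follow-up mean,
# follow-up sd, P(female)).
_DEMOGRAPHICS = {
    TrueStatus.confirmed: (39.3, 23.0, 7.09, 3.2, 0.507),
    TrueStatus.possible: (41.1, 24.8, 8.97, 5.3, 0.514),
    None: (43.9, 23.0, 6.45, 3.5, 0.558),
}


class _Sampler:
    """Categorical sampler via inverse CDF (fast repeated draws)."""

    def __init__(self, dist: dict[str, float]):
        self.codes = list(dist)
        self.cum = np.cumsum(list(dist.values()))
        self.cum[-1] = 1.0

    def draw(self, rng: np.random.Generator, k: int) -> list[str]:
        ix = np.searchsorted(self.cum, rng.random(k), side="right")
        return [self.codes[i] for i in ix]


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, low: float) -> float:
    for _ in range(100):
        x = rng.normal(mean, sd)
        if x >= low:
            return x
    return low


def _random_date(rng: np.random.Generator, start: _dt.date, end: _dt.date) -> _dt.date:
    span = (end - start).days
    return start + _dt.timedelta(days=int(rng.integers(0, span + 1)))


def _nf_hospital_record(
    rng: np.random.Generator, source: HospitalSource, start: _dt.date, end: _dt.date
) -> HospitalRecord:
    date = _random_date(rng, start, end)
    if date < ICD10_CUTOVER:
        code = "237.71" if rng.random() < 0.5 else "237.7"
        version = 9
    else:
        code, version = "Q85.0", 10
    return HospitalRecord.model_construct(
        source=source, icd_version=version, codes=[code], date=date
    )


def _background_hospital_record(
    rng: np.random.Generator, start: _dt.date, end: _dt.date
) -> HospitalRecord:
    date = _random_date(rng, start, end)
    version = 9 if date < ICD10_CUTOVER else 10
    codes = _BACKGROUND_ICD[version]
    source = [HospitalSource.DAD, HospitalSource.NACRS_ED, HospitalSource.SDS][
        int(rng.integers(0, 3))
    ]
    return HospitalRecord.model_construct(
        source=source,
        icd_version=version,
        codes=[codes[int(rng.integers(0, len(codes)))]],
        date=date,
    )


def _pick(rng: np.random.Generator, items: list[str]) -> str:
    return items[int(rng.integers(0, len(items)))]


_CASE_SPECIALTIES = [
    "family_medicine",
    "family_medicine",
    "family_medicine",
    "neurology",
    "pediatrics",
    "genetics",
    "plastic_surgery",
    "dermatology",
]
_NONCASE_SPECIALTIES = ["family_medicine"] * 8 + ["dermatology", "other"]


def _claims(
    rng: np.random.Generator,
    sampler: _Sampler,
    rate: float,
    dispersion: float,
    followup_years: float,
    start: _dt.date,
    end: _dt.date,
    specialties: list[str],
) -> list[OutpatientClaim]:
    mu = rate * followup_years
    if mu <= 0:
        return []
    p = dispersion / (dispersion + mu)
    k = int(rng.negative_binomial(dispersion, p))
    if k == 0:
        return []
    codes = sampler.draw(rng, k)
    span = (end - start).days
    offsets = rng.integers(0, span + 1, size=k)
    spec_ix = rng.integers(0, len(specialties), size=k)
    return [
        OutpatientClaim.model_construct(
            code=codes[i],
            date=start + _dt.timedelta(days=int(offsets[i])),
            specialty=specialties[int(spec_ix[i])],
        )
        for i in range(k)
    ]


def generate_cohort(config: SyntheticConfig) -> list[PatientRecord]:
    """Generate a cohort of :class:`PatientRecord` with ``true_status`` set.

    Deterministic given ``config.seed``; identical configs give
    byte-identical cohorts.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    cr = config.confounder_rates
    case_sampler = _Sampler(config.ohip_case_distribution)
    noncase_sampler = _Sampler(config.ohip_noncase_distribution)
    enc = config.encounters_per_patient_year

    u_status = rng.random(n)
    p_c = config.prevalence_confirmed
    p_cp = p_c + config.prevalence_possible

    records: list[PatientRecord] = []
    for i in range(n):
        if u_status[i] < p_c:
            status: TrueStatus | None = TrueStatus.confirmed
        elif u_status[i] < p_cp:
            status = TrueStatus.possible
        else:
            status = None  # resolved to not_nf1/blank below
        age_mean, age_sd, fu_mean, fu_sd, p_f = _DEMOGRAPHICS[status]
        age = _trunc_normal(rng, age_mean, age_sd, 0.0)
        followup = _trunc_normal(rng, fu_mean, fu_sd, 1.0)
        sex = Sex.F if rng.random() < p_f else Sex.M
        end = _EXTRACTION_DATE - _dt.timedelta(days=int(rng.integers(0, 731)))
        start = end - _dt.timedelta(days=int(round(followup * 365.25)))

        docs: list[EmrDocument] = []
        hosp: list[HospitalRecord] = []
        is_case = status is TrueStatus.confirmed

        if is_case:
            if rng.random() < config.p_cpp_documented:
                docs.append(
                    EmrDocument.model_construct(
                        doc_type=DocType.cpp_problem_list,
                        date=_random_date(rng, start, end),
                        text=_pick(rng, CPP_NF1_TEMPLATES),
                    )
                )
            docs.append(
                EmrDocument.model_construct(
                    doc_type=DocType.progress_note,
                    date=_random_date(rng, start, end),
                    text=_pick(rng, CASE_NOTE_TEMPLATES),
                )
            )
            if rng.random() < config.p_hospital_coded:
                src = (
                    HospitalSource.DAD
                    if rng.random() < config.p_dad_given_coded
                    else (
                        HospitalSource.NACRS_ED
                        if rng.random() < 0.5
                        else HospitalSource.SDS
                    )
                )
                hosp.append(_nf_hospital_record(rng, src, start, end))
        elif status is TrueStatus.possible:
            if rng.random() < config.p_cpp_documented_possible:
                docs.append(
                    EmrDocument.model_construct(
                        doc_type=DocType.cpp_problem_list,
                        date=_random_date(rng, start, end),
                        text=_pick(rng, POSSIBLE_UNVETOED_CPP),
                    )
                )
            else:
                docs.append(
                    EmrDocument.model_construct(
                        doc_type=DocType.cpp_past_medical_history,
                        date=_random_date(rng, start, end),
                        text=_pick(rng, POSSIBLE_VETOED_CPP),
                    )
                )
        else:
            mentioned = False
            for kind, rate in (
                ("bare_nf", cr.bare_nf),
                ("cafe_au_lait_only", cr.cafe_au_lait_only),
                ("family_history", cr.family_history),
                ("rule_out", cr.rule_out),
                ("nf2", cr.nf2),
                ("unvetoed_mention", cr.unvetoed_mention),
            ):
                if rng.random() < rate:
                    mentioned = True
                    if kind in ("bare_nf", "cafe_au_lait_only"):
                        doc_type = DocType.progress_note
                    else:
                        doc_type = DocType.cpp_past_medical_history
                    docs.append(
                        EmrDocument.model_construct(
                            doc_type=doc_type,
                            date=_random_date(rng, start, end),
                            text=_pick(rng, CONFOUNDER_TEMPLATES[kind]),
                        )
                    )
            if rng.random() < cr.sheath_tumour_only:
                mentioned = True
                docs.append(
                    EmrDocument.model_construct(
                        doc_type=DocType.progress_note,
                        date=_random_date(rng, start, end),
                        text="benign nerve sheath tumour excised from forearm",
                    )
                )
            status = TrueStatus.not_nf1 if mentioned else TrueStatus.blank
            u = rng.random()
            if u < config.p_hospital_nf_noncase_dad:
                hosp.append(_nf_hospital_record(rng, HospitalSource.DAD, start, end))
            elif u < config.p_hospital_nf_noncase_dad + config.p_hospital_nf_noncase_other:
                src = HospitalSource.NACRS_ED if rng.random() < 0.5 else HospitalSource.SDS
                hosp.append(_nf_hospital_record(rng, src, start, end))

        if rng.random() < config.p_background_hospitalization:
            hosp.append(_background_hospital_record(rng, start, end))

        claims: list[OutpatientClaim] = []
        if config.generate_claims:
            claims = _claims(
                rng,
                case_sampler if is_case else noncase_sampler,
                enc.case if is_case else enc.non_case,
                enc.nb_dispersion,
                followup,
                start,
                end,
                _CASE_SPECIALTIES if is_case else _NONCASE_SPECIALTIES,
            )

        records.append(
            PatientRecord.model_construct(
                patient_id=f"P{i:07d}",
                age_years=round(age, 2),
                sex=sex,
                emr_documents=docs,
                outpatient_claims=claims,
                hospital_records=hosp,
                record_start=start,
                record_end=end,
                true_status=status,
            )
        )
    return records


def truth_labels(
    records: list[PatientRecord], count_possible_positive: bool = False
) -> dict[str, bool]:
    """Binary truth per patient: confirmed cases are positive (optionally
    also possible cases, for sensitivity analyses); not-NF1 and blank are
    negative."""
    positive = {TrueStatus.confirmed}
    if count_possible_positive:
        positive.add(TrueStatus.possible)
    return {r.patient_id: r.true_status in positive for r in records}


def end_to_end_report(
    config: SyntheticConfig,
    algorithm: str,
    count_possible_positive: bool = False,
) -> DiagnosticReport:
    """Generate a cohort, run the named algorithm, and score it.

    ``algorithm`` is ``"emr_cpp"`` (the CPP classifier with default term
    sets), ``"emr_flag"`` (the liberal flag search), or a name from
    :func:`casefinder.claims_rules.builtin_algorithms`.
    """
    records = generate_cohort(config)
    if algorithm == "emr_cpp":
        inclusions = text_search.default_cpp_inclusions()
        exclusions = text_search.default_cpp_exclusions()
        pred = {
            r.patient_id: text_search.classify_cpp(r, inclusions, exclusions)
            for r in records
        }
    elif algorithm == "emr_flag":
        terms = text_search.default_flag_terms()
        pred = {r.patient_id: text_search.flag_chart(r, terms).flagged for r in records}
    else:
        catalogue = claims_rules.builtin_algorithms()
        if algorithm not in catalogue:
            raise KeyError(
                f"unknown algorithm {algorithm!r}; known: "
                f"emr_cpp, emr_flag, {', '.join(sorted(catalogue))}"
            )
        alg = catalogue[algorithm]
        pred = {r.patient_id: claims_rules.eval_algorithm(r, alg) for r in records}
    cm = confusion_matrix(truth_labels(records, count_possible_positive), pred)
    return diagnostic_report(cm)
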