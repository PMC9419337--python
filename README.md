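# casefinder

Rule-based identification of patients with **neurofibromatosis type 1
(NF1)** in primary-care electronic medical records (EMRs) and
administrative billing data, together with the validation statistics used
to grade such algorithms and a synthetic cohort generator to exercise the
whole pipeline without access to real health records.

NF1 is a common autosomal dominant multi-system disorder (population
prevalence roughly 1 in 3,000–4,000). It has hospital ICD codes (ICD-9
237.7/237.71, ICD-10 Q85.0) but **no outpatient-billing diagnostic code**
in single-payer claims systems like Ontario's OHIP, so finding NF1
patients at population scale means either searching free chart text or
combining nonspecific billing codes. This package implements both
families of algorithms for epidemiologists and health-services
researchers who need validated, auditable case definitions.

## What it implements

**Free-text chart flagging** — a liberal search over all EMR documents for
13 NF1-related terms ("NF", "NF1", "neurofibromatosis", "café-au-lait",
"Lisch", "plexiform", "MPNST", "optic glioma", ...). Three terms ("NF",
"café-au-lait", "sheath tumour") are so nonspecific — "NF" is also a
province abbreviation and a health-card verification code — that they flag
a chart only when a second distinct term co-occurs anywhere in it.

**CPP classification** — the high-accuracy algorithm. Only the problem
list and past medical history of the cumulative patient profile (CPP) are
consulted. A patient is positive iff at least one disease-term mention
(NF1 / Recklinghausen / neurofibromatosis and common misspellings, written
as SQL-LIKE patterns such as `'%neurofibr_m_tos_s%'` and
`'%[^a-z0-9]NF1[^a-z0-9]%'`) survives with no exclusion phrase ("family
history of", "rule out", "r/o", "NF2", ...) in its proximity scope; each
mention is vetoed independently.

**Claims algorithms** — a boolean rule engine over code-count atoms
("≥ *k* events with codes *C* from source *S* within any *w*-year
window"), with a built-in catalogue covering hospital-code algorithms
(DAD discharge abstracts, alone or with NACRS emergency and same-day
surgery records) and OHIP outpatient-code algorithms (codes 192, 216,
225, 709, 758, optionally restricted to specialties that treat NF1).

**Validation statistics** — from a 2×2 confusion matrix against
chart-abstracted truth: sensitivity = TP/(TP+FN), specificity =
TN/(TN+FP), PPV = TP/(TP+FP), NPV = TN/(TN+FN), and the false positive
rate defined among algorithm positives, FPR = FP/(TP+FP) = 1 − PPV. All
intervals are exact Clopper–Pearson (Wilson also reported for
prevalence); prevalence is reported as a proportion and "1 in N"; raw
percent agreement and Cohen's κ cover inter-rater reliability; a
code-frequency table summarizes billing behaviour.

**Synthetic cohorts** — a generator that plants confirmed/possible NF1
cases at realistic prevalence, documents them in the CPP with a
configurable probability, gives only ~31% of cases an NF hospital code,
and seeds non-cases with the confusable text that defeats naive searches.

## Worked example

```python
import datetime as dt
from casefinder import (
    EmrDocument, PatientRecord, ConfusionMatrix,
    classify_cpp, default_cpp_inclusions, default_cpp_exclusions,
    flag_chart, default_flag_terms, diagnostic_report, prevalence_estimate,
)

chart = PatientRecord(
    patient_id="example", age_years=34, sex="F",
    emr_documents=[
        EmrDocument(doc_type="cpp_problem_list", date=dt.date(2012, 3, 1),
                    text="asthma\nr/o NF1\nneurofibromatosis type 1, seen in genetics"),
        EmrDocument(doc_type="progress_note", date=dt.date(2013, 7, 9),
                    text="multiple café-au-lait macules, axillary freckling"),
    ],
    record_start=dt.date(2008, 1, 1), record_end=dt.date(2016, 3, 31),
)
res = flag_chart(chart, default_flag_terms())
print("flagged:", res.flagged, "| terms:", sorted(res.matched_terms))
print("cpp positive:", classify_cpp(chart, default_cpp_inclusions(), default_cpp_exclusions()))

rep = diagnostic_report(ConfusionMatrix(tp=60, tn=273354, fn=11, fp=15))
print("sensitivity:", rep.sensitivity.display())
print("ppv:        ", rep.ppv.display())
print("fpr:        ", rep.fpr.display())
pe = prevalence_estimate(71, 273440)
print(f"prevalence: 1 in {pe.one_in} (exact CI 1 in {pe.one_in_low_exact} to 1 in {pe.one_in_high_exact})")
```

prints

```
flagged: True | terms: ['NF1', 'axillary freckling', 'café-au-lait', 'neurofibroma', 'neurofibromatosis']
cpp positive: True
sensitivity: 85 (74–92)
ppv:         80 (69–88)
fpr:         20 (12–31)
prevalence: 1 in 3851 (exact CI 1 in 4931 to 1 in 3053)
```

The chart is flagged (several distinct terms co-occur), and the CPP
classifier returns positive because the third problem-list entry is an
unvetoed disease mention — the "r/o NF1" entry alone would have been
excluded. The accuracy numbers come from a confusion matrix of 60 true
positives, 11 false negatives and 15 false positives among 273,440
patients: sensitivity 85% (exact 95% CI 74–92%), PPV 80% (69–88%), FPR
20%, and a confirmed-case prevalence of 1 in 3,851.

A CLI mirrors the library:

```
casefinder simulate --n 20000 --seed 7 --out cohort.jsonl
casefinder flag     --cohort cohort.jsonl --out flags.csv
casefinder classify --cohort cohort.jsonl --out decisions.csv
casefinder evaluate --cohort cohort.jsonl --out claims.csv
casefinder validate --cohort cohort.jsonl --pred decisions.csv --out report.json
casefinder report   --counts counts.csv
```

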