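# Methods

## The case-finding problem

NF1 has no outpatient-billing diagnostic code in OHIP-style claims data,
and its hospital ICD codes (237.7, 237.71, Q85.0) appear only when an
admission, emergency visit or day surgery is attributed to NF1 — which
happens for a minority of patients. Case identification therefore leans
on free chart text, where the disease terms are confounded by
abbreviation collisions ("NF" the province / health-card code), isolated
findings ("café-au-lait" without NF1), family-history notes, rule-out
phrasing, and the distinct disorder NF2. The package's two text
algorithms and the claims rule engine formalize exactly these mechanics.

## Text matching

**Pattern dialect.** Term patterns are SQL LIKE strings: `%` matches any
run (including empty), `_` one character, `[...]`/`[^...]` character
classes, anything else is literal; a pattern with no wildcards matches
only a whole trimmed field. This dialect was chosen so rule files can
carry the patterns exactly as they are written in EMR search tooling.
Patterns compile to anchored regular expressions; the span finder returns
minimal matching substrings for `%...%` patterns, while patterns anchored
at a field edge (or wildcard-free) are applied per *entry* — CPP fields
are newline/semicolon-delimited lists, and the entry is the natural field
unit. The engine is tested against an independent brute-force LIKE
matcher by exhaustive enumeration of all strings up to length 6 over a
small alphabet.

**Folding.** Matching is case-insensitive and accent-folded by default
(NFKD decomposition, combining marks stripped, lowercased), so
"Café-au-lait" ≡ "cafe-au-lait". Span offsets are mapped back to the
original text through a per-character index map; ASCII text takes a fast
path.

**Flagging rule.** A chart is flagged if any non-ambiguous term matches,
or at least two distinct term labels match across the whole chart
(chart-level co-occurrence — the hits may be in different documents,
which is deliberately liberal: flagging exists to hand charts to human
abstractors, and recall is the priority). The ambiguous trio is "NF",
"café-au-lait" and "sheath tumour".

**CPP classifier.** Only `cpp_problem_list` and
`cpp_past_medical_history` documents are consulted. Each inclusion
mention is vetoed independently by any exclusion phrase within scope, and
one surviving mention makes the patient positive; this per-mention rule
means "r/o NF1" in one entry cannot poison "NF1, seen in genetics" in
another. Exclusion phrases match with word-boundary checks at
alphanumeric phrase edges (so "not" cannot fire inside "note"). The
default proximity scope is the *same entry*; a character-window mode
(default 50 characters each side of the mention) is available per rule,
since "close proximity" admits both readings and entry structure is the
more faithful unit in problem-list text. This is deliberately not
general clinical NLP: no part-of-speech negation detection, just phrase
proximity, which is what makes the algorithm portable and auditable.

The shipped inclusion list is NF1 (four anchoring variants: exact,
prefix, suffix, infix, all guarded by `[^a-z0-9]` so "NF1" never fires
inside a longer token), "recklinghausen", and "neurofibromatosis" with
three recurring misspellings. The liberal flag set carries the 13
standard terms plus a standalone "sheath tumour" entry so the ambiguity
constraint can apply to bare "sheath tumour" text that the full
"peripheral nerve sheath tumor" term would miss. "not", "no sign of" and
"screen for" are quoted in narrative descriptions of such algorithms but
are not part of the shipped exclusion table; they are available as an
optional list (`OPTIONAL_EXCLUSION_PHRASES`).

## Claims rules

A `CodeCountAtom` is true when the patient has ≥ `min_count` qualifying
events within some window. Windows are closed intervals of
`window_years × 365.25` days anchored at each observed event date — the
standard rolling-window convention in claims work, and the choice is
brute-force testable (the implementation is checked against an O(n²)
anchor scan). Hospital atoms qualify if *any* code on the record is in
the code set; ICD matching is dot-insensitive and prefix-tolerant
("Q850" ≡ "Q85.0"), toggleable per atom, because discharge-abstract
extracts vary in dot usage. Specialty restriction applies to OHIP atoms
only, against a closed vocabulary; unknown specialties raise at
construction rather than silently never matching.

The built-in catalogue contains the six well-defined reference
algorithms: DAD-only ("cihi"), DAD∨NACRS∨SDS, 1-OHIP-ever,
DAD ∨ 2-OHIP-by-specialist-ever, DAD ∨ 4-OHIP-in-3-years, and
OHIP-225 ∧ OHIP-758-by-specialist. Published tabulations of these
algorithms contain two rows with identical labels but different counts
and one row whose sensitivity/specificity cells appear transposed; those
rows are not shipped.

## Statistics

Point estimates are exact integer ratios; display rounding is half-up
(integer percent for accuracy tables, one decimal for code shares) and
never feeds back into computation. Binomial CIs are Clopper–Pearson
exact (beta quantiles, via statsmodels, degenerate edges pinned to 0/1),
which reproduces the reference intervals 74–92 (60/71) and 69–88 (60/75)
after rounding. FPR is FP/(TP+FP) = 1 − PPV, the share of
algorithm-positives that are not confirmed cases — the only definition
consistent with 20% from 15 false positives among 75 positives.
Prevalence reports both exact and Wilson intervals in proportion and
"1 in N" form; neither method reproduces the reference "1 in 3107 to
1 in 4921" bounds exactly (exact gives 1 in 3053–4931, Wilson 1 in
3054–4857), so both are reported and the discrepancy is documented rather
than chased. Cohen's κ uses the marginal-product expected agreement and
is undefined (None) when expected agreement is 1; it is cross-checked
against scikit-learn's implementation.

## Synthetic cohorts

The generator emulates a rostered primary-care population observed up to
a fixed extraction date:

| Parameter | Default | Meaning |
|---|---|---|
| `prevalence_confirmed` | 71/273,440 | confirmed NF1 cases |
| `prevalence_possible` | 37/273,440 | possible-NF1 charts |
| `p_cpp_documented` | 60/71 ≈ 0.845 | confirmed case has an unvetoed CPP disease term (sets EMR sensitivity) |
| `p_cpp_documented_possible` | 8/37 | possible case has an unvetoed CPP mention (the main false-positive source) |
| `p_hospital_coded` | 22/71 ≈ 0.31 | confirmed case ever has an NF-coded hospital event |
| `p_dad_given_coded` | 15/22 | NF-coded cases whose code sits on a discharge abstract |
| `confounder_rates.*` | 10⁻⁴–3·10⁻³ | per-type rates of bare-NF, café-au-lait-only, family-history, rule-out, NF2 and unvetoed spurious mentions among non-cases |
| `encounters_per_patient_year` | case 56, non-case 4 | outpatient claim intensity (negative binomial, dispersion 1.5) |

Ages are truncated normals matching the per-group means/SDs (39.3 ± 23
confirmed, 41.1 ± 24.8 possible, 43.9 ± 23 otherwise; only these moments
are published, so only these are matched — the test suite compares
against the analytic truncated-normal mean, not the untruncated one).
Sex is Bernoulli (55.8% female overall), follow-up truncated normal
≥ 1 year, record spans closed intervals ending within two years of the
2016-03-31 extraction date. Hospital records switch from ICD-9 to ICD-10
at 2002-04-01. The case encounter rate is high because confirmed cases
average ~400 encounters over ~7 years of follow-up; a single shared rate
cannot express that against a primary-care background, hence the
case/non-case split. Confounder rates were set once so that the order of
magnitude of flagged-but-not-NF1 charts resembles a realistic primary
care population (a few per thousand); they are not fitted quantities.

Text is template-based — phrase banks per category, deterministic and
auditable, never language-model generated. The vetoed templates
(family-history, rule-out, NF2) are co-designed with the default
exclusion rules, and a dedicated test asserts every planted vetoed
template is actually vetoed and every documented-case template is
actually detected. "Possible" cases are CPP-mention-without-detail or
relative-of-case templates and count as evaluation-negative by default
(only confirmed cases are true positives), with a switch
(`count_possible_positive`) for sensitivity analyses.

What the generator does *not* emulate: real clinical prose (templates
are short and clean, so text-matching performance on synthetic data is
an upper bound), French or other non-English documentation, coding drift
over time, within-patient correlation of billing codes, and
re-identification-realistic content. Passing tests therefore demonstrate
the algorithms' logic and calibration under the stated structure, not
their accuracy on any real EMR.

## Problem sizes and determinism

Identical configs and seeds give byte-identical cohorts (single numpy
`default_rng` stream). The parameter-recovery tests run at 120,000
patients and the acceptance script's end-to-end run at 150,000 with
claims generation off (claims are irrelevant to the text pipeline) plus
a 20,000-patient claims-on run at elevated prevalence for billing-share
recovery; these sizes give a few dozen cases — enough for 3-standard-error
Monte-Carlo checks while keeping the default suite fast on one core.

## Known limitations

* Exclusion matching is phrase-and-proximity only; hedged or creative
  negations outside the phrase list are not caught.
* The LIKE dialect has no escape character; a literal `%`, `_` or `[`
  cannot be matched (none occurs in any shipped term).
* "1 in N" CI bounds inherit the rounding of the proportion bounds.
* The CSV cohort dialect stores documents in a fourth table
  (`documents.csv`) beside patients/claims/hospital records, since chart
  text cannot round-trip through a flat patient table.
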