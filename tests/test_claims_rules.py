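"""The code-count rule engine and the built-in algorithm catalogue."""

import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from casefinder import (
    ClaimsAlgorithm,
    CodeCountAtom,
    HospitalRecord,
    OutpatientClaim,
    PatientRecord,
    builtin_algorithms,
    count_in_window,
    eval_algorithm,
    eval_atom,
)
from casefinder.claims_rules import NF_ICD_CODES, BoolNode

SPAN = dict(record_start=dt.date(1995, 1, 1), record_end=dt.date(2016, 1, 1))


def patient(claims=(), hospital=(), pid="c1"):
    return PatientRecord(
        patient_id=pid,
        age_years=30.0,
        sex="M",
        outpatient_claims=list(claims),
        hospital_records=list(hospital),
        **SPAN,
    )


def claim(code, date, specialty="family_medicine"):
    return OutpatientClaim(code=code, date=date, specialty=specialty)


def hosp(codes, date, source="DAD"):
    return HospitalRecord(
        source=source, icd_version=9 if date < dt.date(2002, 4, 1) else 10,
        codes=codes, date=date,
    )


def brute_count_in_window(dates, w):
    """Independent O(n^2) tally over all anchor choices."""
    if w == "ever":
        return len(dates)
    width = dt.timedelta(days=w * 365.25)
    return max((sum(1 for d in dates if a <= d <= a + width) for a in dates), default=0)


class TestCountInWindow:
    @pytest.mark.parametrize(
        "dates,w,expected",
        [
            ([dt.date(2010, 1, 1), dt.date(2011, 6, 1), dt.date(2012, 12, 30)], 3, 3),
            ([dt.date(2010, 1, 1)], 1, 1),
            ([dt.date(2000, 1, 1), dt.date(2005, 1, 1), dt.date(2010, 1, 1)], 3, 1),
            ([], "ever", 0),
            ([dt.date(2010, 1, 1)] * 4, "ever", 4),
        ],
    )
    def test_examples(self, dates, w, expected):
        assert count_in_window(dates, w) == expected

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError):
            count_in_window([dt.date(2010, 1, 1)], -1)

    @settings(derandomize=True, max_examples=200)
    @given(
        offsets=st.lists(st.integers(0, 4000), min_size=0, max_size=40),
        w=st.sampled_from([0.5, 1, 2, 3]),
    )
    def test_matches_brute_force(self, offsets, w):
        dates = [dt.date(2000, 1, 1) + dt.timedelta(days=o) for o in offsets]
        assert count_in_window(dates, w) == brute_count_in_window(sorted(dates), w)


class TestEvalAtom:
    def test_hospital_any_code_on_record(self):
        p = patient(hospital=[hosp(["Q85.0", "I10"], dt.date(2010, 1, 1))])
        atom = CodeCountAtom(source="DAD", code_set=set(NF_ICD_CODES))
        assert eval_atom(p, atom)

    def test_specialty_constraint(self):
        p = patient(claims=[claim("709", dt.date(2010, 1, 1)), claim("709", dt.date(2011, 1, 1))])
        unrestricted = CodeCountAtom(source="OHIP", code_set={"709"}, min_count=2)
        starred = CodeCountAtom(
            source="OHIP", code_set={"709"}, min_count=2,
            specialty_set={"neurology", "genetics"},
        )
        assert eval_atom(p, unrestricted)
        assert not eval_atom(p, starred)

    def test_empty_patient_false_for_any_atom(self):
        p = patient()
        for atom in [
            CodeCountAtom(source=s, code_set={"Q85.0"}) for s in ("DAD", "NACRS_ED", "SDS")
        ] + [CodeCountAtom(source="OHIP", code_set={"709"})]:
            assert not eval_atom(p, atom)

    def test_icd_prefix_tolerance(self):
        p = patient(hospital=[hosp(["2377"], dt.date(2000, 1, 1))])
        tolerant = CodeCountAtom(source="DAD", code_set=set(NF_ICD_CODES))
        strict = CodeCountAtom(source="DAD", code_set=set(NF_ICD_CODES), icd_prefix_match=False)
        assert eval_atom(p, tolerant)
        assert not eval_atom(p, strict)

    def test_specialty_on_hospital_atom_rejected(self):
        with pytest.raises(ValueError):
            CodeCountAtom(source="DAD", code_set={"Q85.0"}, specialty_set={"neurology"})

    def test_unknown_specialty_fails_loudly(self):
        with pytest.raises(ValueError, match="unknown special"):
            CodeCountAtom(source="OHIP", code_set={"709"}, specialty_set={"astrology"})


class TestCatalogue:
    def test_contains_reference_algorithms(self):
        algs = builtin_algorithms()
        assert len(algs) >= 6
        assert {
            "cihi", "cihi_nacrs_sds", "ohip_1_ever",
            "cihi_or_2ohip_spec_ever", "cihi_or_4ohip_3y", "ohip225_and_758spec_ever",
        } <= set(algs)

    def test_hospital_atoms_use_nf_icd_set(self):
        def leaves(node):
            if isinstance(node, CodeCountAtom):
                yield node
            else:
                for c in node.children:
                    yield from leaves(c)

        for alg in builtin_algorithms().values():
            for atom in leaves(alg.expr):
                if atom.source != "OHIP":
                    assert atom.code_set == set(NF_ICD_CODES)
                else:
                    assert atom.code_set <= {"192", "216", "225", "709", "758"}

    def test_all_false_on_empty_patient(self):
        p = patient()
        assert all(not eval_algorithm(p, a) for a in builtin_algorithms().values())

    def test_sds_only_patient_splits_cihi_rows(self):
        p = patient(hospital=[hosp(["Q85.0"], dt.date(2010, 1, 1), source="SDS")])
        algs = builtin_algorithms()
        assert not eval_algorithm(p, algs["cihi"])
        assert eval_algorithm(p, algs["cihi_nacrs_sds"])

    def test_ohip_pair_algorithm(self):
        p = patient(
            claims=[
                claim("225", dt.date(2010, 1, 1), "family_medicine"),
                claim("758", dt.date(2012, 1, 1), "genetics"),
            ]
        )
        assert eval_algorithm(p, builtin_algorithms()["ohip225_and_758spec_ever"])

    def test_specialty_restricted_pair_fails_without_specialist(self):
        p = patient(
            claims=[
                claim("709", dt.date(2010, 1, 1), "family_medicine"),
                claim("709", dt.date(2011, 1, 1), "family_medicine"),
            ]
        )
        atom = CodeCountAtom(
            source="OHIP",
            code_set={"192", "216", "225", "709", "758"},
            min_count=2,
            specialty_set={"neurology", "neurosurgery", "pediatrics",
                           "genetics", "plastic_surgery", "general_surgery"},
        )
        assert not eval_atom(p, atom)


# ---------------------------------------------------------------------------
# Monotonicity invariants

_DATES = st.lists(
    st.integers(0, 5000).map(lambda o: dt.date(2000, 1, 1) + dt.timedelta(days=o)),
    min_size=0,
    max_size=15,
)


@settings(derandomize=True, max_examples=150)
@given(
    offsets=_DATES,
    codes=st.lists(st.sampled_from(["709", "225", "758", "999"]), min_size=0, max_size=15),
    min_count=st.integers(1, 4),
    w=st.sampled_from([1, 2, 3, "ever"]),
)
def test_atom_monotonicity(offsets, codes, min_count, w):
    """Enlarging the code set, lengthening the window, or lowering the
    required count never flips a true atom to false; restricting by
    specialty never flips false to true."""
    events = [claim(c, d) for c, d in zip(codes, offsets)]
    p = patient(claims=events)
    base = CodeCountAtom(source="OHIP", code_set={"709"}, min_count=min_count, window_years=w)
    r = eval_atom(p, base)
    bigger_codes = base.model_copy(update={"code_set": {"709", "225", "758"}})
    assert eval_atom(p, bigger_codes) or not r
    lower_count = base.model_copy(update={"min_count": 1})
    assert eval_atom(p, lower_count) or not r
    if w != "ever":
        longer = base.model_copy(update={"window_years": float(w) + 1})
        assert eval_atom(p, longer) or not r
    starred = base.model_copy(update={"specialty_set": {"neurology"}})
    assert r or not eval_atom(p, starred)


@settings(derandomize=True, max_examples=100)
@given(
    offsets=_DATES,
    sources=st.lists(st.sampled_from(["DAD", "NACRS_ED", "SDS"]), min_size=0, max_size=6),
)
def test_or_dominance_cihi_subset_of_broader(offsets, sources):
    """Every CIHI-positive patient is positive under CIHI-or-NACRS-or-SDS."""
    hs = [hosp(["Q85.0"], d, source=s) for d, s in zip(offsets, sources)]
    p = patient(hospital=hs)
    algs = builtin_algorithms()
    if eval_algorithm(p, algs["cihi"]):
        assert eval_algorithm(p, algs["cihi_nacrs_sds"])


def test_short_circuit_equals_full_evaluation():
    p = patient(hospital=[hosp(["Q85.0"], dt.date(2010, 1, 1))])
    alg = ClaimsAlgorithm(
        name="t",
        expr=BoolNode(
            op="or",
            children=[
                CodeCountAtom(source="DAD", code_set={"Q85.0"}),
                CodeCountAtom(source="OHIP", code_set={"709"}, min_count=3),
            ],
        ),
    )
    flipped = ClaimsAlgorithm(name="t2", expr=BoolNode(op="or", children=list(reversed(alg.expr.children))))
    assert eval_algorithm(p, alg) == eval_algorithm(p, flipped) is True
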