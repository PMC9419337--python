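import datetime as dt

import pytest

from casefinder import EmrDocument, PatientRecord

SPAN_START = dt.date(2000, 1, 1)
SPAN_END = dt.date(2016, 1, 1)


@pytest.fixture
def make_patient():
    """Factory for a patient whose documents carry the given texts.

    ``doc_types`` defaults to progress notes; pass e.g.
    ``["cpp_problem_list"]`` to place text in CPP sections.
    """

    def _make(texts=(), doc_types=None, pid="p1", **kwargs):
        doc_types = doc_types or ["progress_note"] * len(texts)
        docs = [
            EmrDocument(doc_type=t, date=dt.date(2010, 6, 1), text=s)
            for s, t in zip(texts, doc_types)
        ]
        defaults = dict(
            patient_id=pid,
            age_years=40.0,
            sex="F",
            emr_documents=docs,
            record_start=SPAN_START,
            record_end=SPAN_END,
        )
        defaults.update(kwargs)
        return PatientRecord(**defaults)

    return _make
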