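"""Cohort and configuration file readers/writers.

Two cohort dialects, both plain text:

* ``jsonl`` — one JSON object per line, one patient per object (nested
  documents/claims/hospital records).
* ``csv`` — a directory of four joined tables (``patients.csv``,
  ``documents.csv``, ``claims.csv``, ``hospital_records.csv``) keyed on
  ``patient_id``.

Term-set, exclusion-rule and algorithm-catalogue files are YAML or JSON.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import yaml

from .claims_rules import ClaimsAlgorithm
from .data_model import (
    EmrDocument,
    HospitalRecord,
    OutpatientClaim,
    PatientRecord,
)
from .text_search import ExclusionRule, TermPattern

__all__ = [
    "read_cohort",
    "write_cohort",
    "load_terms",
    "load_exclusions",
    "load_algorithms",
    "CohortFormatError",
]

_CSV_TABLES = ("patients", "documents", "claims", "hospital_records")


class CohortFormatError(ValueError):
    """Malformed cohort file; message names the offending line or row."""


# ---------------------------------------------------------------------------
# JSONL dialect

def _read_jsonl(path: Path) -> list[PatientRecord]:
    records = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                records.append(PatientRecord.model_validate(json.loads(line)))
            except Exception as exc:
                raise CohortFormatError(f"{path}:{lineno}: {exc}") from exc
    return records


def _write_jsonl(records: list[PatientRecord], path: Path) -> None:
    with path.open("w") as fh:
        for rec in records:
            fh.write(json.dumps(rec.model_dump(mode="json"), ensure_ascii=False) + "\n")


# ---------------------------------------------------------------------------
# CSV-trio dialect (patients + child tables joined on patient_id)

def _write_csv(records: list[PatientRecord], directory: Path) -> None:
    directory.mkdir(parents=True, exist_ok=True)
    with (directory / "patients.csv").open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["patient_id", "age_years", "sex", "record_start", "record_end", "true_status"]
        )
        for r in records:
            w.writerow(
                [
                    r.patient_id,
                    r.age_years,
                    r.sex.value,
                    r.record_start.isoformat(),
                    r.record_end.isoformat(),
                    r.true_status.value if r.true_status else "",
                ]
            )
    with (directory / "documents.csv").open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "doc_type", "date", "text"])
        for r in records:
            for d in r.emr_documents:
                w.writerow([r.patient_id, d.doc_type.value, d.date.isoformat(), d.text])
    with (directory / "claims.csv").open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "code", "date", "specialty"])
        for r in records:
            for c in r.outpatient_claims:
                w.writerow([r.patient_id, c.code, c.date.isoformat(), c.specialty])
    with (directory / "hospital_records.csv").open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "source", "icd_version", "codes", "date"])
        for r in records:
            for h in r.hospital_records:
                w.writerow(
                    [
                        r.patient_id,
                        h.source.value,
                        h.icd_version,
                        "|".join(h.codes),
                        h.date.isoformat(),
                    ]
                )


def _read_csv(directory: Path) -> list[PatientRecord]:
    def rows(name: str) -> list[dict]:
        p = directory / f"{name}.csv"
        if not p.exists():
            raise CohortFormatError(f"missing table {p}")
        with p.open(newline="") as fh:
            return list(csv.DictReader(fh))

    children: dict[str, dict[str, list]] = {t: {} for t in _CSV_TABLES[1:]}
    for row in rows("documents"):
        children["documents"].setdefault(row["patient_id"], []).append(
            EmrDocument(doc_type=row["doc_type"], date=row["date"], text=row["text"])
        )
    for row in rows("claims"):
        children["claims"].setdefault(row["patient_id"], []).append(
            OutpatientClaim(code=row["code"], date=row["date"], specialty=row["specialty"])
        )
    for row in rows("hospital_records"):
        children["hospital_records"].setdefault(row["patient_id"], []).append(
            HospitalRecord(
                source=row["source"],
                icd_version=int(row["icd_version"]),
                codes=row["codes"].split("|"),
                date=row["date"],
            )
        )
    records = []
    seen = set()
    for row in rows("patients"):
        pid = row["patient_id"]
        seen.add(pid)
        records.append(
            PatientRecord(
                patient_id=pid,
                age_years=float(row["age_years"]),
                sex=row["sex"],
                emr_documents=children["documents"].get(pid, []),
                outpatient_claims=children["claims"].get(pid, []),
                hospital_records=children["hospital_records"].get(pid, []),
                record_start=row["record_start"],
                record_end=row["record_end"],
                true_status=row["true_status"] or None,
            )
        )
    orphans = set().union(*(children[t].keys() for t in children)) - seen
    if orphans:
        raise CohortFormatError(
            f"child rows reference unknown patient_id(s): {sorted(orphans)[:5]}"
        )
    return records


def read_cohort(path: str | Path, dialect: str | None = None) -> list[PatientRecord]:
    """Read a cohort file.  ``dialect`` is ``"jsonl"`` or ``"csv"``; when
    omitted it is inferred (a directory means csv)."""
    path = Path(path)
    if dialect is None:
        dialect = "csv" if path.is_dir() else "jsonl"
    if dialect == "jsonl":
        return _read_jsonl(path)
    if dialect == "csv":
        return _read_csv(path)
    raise CohortFormatError(f"unknown dialect {dialect!r}")


def write_cohort(
    records: list[PatientRecord], path: str | Path, dialect: str = "jsonl"
) -> None:
    path = Path(path)
    if dialect == "jsonl":
        _write_jsonl(records, path)
    elif dialect == "csv":
        _write_csv(records, path)
    else:
        raise CohortFormatError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Rule/term/algorithm files

def _load_structured(path: str | Path):
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def load_terms(path: str | Path) -> list[TermPattern]:
    return [TermPattern.model_validate(d) for d in _load_structured(path)]


def load_exclusions(path: str | Path) -> list[ExclusionRule]:
    return [ExclusionRule.model_validate(d) for d in _load_structured(path)]


def load_algorithms(path: str | Path) -> dict[str, ClaimsAlgorithm]:
    algs = [ClaimsAlgorithm.model_validate(d) for d in _load_structured(path)]
    names = [a.name for a in algs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate algorithm names in catalogue")
    return {a.name: a for a in algs}
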