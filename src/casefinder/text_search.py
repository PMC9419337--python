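"""Free-text NF1 search: liberal chart flagging and the CPP classifier.

Two rule-based algorithms operate on chart text:

* **Chart flagging** (:func:`flag_chart`) — a liberal search over *all* EMR
  documents for thirteen NF1-related terms.  Three terms ("NF",
  "café-au-lait", "sheath tumour") are so nonspecific in clinical text —
  "NF" is also a province abbreviation and a health-card verification
  code — that a chart is flagged on them only when a second, distinct term
  also appears anywhere in the chart.

* **CPP classification** (:func:`classify_cpp`) — the high-accuracy
  algorithm.  Only the problem-list and past-medical-history sections of
  the cumulative patient profile are consulted.  A patient is positive if
  at least one disease-term mention (NF1 / Recklinghausen /
  neurofibromatosis and common misspellings) survives with no exclusion
  phrase (family history, rule-out, negation, NF2, ...) in its proximity
  scope; each mention is vetoed independently.

Patterns use the SQL LIKE dialect (``%`` any run, ``_`` one character,
``[^...]``/``[...]`` character classes, otherwise literal; a wildcard-free
pattern matches only a whole trimmed field).  Matching is case-insensitive
and accent-folded by default, so "café-au-lait" and "Cafe-au-lait" are the
same token.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache

from pydantic import BaseModel, Field, PositiveInt

from .data_model import CPP_CLASSIFIER_DOC_TYPES, EmrDocument, PatientRecord

__all__ = [
    "TermPattern",
    "ExclusionRule",
    "ExclusionScope",
    "FlagResult",
    "LikePatternError",
    "compile_like_pattern",
    "find_term_mentions",
    "flag_chart",
    "classify_cpp",
    "default_flag_terms",
    "default_cpp_inclusions",
    "default_cpp_exclusions",
    "split_entries",
    "fold",
]


class LikePatternError(ValueError):
    """Malformed LIKE pattern; carries the offending offset."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} at offset {offset}")
        self.offset = offset


class TermPattern(BaseModel):
    """One search-term row: a label, a LIKE pattern, and an ambiguity flag.

    Several rows may share a label (e.g. four anchoring variants of "NF1");
    flagging counts *distinct labels*.  ``ambiguous=True`` means the term
    contributes to flagging only alongside a second distinct label.
    """

    label: str
    pattern: str = Field(min_length=1)
    ambiguous: bool = False


class ExclusionScope(str, Enum):
    same_entry = "same_entry"
    window = "window"


class ExclusionRule(BaseModel):
    """A literal phrase that vetoes disease mentions in its proximity scope."""

    phrase: str = Field(min_length=1)
    scope: ExclusionScope = ExclusionScope.same_entry
    window_chars: PositiveInt = 50


@dataclass(frozen=True)
class Mention:
    """A matched term occurrence: document index, character span, label."""

    doc_index: int
    start: int
    end: int
    label: str


@dataclass
class FlagResult:
    flagged: bool
    matched_terms: set[str] = field(default_factory=set)
    match_spans: list[Mention] = field(default_factory=list)


# --------------------------------------------------------------------------
# Accent/case folding with an offset map back into the original text.

def _fold_char(ch: str) -> str:
    decomposed = unicodedata.normalize("NFKD", ch)
    return "".join(c for c in decomposed if not unicodedata.combining(c)).lower()


def fold(text: str) -> str:
    """Lowercase and strip diacritics ("café" -> "cafe")."""
    if text.isascii():
        return text.lower()
    return "".join(_fold_char(ch) for ch in text)


def _fold_with_map(text: str) -> tuple[str, list[int] | range]:
    """Fold and return, per folded character, its source index in ``text``.

    The map carries one extra trailing entry (``len(text)``) so folded end
    offsets translate directly.
    """
    if text.isascii():
        return text.lower(), range(len(text) + 1)
    out: list[str] = []
    idx: list[int] = []
    for i, ch in enumerate(text):
        f = _fold_char(ch)
        out.append(f)
        idx.extend([i] * len(f))
    idx.append(len(text))
    return "".join(out), idx


# --------------------------------------------------------------------------
# LIKE dialect -> regular expression

def _class_body(inner: str, offset: int) -> str:
    if not inner:
        raise LikePatternError("empty character class", offset)
    out = []
    for ch in inner:
        out.append("\\" + ch if ch in r"\]^" else ch)  # '-' kept: range semantics
    return "".join(out)


def _translate(pattern: str, *, lazy_percent: bool) -> str:
    star = ".*?" if lazy_percent else ".*"
    out: list[str] = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "%":
            out.append(star)
            i += 1
        elif ch == "_":
            out.append(".")
            i += 1
        elif ch == "[":
            j = pattern.find("]", i + 1)
            if j < 0:
                raise LikePatternError("unclosed character class", i)
            inner = pattern[i + 1 : j]
            neg = inner.startswith("^")
            body = _class_body(inner[1:] if neg else inner, i)
            out.append("[" + ("^" if neg else "") + body + "]")
            i = j + 1
        else:
            out.append(re.escape(ch))
            i += 1
    return "".join(out)


class CompiledPattern:
    """A compiled LIKE pattern: a whole-field predicate plus a span finder.

    * ``matches(s)`` — LIKE semantics over the whole string.
    * ``finditer(s)`` — minimal matching substrings.  For ``%...%``
      patterns the inner core is located anywhere; a missing leading or
      trailing ``%`` anchors the core to the field start or end; with no
      ``%`` at all the pattern must equal the whole trimmed field.
    """

    def __init__(self, pattern: str, case_insensitive: bool = True):
        self.raw = pattern
        self.case_insensitive = case_insensitive
        src = fold(pattern) if case_insensitive else pattern
        self._full = re.compile(_translate(src, lazy_percent=False), re.DOTALL)
        core = src
        self.leading = core.startswith("%")
        while core.startswith("%"):
            core = core[1:]
        self.trailing = core.endswith("%") and not core.endswith(r"\%")
        while core.endswith("%"):
            core = core[:-1]
        self.whole_field = not (self.leading or self.trailing) and "%" not in src
        body = _translate(core, lazy_percent=True)
        if not self.leading:
            body = "^" + body
        if not self.trailing:
            body = body + "$"
        self._core = re.compile(body, re.DOTALL)

    def _prep(self, s: str) -> str:
        return fold(s) if self.case_insensitive else s

    def matches(self, s: str) -> bool:
        return self._full.fullmatch(self._prep(s)) is not None

    def finditer(self, s: str) -> list[tuple[int, int]]:
        """Spans of minimal matching substrings, in original-text offsets."""
        if self.case_insensitive:
            folded, idx = _fold_with_map(s)
        else:
            folded, idx = s, list(range(len(s) + 1))
        if self.whole_field:
            stripped = folded.strip()
            lead = len(folded) - len(folded.lstrip())
            if stripped and self._core.fullmatch(stripped):
                return [(idx[lead], idx[lead + len(stripped)])]
            if not stripped and self._core.fullmatch(""):
                return [(idx[0], idx[0])]
            return []
        return [(idx[m.start()], idx[m.end()]) for m in self._core.finditer(folded)]


@lru_cache(maxsize=4096)
def compile_like_pattern(pattern: str, case_insensitive: bool = True) -> CompiledPattern:
    """Compile a LIKE-dialect pattern; raises :class:`LikePatternError` on a
    malformed character class, naming the offset.  Compiled patterns are
    cached, so repeated per-patient calls with the same term set are cheap."""
    return CompiledPattern(pattern, case_insensitive)


# --------------------------------------------------------------------------
# Entry splitting (CPP fields are newline/semicolon-delimited lists)

_ENTRY_SEP = re.compile(r"[;\n]")


def split_entries(text: str) -> list[tuple[int, int]]:
    """Offset spans of newline/semicolon-delimited entries, including empties."""
    spans = []
    start = 0
    for m in _ENTRY_SEP.finditer(text):
        spans.append((start, m.start()))
        start = m.end()
    spans.append((start, len(text)))
    return spans


# --------------------------------------------------------------------------
# Term search over documents

def _compiled(terms: list[TermPattern]) -> list[tuple[TermPattern, CompiledPattern]]:
    return [(t, compile_like_pattern(t.pattern)) for t in terms]


def _mentions_in_text(
    text: str, compiled: list[tuple[TermPattern, CompiledPattern]]
) -> list[tuple[int, int, str]]:
    """All (start, end, label) mentions in one text field.

    Fully-floating ``%...%`` patterns scan the whole text; anchored or
    wildcard-free patterns treat each newline/semicolon entry as the field.
    """
    found: set[tuple[int, int, str]] = set()
    entries = split_entries(text)
    for term, cp in compiled:
        if cp.leading and cp.trailing:
            for s, e in cp.finditer(text):
                found.add((s, e, term.label))
        else:
            for es, ee in entries:
                for s, e in cp.finditer(text[es:ee]):
                    found.add((es + s, es + e, term.label))
    return sorted(found)


def find_term_mentions(
    doc: EmrDocument, terms: list[TermPattern]
) -> list[tuple[str, tuple[int, int]]]:
    """All term mentions in one document as (label, (start, end)), sorted by
    offset, duplicates removed."""
    return [
        (label, (s, e)) for s, e, label in _mentions_in_text(doc.text, _compiled(terms))
    ]


def flag_chart(patient: PatientRecord, terms: list[TermPattern]) -> FlagResult:
    """Liberal chart-level flagging with the ambiguity constraint.

    A chart is flagged if any non-ambiguous term matches anywhere, or if at
    least two *distinct* term labels match across the whole chart (the
    co-occurrence is chart-level: the hits may sit in different documents).
    """
    compiled = _compiled(terms)
    ambiguous_labels = {t.label for t in terms if t.ambiguous}
    spans: list[Mention] = []
    labels: set[str] = set()
    for di, doc in enumerate(patient.emr_documents):
        for s, e, label in _mentions_in_text(doc.text, compiled):
            spans.append(Mention(doc_index=di, start=s, end=e, label=label))
            labels.add(label)
    flagged = bool(labels - ambiguous_labels) or len(labels) >= 2
    return FlagResult(flagged=flagged, matched_terms=labels, match_spans=spans)


# --------------------------------------------------------------------------
# CPP classification

def _phrase_occurrences(text_folded: str, phrase_folded: str) -> list[tuple[int, int]]:
    """Word-boundary-aware literal occurrences of a folded phrase.

    A boundary check applies only where the phrase edge is alphanumeric, so
    "r/o" will not fire inside "pr/on" but "?early" needs no letter gap
    before the '?'.
    """
    occ = []
    n = len(phrase_folded)
    if n == 0:
        return occ
    start = 0
    while True:
        i = text_folded.find(phrase_folded, start)
        if i < 0:
            return occ
        ok = True
        if phrase_folded[0].isalnum() and i > 0 and text_folded[i - 1].isalnum():
            ok = False
        j = i + n
        if phrase_folded[-1].isalnum() and j < len(text_folded) and text_folded[j].isalnum():
            ok = False
        if ok:
            occ.append((i, j))
        start = i + 1


def classify_cpp(
    patient: PatientRecord,
    inclusions: list[TermPattern],
    exclusions: list[ExclusionRule],
) -> bool:
    """CPP inclusion/exclusion classification.

    Only problem-list and past-medical-history documents are consulted.
    Every inclusion mention is vetoed independently: a mention dies if any
    exclusion phrase occurs in its scope (the same newline/semicolon entry,
    or a character window around the mention).  The patient is positive iff
    at least one mention survives.
    """
    compiled = _compiled(inclusions)
    excl_folded = [(rule, fold(rule.phrase)) for rule in exclusions]
    for doc in patient.emr_documents:
        if doc.doc_type not in CPP_CLASSIFIER_DOC_TYPES:
            continue
        text = doc.text
        folded, idx = _fold_with_map(text)
        # occurrences of each exclusion phrase, in original-text offsets
        occurrences: list[tuple[ExclusionRule, int, int]] = []
        for rule, pf in excl_folded:
            for fs, fe in _phrase_occurrences(folded, pf):
                occurrences.append((rule, idx[fs], idx[fe]))
        entries = split_entries(text)

        def entry_of(pos: int) -> int:
            for k, (es, ee) in enumerate(entries):
                if es <= pos <= ee:
                    return k
            return len(entries) - 1

        for ms, me, _label in _mentions_in_text(text, compiled):
            vetoed = False
            for rule, xs, xe in occurrences:
                if rule.scope is ExclusionScope.same_entry:
                    if entry_of(xs) == entry_of(ms):
                        vetoed = True
                        break
                else:
                    w = rule.window_chars
                    if xs <= me + w and xe >= ms - w:
                        vetoed = True
                        break
            if not vetoed:
                return True
    return False


# --------------------------------------------------------------------------
# Shipped default term sets

def default_flag_terms() -> list[TermPattern]:
    """The liberal flagging set: thirteen NF1-related terms plus the bare
    "sheath tumour" token, with "NF", "café-au-lait" and "sheath tumour"
    marked ambiguous.

    Anchored variants keep bare "NF"/"NF1" from matching inside longer
    tokens while still catching them at field edges.
    """
    t = TermPattern
    nf_variants = ["NF", "NF[^a-z0-9]%", "%[^a-z0-9]NF", "%[^a-z0-9]NF[^a-z0-9]%"]
    nf1_variants = ["NF1", "NF1[^a-z0-9]%", "%[^a-z0-9]NF1", "%[^a-z0-9]NF1[^a-z0-9]%"]
    terms = [t(label="NF", pattern=p, ambiguous=True) for p in nf_variants]
    terms += [t(label="NF1", pattern=p) for p in nf1_variants]
    terms += [
        t(label="neurofibromatosis", pattern="%neurofibr_m_tos_s%"),
        t(label="neurofibroma", pattern="%neurofibroma%"),
        t(label="café-au-lait", pattern="%caf_%au%lait%", ambiguous=True),
        t(label="Lisch", pattern="%lisch%"),
        t(label="plexiform", pattern="%plexiform%"),
        t(label="axillary freckling", pattern="%axillary freckling%"),
        t(label="inguinal freckling", pattern="%inguinal freckling%"),
        t(label="peripheral nerve sheath tumor", pattern="%peripheral nerve sheath tumo%"),
        t(
            label="malignant peripheral nerve sheath tumor",
            pattern="%malignant peripheral nerve sheath tumo%",
        ),
        t(label="sheath tumour", pattern="%sheath tumo%", ambiguous=True),
        t(label="MPNST", pattern="%mpnst%"),
        t(label="optic glioma", pattern="%optic glioma%"),
    ]
    return terms


def default_cpp_inclusions() -> list[TermPattern]:
    """CPP classifier inclusion terms: NF1 (four anchoring variants),
    Recklinghausen, and neurofibromatosis with its common misspellings."""
    t = TermPattern
    return [
        t(label="NF1", pattern="NF1"),
        t(label="NF1", pattern="NF1[^a-z0-9]%"),
        t(label="NF1", pattern="%[^a-z0-9]NF1"),
        t(label="NF1", pattern="%[^a-z0-9]NF1[^a-z0-9]%"),
        t(label="recklinghausen", pattern="%recklinghausen%"),
        t(label="neurofibromatosis", pattern="%neurofibr_m_tos_s%"),
        t(label="neurofibromatosis", pattern="%Neuro Fibromatosis%"),
        t(label="neurofibromatosis", pattern="%Neurofibiromatosis%"),
        t(label="neurofibromatosis", pattern="%neurofibomatosis%"),
    ]


#: Optional negation cues quoted in narrative descriptions of the algorithm
#: but absent from its printed rule table; not part of the default set.
OPTIONAL_EXCLUSION_PHRASES = ["not", "no sign of", "screen for"]


def default_cpp_exclusions(
    scope: ExclusionScope = ExclusionScope.same_entry, window_chars: int = 50
) -> list[ExclusionRule]:
    """Default exclusion phrases: negations, family-history and rule-out
    wording, hedging, relatives, and the distinct disease NF2."""
    phrases = [
        "negative for",
        "no evidence",
        "no history of",
        "at risk of",
        "?early",
        "family history of",
        "FMHx",
        "fhx",
        "without",
        "with out",
        "maternal",
        "paternal",
        "brother",
        "sister",
        "unconfirmed",
        "suspect",
        "rule out",
        "r/ o",
        "r/o",
        "possible",
        "possibly",
        "probable",
        "NF2",
    ]
    return [
        ExclusionRule(phrase=p, scope=scope, window_chars=window_chars) for p in phrases
    ]
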