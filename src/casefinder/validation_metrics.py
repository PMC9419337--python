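"""Diagnostic accuracy, prevalence, agreement and code-frequency statistics.

All point estimates are exact ratios of integer counts; rounding (half-up,
to integer percent for accuracy tables and one decimal for code-frequency
shares) is display-only.  Binomial confidence intervals are Clopper–Pearson
exact by default, with Wilson score intervals available alongside for
prevalence.

The false positive rate is defined *among algorithm positives*:
``fpr = fp / (tp + fp) = 1 - PPV`` — the share of flagged patients who are
not confirmed cases, which is the operationally relevant error for a
case-finding tool.
"""

from __future__ import annotations

from collections import Counter
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd
from pydantic import BaseModel
from statsmodels.stats.proportion import proportion_confint

from .data_model import ConfusionMatrix, PatientRecord

__all__ = [
    "ProportionWithCI",
    "DiagnosticReport",
    "PrevalenceEstimate",
    "confusion_matrix",
    "exact_binomial_ci",
    "wilson_ci",
    "diagnostic_report",
    "prevalence_estimate",
    "percent_agreement",
    "cohens_kappa",
    "code_frequency_table",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero, as printed tables do (84.507 -> 85)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def exact_binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper–Pearson exact binomial interval from beta quantiles.

    ``k = 0`` gives a lower bound of exactly 0; ``k = n`` an upper bound of
    exactly 1.
    """
    if not 0 <= k <= n or n < 1:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    lo, hi = proportion_confint(k, n, alpha=1 - level, method="beta")
    # statsmodels returns NaN at the degenerate edges; the exact bounds are 0/1
    lo = 0.0 if k == 0 else float(lo)
    hi = 1.0 if k == n else float(hi)
    return lo, hi


def wilson_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval (reported alongside the exact one for
    prevalence)."""
    if not 0 <= k <= n or n < 1:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    lo, hi = proportion_confint(k, n, alpha=1 - level, method="wilson")
    return float(lo), float(hi)


class ProportionWithCI(BaseModel):
    numerator: int
    denominator: int
    point: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    method: str = "clopper-pearson"

    @classmethod
    def from_counts(
        cls, k: int, n: int, level: float = 0.95, method: str = "clopper-pearson"
    ) -> "ProportionWithCI":
        ci = exact_binomial_ci(k, n, level) if method == "clopper-pearson" else wilson_ci(k, n, level)
        return cls(
            numerator=k,
            denominator=n,
            point=k / n,
            ci_low=ci[0],
            ci_high=ci[1],
            level=level,
            method=method,
        )

    @property
    def percent(self) -> float:
        """Point estimate as a half-up-rounded integer percent."""
        return round_half_up(100 * self.point)

    def display(self) -> str:
        """Printed-table style, e.g. ``"85 (74-92)"``."""
        f = lambda p: f"{round_half_up(100 * p):g}"  # noqa: E731
        return f"{f(self.point)} ({f(self.ci_low)}–{f(self.ci_high)})"


class DiagnosticReport(BaseModel):
    cm: ConfusionMatrix
    sensitivity: ProportionWithCI | None
    specificity: ProportionWithCI | None
    ppv: ProportionWithCI | None
    npv: ProportionWithCI | None
    fpr: ProportionWithCI | None


def confusion_matrix(
    truth: Mapping[str, bool], predicted: Mapping[str, bool]
) -> ConfusionMatrix:
    """Tabulate per-patient predictions against truth.

    Both mappings must cover exactly the same patient set.
    """
    if set(truth) != set(predicted):
        missing = set(truth) ^ set(predicted)
        raise ValueError(f"truth/predicted patient sets differ, e.g. {sorted(missing)[:5]}")
    tp = fp = tn = fn = 0
    for pid, t in truth.items():
        p = predicted[pid]
        if t and p:
            tp += 1
        elif t:
            fn += 1
        elif p:
            fp += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def diagnostic_report(cm: ConfusionMatrix, level: float = 0.95) -> DiagnosticReport:
    """Sensitivity, specificity, PPV, NPV and FPR with exact CIs.

    A metric whose denominator is zero is reported as ``None`` (undefined),
    never as 0.
    """
    if cm.total == 0:
        raise ValueError("confusion matrix is all zeros")

    def prop(k: int, n: int) -> ProportionWithCI | None:
        return ProportionWithCI.from_counts(k, n, level) if n > 0 else None

    return DiagnosticReport(
        cm=cm,
        sensitivity=prop(cm.tp, cm.tp + cm.fn),
        specificity=prop(cm.tn, cm.tn + cm.fp),
        ppv=prop(cm.tp, cm.tp + cm.fp),
        npv=prop(cm.tn, cm.tn + cm.fn),
        fpr=prop(cm.fp, cm.tp + cm.fp),
    )


class PrevalenceEstimate(BaseModel):
    """Prevalence as a proportion and in "1 in N" form, with exact and
    Wilson intervals (inverted consistently: a lower proportion bound maps
    to the larger "1 in" number)."""

    cases: int
    n: int
    one_in: int | None
    proportion: float
    exact: ProportionWithCI
    wilson: ProportionWithCI
    one_in_low_exact: int | None
    one_in_high_exact: int | None
    one_in_low_wilson: int | None
    one_in_high_wilson: int | None


def _one_in(p: float) -> int | None:
    return int(round_half_up(1 / p)) if p > 0 else None


def prevalence_estimate(cases: int, n: int, level: float = 0.95) -> PrevalenceEstimate:
    """Prevalence of ``cases`` among ``n`` with both CI methods.

    ``one_in = round(n / cases)``; the "1 in" CI bounds are the reciprocals
    of the proportion bounds, so ``one_in_low`` (the rarer bound) comes from
    ``ci_low``.
    """
    if not 0 <= cases <= n or n < 1:
        raise ValueError(f"need 0 <= cases <= n, got cases={cases}, n={n}")
    exact = ProportionWithCI.from_counts(cases, n, level)
    wil = ProportionWithCI.from_counts(cases, n, level, method="wilson")
    return PrevalenceEstimate(
        cases=cases,
        n=n,
        one_in=_one_in(cases / n),
        proportion=cases / n,
        exact=exact,
        wilson=wil,
        one_in_low_exact=_one_in(exact.ci_low),
        one_in_high_exact=_one_in(exact.ci_high),
        one_in_low_wilson=_one_in(wil.ci_low),
        one_in_high_wilson=_one_in(wil.ci_high),
    )


def percent_agreement(
    labels_a: Sequence[str], labels_b: Sequence[str]
) -> tuple[float, float | None]:
    """Raw percent agreement between two raters, plus Cohen's kappa.

    Kappa corrects agreement for chance using the product of marginal label
    frequencies; it is undefined (``None``) when expected agreement is 1.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError("label vectors differ in length")
    if not labels_a:
        raise ValueError("empty label vectors")
    n = len(labels_a)
    po = sum(a == b for a, b in zip(labels_a, labels_b)) / n
    return po, cohens_kappa(labels_a, labels_b)


def cohens_kappa(labels_a: Sequence[str], labels_b: Sequence[str]) -> float | None:
    n = len(labels_a)
    ca, cb = Counter(labels_a), Counter(labels_b)
    pe = sum(ca[k] * cb.get(k, 0) for k in ca) / (n * n)
    if pe == 1:
        return None
    po = sum(a == b for a, b in zip(labels_a, labels_b)) / n
    return (po - pe) / (1 - pe)


def code_frequency_table(
    cohort: Iterable[PatientRecord],
    combine_groups: Mapping[str, set[str]] | None = None,
    descriptions: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Frequency of outpatient diagnostic codes across a cohort's claims.

    Codes listed together in ``combine_groups`` (e.g. the skin-related
    codes 709, 216 and 173) are reported as a single row under the group
    label.  ``percent`` is the share of all encounters, half-up rounded to
    one decimal; ``count`` is exact.  Sorted by count descending.
    """
    counts: Counter[str] = Counter()
    total = 0
    for rec in cohort:
        for claim in rec.outpatient_claims:
            counts[claim.code] += 1
            total += 1
    if total == 0:
        return pd.DataFrame(columns=["code", "count", "percent"])
    combine_groups = combine_groups or {}
    code_to_group = {c: g for g, cs in combine_groups.items() for c in cs}
    grouped: Counter[str] = Counter()
    for code, cnt in counts.items():
        grouped[code_to_group.get(code, code)] += cnt
    rows = [
        {
            "code": key,
            "description": (descriptions or {}).get(key, ""),
            "count": cnt,
            "percent": round_half_up(100 * cnt / total, 1),
        }
        for key, cnt in grouped.items()
    ]
    df = pd.DataFrame(rows).sort_values(["count", "code"], ascending=[False, True])
    return df.reset_index(drop=True)


#: Table-4-style grouping: the three skin-related outpatient codes.
SKIN_CODE_GROUP = {"skin (709+216+173)": {"709", "216", "173"}}
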