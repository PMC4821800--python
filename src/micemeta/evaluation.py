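"""Document-level scoring of system annotations against a gold standard.

A document is a *positive* when the system emits an annotation for the
characteristic under evaluation. Counting is per document:

* gold reported, system reported, values agree            -> TP
* system reported, gold absent or values disagree         -> FP
* gold reported, system absent                            -> FN
* neither reported                                        -> TN

Value agreement is strict by default: sex must match in category
(female/male/both); age must match after normalizing both ranges to days
(day=1, week=7, month=30), with an optional +/- tolerance in days.

Precision = 100*TP/(TP+FP), recall = 100*TP/(TP+FN), and the F-score is the
harmonic mean 2*P*R/(P+R) on the percent scale. Zero-denominator cases are
signalled (UndefinedMetricError), never silently reported as 0. Display
values are truncated (not rounded) to one decimal — the convention under
which the evaluation table is internally consistent, e.g. P=96.8 from
TP=31, FP=1 — while the raw values stay available on EvalMetrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional

from .extraction import normalize_age_to_days
from .models import (
    ConfusionMatrix,
    DocAnnotation,
    EvalMetrics,
    GoldAnnotation,
    InputError,
    UndefinedMetricError,
)


def _age_agrees(system, gold, tolerance_days: float) -> bool:
    s_lo, s_hi = normalize_age_to_days(system)
    g_lo, g_hi = normalize_age_to_days(gold)
    return abs(s_lo - g_lo) <= tolerance_days and abs(s_hi - g_hi) <= tolerance_days


def confusion_matrix(
    system: Iterable[DocAnnotation],
    gold: Dict[str, GoldAnnotation],
    characteristic: str,
    age_tolerance_days: float = 0.0,
) -> ConfusionMatrix:
    """Tally document-level TP/TN/FP/FN for one characteristic (sex|age)."""
    if characteristic not in ("sex", "age"):
        raise ValueError(f"unknown characteristic {characteristic!r}")
    system = list(system)
    missing = [a.doc_id for a in system if a.doc_id not in gold]
    if missing:
        raise InputError(f"no gold annotation for doc_id(s): {', '.join(sorted(missing))}")

    tp = tn = fp = fn = 0
    for ann in system:
        g = gold[ann.doc_id]
        if characteristic == "sex":
            sys_pos = ann.sex_status != "none"
            gold_pos = g.sex_status != "none"
            agree = sys_pos and gold_pos and ann.sex_status == g.sex_status
        else:
            sys_pos = ann.age_status == "reported"
            gold_pos = g.age_status == "reported"
            agree = (sys_pos and gold_pos
                     and _age_agrees(ann.age_value, g.age_value, age_tolerance_days))
        if sys_pos and agree:
            tp += 1
        elif sys_pos:
            fp += 1
        elif gold_pos:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)


def precision(cm: ConfusionMatrix) -> float:
    """100*TP/(TP+FP); undefined when the system returned no positives."""
    if cm.tp + cm.fp == 0:
        raise UndefinedMetricError("precision undefined: TP+FP = 0")
    return 100.0 * cm.tp / (cm.tp + cm.fp)


def recall(cm: ConfusionMatrix) -> float:
    """100*TP/(TP+FN); undefined when gold contains no positives."""
    if cm.tp + cm.fn == 0:
        raise UndefinedMetricError("recall undefined: TP+FN = 0")
    return 100.0 * cm.tp / (cm.tp + cm.fn)


def f_score(p: float, r: float) -> float:
    """Harmonic mean of precision and recall on the percent scale."""
    if p + r == 0:
        raise UndefinedMetricError("F-score undefined: P+R = 0")
    return 2.0 * p * r / (p + r)


def truncate_pct(x: float, decimals: int = 1) -> float:
    """Truncate a percentage toward zero at the given number of decimals."""
    k = 10 ** decimals
    # guard against float artifacts like 96.875*10 -> 968.7499999
    return math.floor(round(x * k, 9)) / k


@dataclass(frozen=True)
class CharacteristicReport:
    characteristic: str
    cm: ConfusionMatrix
    raw: EvalMetrics
    display: EvalMetrics  # truncated to one decimal


def metrics_from_cm(cm: ConfusionMatrix) -> EvalMetrics:
    p = precision(cm)
    r = recall(cm)
    return EvalMetrics(precision=p, recall=r, f_score=f_score(p, r))


def display_metrics(cm: ConfusionMatrix) -> EvalMetrics:
    """One-decimal presentation: P and R are truncated first, then F is the
    harmonic mean of the truncated pair, itself truncated."""
    p = truncate_pct(precision(cm))
    r = truncate_pct(recall(cm))
    return EvalMetrics(precision=p, recall=r, f_score=truncate_pct(f_score(p, r)))


def evaluate(
    system: Iterable[DocAnnotation],
    gold: Dict[str, GoldAnnotation],
    age_tolerance_days: float = 0.0,
) -> Dict[str, CharacteristicReport]:
    """Score both characteristics; returns one report per characteristic."""
    system = list(system)
    out = {}
    for characteristic in ("sex", "age"):
        cm = confusion_matrix(system, gold, characteristic,
                              age_tolerance_days=age_tolerance_days)
        out[characteristic] = CharacteristicReport(
            characteristic=characteristic, cm=cm,
            raw=metrics_from_cm(cm), display=display_metrics(cm),
        )
    return out


def format_report(reports: Dict[str, CharacteristicReport]) -> str:
    """Fixed-width evaluation table (TP/TN/FP/FN, P, R, F per characteristic)."""
    lines = [
        f"{'Characteristic':<15}{'TP':>5}{'TN':>5}{'FP':>5}{'FN':>5}"
        f"{'P (%)':>9}{'R (%)':>9}{'F (%)':>9}"
    ]
    for name, rep in reports.items():
        cm, d = rep.cm, rep.display
        lines.append(
            f"{name.capitalize():<15}{cm.tp:>5}{cm.tn:>5}{cm.fp:>5}{cm.fn:>5}"
            f"{d.precision:>9.1f}{d.recall:>9.1f}{d.f_score:>9.1f}"
        )
    return "\n".join(lines)
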