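"""Corpus-level reporting statistics over document annotations.

Documents (not mice) are the unit of analysis throughout. Each document
falls in exactly one reporting category — both characteristics reported,
sex only, age only, or none — and the analytics stratify those categories
by year, journal, disease group or research subgroup, compute sex-bias
ratios on female-only vs male-only documents, test the female/male split
with an exact binomial test, compare strata with a two-way ANOVA without
replication (one observation per cell; the interaction is the residual),
and correlate a per-journal reporting index against journal metrics with
Spearman's rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .models import (
    DocAnnotation,
    InputError,
    MetadataTable,
    UndefinedMetricError,
)

CATEGORIES = ("both_reported", "sex_only", "age_only", "none")
STRATIFY_FIELDS = ("year", "journal", "disease_group", "subgroup")


def reporting_category(ann: DocAnnotation) -> str:
    """Exhaustive, mutually exclusive assignment of a document."""
    sex = ann.sex_status != "none"
    age = ann.age_status == "reported"
    if sex and age:
        return "both_reported"
    if sex:
        return "sex_only"
    if age:
        return "age_only"
    return "none"


@dataclass(frozen=True)
class ReportingSummary:
    stratum: str
    counts: Dict[str, int]  # category -> count

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def percentages(self) -> Dict[str, float]:
        n = self.total
        return {c: (100.0 * k / n if n else 0.0) for c, k in self.counts.items()}


@dataclass(frozen=True)
class SexBreakdown:
    stratum: str
    female: int
    male: int
    both: int
    not_reported: int

    @property
    def total(self) -> int:
        return self.female + self.male + self.both + self.not_reported


@dataclass(frozen=True)
class BiasRatio:
    stratum: str
    direction: str  # "female" | "male" | "none"
    ratio: float  # majority:minority, >= 1


@dataclass(frozen=True)
class AnovaFactor:
    ss: float
    df: int
    ms: float
    f: Optional[float]
    p_value: Optional[float]


@dataclass(frozen=True)
class AnovaResult:
    rows: AnovaFactor
    cols: AnovaFactor
    residual: AnovaFactor
    ss_total: float


def _strata_of(doc_id: str, metadata: Optional[MetadataTable], stratify_by: Optional[str]):
    """The stratum label(s) a document contributes to (groups may overlap)."""
    if stratify_by is None:
        return ("all",)
    if stratify_by not in STRATIFY_FIELDS:
        raise InputError(f"unknown stratify field {stratify_by!r}; "
                         f"expected one of {STRATIFY_FIELDS}")
    if metadata is None or doc_id not in metadata:
        raise InputError(f"no metadata for doc_id {doc_id!r}")
    rec = metadata[doc_id]
    if stratify_by == "year":
        return (str(rec.year),)
    if stratify_by == "journal":
        return (rec.journal or "",)
    if stratify_by == "disease_group":
        return tuple(sorted(rec.disease_groups))
    return tuple(sorted(rec.subgroups))


def reporting_breakdown(
    annotations: Iterable[DocAnnotation],
    metadata: Optional[MetadataTable] = None,
    stratify_by: Optional[str] = None,
) -> List[ReportingSummary]:
    """Per-stratum counts of the four reporting categories.

    With ``stratify_by=None`` a single "all" stratum is returned. A document
    belonging to several disease groups contributes to each of them (group
    membership is input metadata, not exclusive)."""
    tallies: Dict[str, Dict[str, int]] = {}
    for ann in annotations:
        cat = reporting_category(ann)
        for stratum in _strata_of(ann.doc_id, metadata, stratify_by):
            t = tallies.setdefault(stratum, {c: 0 for c in CATEGORIES})
            t[cat] += 1
    return [ReportingSummary(stratum=s, counts=tallies[s]) for s in sorted(tallies)]


def sex_breakdown(
    annotations: Iterable[DocAnnotation],
    metadata: Optional[MetadataTable] = None,
    stratify_by: Optional[str] = None,
) -> List[SexBreakdown]:
    """Per-stratum counts of female-only / male-only / both / not-reported."""
    tallies: Dict[str, Dict[str, int]] = {}
    for ann in annotations:
        key = ann.sex_status if ann.sex_status != "none" else "not_reported"
        for stratum in _strata_of(ann.doc_id, metadata, stratify_by):
            t = tallies.setdefault(
                stratum, {"female": 0, "male": 0, "both": 0, "not_reported": 0})
            t[key] += 1
    return [SexBreakdown(stratum=s, **tallies[s]) for s in sorted(tallies)]


def yearly_trend(summaries: List[ReportingSummary]) -> Dict[int, Dict[str, float]]:
    """Normalize per-year category counts to fractions of that year's articles."""
    if not summaries:
        raise InputError("yearly_trend needs at least one year stratum")
    out: Dict[int, Dict[str, float]] = {}
    for s in summaries:
        n = s.total
        out[int(s.stratum)] = {c: (s.counts[c] / n if n else 0.0) for c in CATEGORIES}
    return out


def trend_slope(series: Sequence[Tuple[float, float]]) -> float:
    """OLS slope of fraction on year."""
    years = np.asarray([p[0] for p in series], dtype=float)
    fracs = np.asarray([p[1] for p in series], dtype=float)
    if len(np.unique(years)) < 2:
        raise InputError("trend_slope needs at least two distinct years")
    slope, _intercept = np.polyfit(years, fracs, 1)
    return float(slope)


def sex_bias_ratio(breakdown: SexBreakdown) -> BiasRatio:
    """Majority:minority ratio of female-only vs male-only documents.

    Both-sex documents are excluded from both sides. Equal counts give
    ratio 1 with direction "none"."""
    f, m = breakdown.female, breakdown.male
    if f + m == 0:
        raise UndefinedMetricError(
            f"sex bias undefined in stratum {breakdown.stratum!r}: no single-sex documents")
    if f == m:
        return BiasRatio(stratum=breakdown.stratum, direction="none", ratio=1.0)
    if f > m:
        if m == 0:
            raise UndefinedMetricError(
                f"sex bias undefined in stratum {breakdown.stratum!r}: zero male-only documents")
        return BiasRatio(stratum=breakdown.stratum, direction="female", ratio=f / m)
    if f == 0:
        raise UndefinedMetricError(
            f"sex bias undefined in stratum {breakdown.stratum!r}: zero female-only documents")
    return BiasRatio(stratum=breakdown.stratum, direction="male", ratio=m / f)


def binomial_proportion_test(
    n_female: int,
    n_male: int,
    ci_method: str = "normal",
) -> Tuple[float, float, float, float]:
    """Two-sided exact binomial test of p=0.5 on the female share.

    Returns (p_hat, p_value, ci_low_pct, ci_high_pct). The 95% CI for the
    female proportion uses the normal approximation p +/- 1.96*sqrt(p(1-p)/n)
    by default (``ci_method="normal"``); Clopper-Pearson is available via
    ``ci_method="exact"``. CI bounds are on the percent scale.
    """
    n = n_female + n_male
    if n == 0:
        raise InputError("binomial test needs at least one single-sex document")
    test = stats.binomtest(n_female, n, p=0.5, alternative="two-sided")
    p_hat = n_female / n
    if ci_method == "normal":
        half = 1.96 * np.sqrt(p_hat * (1.0 - p_hat) / n)
        lo, hi = p_hat - half, p_hat + half
    elif ci_method == "exact":
        ci = test.proportion_ci(confidence_level=0.95, method="exact")
        lo, hi = ci.low, ci.high
    else:
        raise InputError(f"unknown ci_method {ci_method!r}")
    return p_hat, float(test.pvalue), float(100.0 * lo), float(100.0 * hi)


def two_way_anova_no_replication(table) -> AnovaResult:
    """Two-factor ANOVA with one observation per cell.

    ``table`` is an r x c array-like (rows = strata, columns = categories,
    cells typically percentages). The classical partition is
    SS_total = SS_rows + SS_cols + SS_residual with df (r-1), (c-1),
    (r-1)(c-1); with no replication the interaction serves as the error
    term, so F = MS_factor / MS_residual.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise InputError("ANOVA table must be at least 2x2")
    if np.isnan(x).any():
        raise InputError("ANOVA table has missing cells")
    r, c = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = c * float(((row_means - grand) ** 2).sum())
    ss_cols = r * float(((col_means - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ss_resid = float((resid ** 2).sum())
    df_rows, df_cols = r - 1, c - 1
    df_resid = df_rows * df_cols
    ms_rows = ss_rows / df_rows
    ms_cols = ss_cols / df_cols
    ms_resid = ss_resid / df_resid

    def factor(ss: float, df: int, ms: float) -> AnovaFactor:
        if ms_resid == 0.0:
            return AnovaFactor(ss=ss, df=df, ms=ms, f=None, p_value=None)
        f = ms / ms_resid
        return AnovaFactor(ss=ss, df=df, ms=ms, f=f,
                           p_value=float(stats.f.sf(f, df, df_resid)))

    return AnovaResult(
        rows=factor(ss_rows, df_rows, ms_rows),
        cols=factor(ss_cols, df_cols, ms_cols),
        residual=AnovaFactor(ss=ss_resid, df=df_resid, ms=ms_resid, f=None, p_value=None),
        ss_total=ss_total,
    )


def journal_reporting_index(n_reporting_any: int, n_reporting_none: int) -> float:
    """Articles reporting sex and/or age divided by articles reporting neither."""
    if n_reporting_none == 0:
        raise UndefinedMetricError(
            "reporting index undefined: no non-reporting articles in this journal")
    return n_reporting_any / n_reporting_none


def spearman_rank_corr(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Spearman's rank correlation (mid-ranks for ties) with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputError("spearman: vectors must have equal length")
    if len(x) < 3:
        raise InputError("spearman: need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedMetricError("spearman undefined for a constant vector")
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)


def journal_reporting_indices(
    annotations: Iterable[DocAnnotation],
    metadata: MetadataTable,
    min_articles: int = 1,
) -> Dict[str, float]:
    """Per-journal reporting index; journals with a zero denominator are
    skipped (they cannot enter the correlation) as are journals below
    ``min_articles``."""
    summaries = reporting_breakdown(annotations, metadata, stratify_by="journal")
    out: Dict[str, float] = {}
    for s in summaries:
        if s.total < min_articles:
            continue
        n_any = s.total - s.counts["none"]
        try:
            out[s.stratum] = journal_reporting_index(n_any, s.counts["none"])
        except UndefinedMetricError:
            continue
    return out
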