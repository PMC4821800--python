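"""Core domain types shared across the pipeline.

The unit of analysis throughout is the *document*: a full-text article is
scanned for sex and age mentions, the candidates are unified to at most one
mention per characteristic, and all downstream scoring and analytics operate
on those document-level annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

SEX_CATEGORIES = ("female", "male", "both")
SEX_STATUSES = SEX_CATEGORIES + ("none",)
AGE_UNITS = ("day", "week", "month")
SUBGROUPS = ("genetics", "immunology", "physiopathology", "therapy")

#: Declared day-equivalents used by :func:`micemeta.extraction.normalize_age_to_days`.
DAYS_PER_UNIT = {"day": 1, "week": 7, "month": 30}


class MicemetaError(Exception):
    """Base class for package errors."""


class InputError(MicemetaError):
    """Malformed or inconsistent user input (files, tables, configs)."""


class UndefinedMetricError(MicemetaError):
    """A statistic whose defining ratio has a zero denominator."""


@dataclass(frozen=True)
class AgeValue:
    """A numeric age range bound to a time unit.

    ``qualifier`` is ``"exact"`` when the source phrase carried a single
    numeral (min == max) and ``"range"`` for a closed numeric range.
    """

    min_value: float
    max_value: float
    unit: str
    qualifier: str = "exact"

    def __post_init__(self) -> None:
        if self.unit not in AGE_UNITS:
            raise ValueError(f"unknown age unit {self.unit!r}; expected one of {AGE_UNITS}")
        if not (0 <= self.min_value <= self.max_value):
            raise ValueError(
                f"invalid age bounds ({self.min_value}, {self.max_value}): "
                "need 0 <= min <= max"
            )
        if self.qualifier not in ("exact", "range"):
            raise ValueError(f"unknown qualifier {self.qualifier!r}")


@dataclass(frozen=True)
class Mention:
    """One matched text span, typed as a sex or an age statement.

    Offsets are 0-based and half-open over the document text; ``surface``
    must equal ``text[start:end]`` (checked by the matcher, not here, since
    the mention does not carry the text).
    """

    doc_id: str
    start: int
    end: int
    surface: str
    kind: str  # "sex" | "age"
    rule_id: str
    sex_category: Optional[str] = None
    age_value: Optional[AgeValue] = None

    def __post_init__(self) -> None:
        if self.kind not in ("sex", "age"):
            raise ValueError(f"unknown mention kind {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")
        if self.kind == "sex":
            if self.sex_category not in SEX_CATEGORIES or self.age_value is not None:
                raise ValueError("sex mention must carry sex_category and no age_value")
        else:
            if self.age_value is None or self.sex_category is not None:
                raise ValueError("age mention must carry age_value and no sex_category")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ArticleDoc:
    """One full-text document plus its study metadata.

    ``segments`` optionally records labeled section spans (label, start, end)
    over ``text``; extraction always runs over the whole text.
    """

    doc_id: str
    text: str
    year: Optional[int] = None
    journal: Optional[str] = None
    disease_groups: frozenset = field(default_factory=frozenset)
    subgroups: frozenset = field(default_factory=frozenset)
    segments: Optional[list] = None

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")
        if self.year is not None and not (1900 <= self.year <= 2100):
            raise ValueError(f"implausible publication year {self.year}")


@dataclass(frozen=True)
class MetadataRecord:
    year: Optional[int]
    journal: Optional[str]
    disease_groups: frozenset
    subgroups: frozenset


@dataclass
class MetadataTable:
    """Mapping doc_id -> study metadata (year, journal, groups, subgroups)."""

    records: dict  # doc_id -> MetadataRecord

    def __getitem__(self, doc_id: str) -> MetadataRecord:
        return self.records[doc_id]

    def __contains__(self, doc_id: str) -> bool:
        return doc_id in self.records

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class DocAnnotation:
    """The unified document-level annotation: one mention per characteristic.

    ``sex_status`` is the category of the winning sex mention or ``"none"``;
    ``age_status`` is ``"reported"`` or ``"none"``. ``sex_qualifier``
    distinguishes both-sex designs only when the winning mention itself
    encodes it (mixed vs separated); analytics treat all of them as "both".
    """

    doc_id: str
    sex_status: str = "none"
    sex_mention: Optional[Mention] = None
    sex_qualifier: Optional[str] = None  # mixed | separated | unspecified
    age_status: str = "none"
    age_value: Optional[AgeValue] = None
    age_mention: Optional[Mention] = None

    def __post_init__(self) -> None:
        if self.sex_status not in SEX_STATUSES:
            raise ValueError(f"unknown sex status {self.sex_status!r}")
        if self.age_status not in ("reported", "none"):
            raise ValueError(f"unknown age status {self.age_status!r}")
        if (self.sex_status == "none") != (self.sex_mention is None):
            raise ValueError("sex_status none iff sex_mention absent")
        if (self.age_status == "none") != (self.age_value is None):
            raise ValueError("age_status none iff age_value absent")


@dataclass(frozen=True)
class GoldAnnotation:
    """Manually assigned document-level truth, same vocabulary as DocAnnotation."""

    doc_id: str
    sex_status: str = "none"  # female | male | both | none
    age_status: str = "none"  # reported | none
    age_value: Optional[AgeValue] = None

    def __post_init__(self) -> None:
        if self.sex_status not in SEX_STATUSES:
            raise ValueError(f"unknown sex status {self.sex_status!r}")
        if self.age_status not in ("reported", "none"):
            raise ValueError(f"unknown age status {self.age_status!r}")
        if (self.age_status == "none") != (self.age_value is None):
            raise ValueError("age_status none iff age_value absent")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Document-level counts: a positive is a document with a (correct) annotation."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class EvalMetrics:
    """Precision/recall/F on the percent scale (raw, unrounded)."""

    precision: float
    recall: float
    f_score: float
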