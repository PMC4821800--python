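"""Synthetic article generator with known gold annotations.

Each generated document is Methods-like filler prose plus zero, one or two
informative sentences drawn from an "in-grammar" template tier (guaranteed
matchable by the default rules), and optionally one "hard-case" distractor
sentence: sex implied only by pregnancy, literal sex words inside an
embryo-crossing/breeding description, or an open-ended age span with no
closed numeric range. Gold annotations reflect only the informative
sentences, never the distractors — so on a distractor-free corpus the
default extraction pipeline scores P = R = 100% against the generator's
gold, and with distractors enabled every error falls in one of the
documented hard-case classes.

Generation is fully deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .models import (
    AgeValue,
    ArticleDoc,
    GoldAnnotation,
    InputError,
    MetadataRecord,
    MetadataTable,
)

# ---------------------------------------------------------------------------
# Configuration

#: Default per-disease-group sex mixes (female, male, both) for single-sex
#: bias structure: cardiovascular male-heavy, infectious female-heavy,
#: diabetes mildly male-heavy; remaining groups follow the global default.
DEFAULT_GROUP_SEX_MIX = {
    "cardiovascular": (0.28, 0.63, 0.09),
    "infectious": (0.708, 0.20, 0.092),
    "diabetes": (0.35, 0.55, 0.10),
}

DEFAULT_DISEASE_GROUPS = (
    "cardiovascular", "cancer", "diabetes", "lung", "infectious", "neurological",
)

DEFAULT_JOURNALS = tuple(f"Synthetic Journal {i:02d}" for i in range(1, 21))

SUBGROUP_POOL = ("genetics", "immunology", "physiopathology", "therapy")


@dataclass
class SynthConfig:
    """Study-condition parameters for corpus generation.

    The default category mix (50% both, 12% sex only, 18% age only, 20%
    none) and the default sex mix (51% female, 37% male, 12% both sexes)
    describe a corpus where roughly one article in five reports neither
    characteristic and female-only studies outnumber male-only ones by
    about 1.4:1.
    """

    n_docs: int = 100
    p_both: float = 0.50
    p_sex_only: float = 0.12
    p_age_only: float = 0.18
    p_none: float = 0.20
    #: probabilities over (female, male, both) for documents that report sex
    sex_mix: Tuple[float, float, float] = (0.51, 0.37, 0.12)
    #: probabilities over (day, week, month) for documents that report age
    age_unit_mix: Tuple[float, float, float] = (0.15, 0.75, 0.10)
    distractor_rate: float = 0.0
    year_range: Tuple[int, int] = (1994, 2014)
    journals: Tuple[str, ...] = DEFAULT_JOURNALS
    disease_groups: Tuple[str, ...] = DEFAULT_DISEASE_GROUPS
    #: per-group overrides of sex_mix (female, male, both)
    group_sex_mix: Dict[str, Tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SEX_MIX))
    seed: int = 0

    def __post_init__(self) -> None:
        cat = self.p_both + self.p_sex_only + self.p_age_only + self.p_none
        if abs(cat - 1.0) > 1e-9:
            raise InputError(f"category probabilities sum to {cat}, not 1")
        for name, vec in [("sex_mix", self.sex_mix), ("age_unit_mix", self.age_unit_mix),
                          *[(f"group_sex_mix[{g}]", v) for g, v in self.group_sex_mix.items()]]:
            if abs(sum(vec) - 1.0) > 1e-9 or min(vec) < 0:
                raise InputError(f"{name} must be a normalized probability vector, got {vec}")
        if not 0 <= self.distractor_rate <= 1:
            raise InputError("distractor_rate must be in [0, 1]")
        if self.n_docs < 0:
            raise InputError("n_docs must be >= 0")


# ---------------------------------------------------------------------------
# Template tiers

# In-grammar sex sentences: {category} formatting slots; every template's
# matched span is longer than any span a distractor can produce ("females",
# 7 chars), so the informative mention always wins unification.
_SEX_TEMPLATES = {
    "female": (
        "Ten C57BL/6 female mice were housed under specific pathogen-free conditions.",
        "All experiments used female mice obtained from the institutional colony.",
    ),
    "male": (
        "Groups of eight male mice were assigned to each treatment arm.",
        "Only male mice were included to limit hormonal variation.",
    ),
    "both": (
        "Mice of either sex were used throughout the study.",
        "Cohorts included both sexes in equal numbers.",
    ),
}

# In-grammar age sentences; slots: lo, hi (integers), unit word.
_AGE_RANGE_TEMPLATES = (
    "Animals were aged {lo} to {hi} {unit}s old at the start of treatment.",
    "Experiments were performed on {lo}-{hi}-{unit}s old animals.",
    "Subjects were {lo} to {hi} {unit}s of age at enrollment.",
)
_AGE_SINGLE_TEMPLATES = (
    "Animals were {n}-{unit}s old at the time of inoculation.",
    "Tissue was collected at the age of {n} {unit}s.",
    "All animals were {n} {unit}s of age when imaging began.",
)

# Hard-case distractors: resemble sex/age statements but carry no gold
# annotation. Classes: pregnancy-implied sex, breeding-cross sex words,
# open-ended age span.
DISTRACTOR_CLASSES = ("pregnancy", "crossing", "open_age")
_DISTRACTORS = {
    "pregnancy": "Primary epithelial cells were isolated from 15-d timed-pregnant CD-1 mice.",
    "crossing": "The colony is maintained by crossing male carriers with FVB/NJ females.",
    "open_age": ("Nineteen animals of ages from postnatal day (P) 7 to several months "
                 "were deeply anesthetized."),
}

# Filler vocabulary: deliberately free of sex words, age clues and
# numeral-unit collocations so filler can never produce a mention.
_FILLER_WORDS = (
    "the protocol was approved by institutional committees and tissue samples "
    "were processed according to standard procedures . lysates were analyzed "
    "by immunoblotting with antibodies against target proteins . sections were "
    "stained with hematoxylin and imaged on a confocal microscope . data were "
    "normalized against housekeeping controls and compared across conditions . "
    "statistical significance was assessed with appropriate corrections"
).split()

_UNIT_WORDS = ("day", "week", "month")
_UNIT_AGE_BOUNDS = {"day": (3, 28), "week": (3, 20), "month": (1, 12)}


def _filler(rng: np.random.Generator, n_words: int) -> str:
    words = rng.choice(np.array(_FILLER_WORDS, dtype=object), size=n_words)
    return " ".join(words.tolist())


def _draw_age(cfg: SynthConfig, rng: np.random.Generator) -> Tuple[AgeValue, str]:
    unit = _UNIT_WORDS[int(rng.choice(3, p=list(cfg.age_unit_mix)))]
    lo_bound, hi_bound = _UNIT_AGE_BOUNDS[unit]
    if rng.random() < 0.5:  # closed numeric range
        lo = int(rng.integers(lo_bound, hi_bound))
        hi = int(rng.integers(lo + 1, hi_bound + 1))
        tmpl = _AGE_RANGE_TEMPLATES[int(rng.integers(len(_AGE_RANGE_TEMPLATES)))]
        return (AgeValue(lo, hi, unit, qualifier="range"),
                tmpl.format(lo=lo, hi=hi, unit=unit))
    n = int(rng.integers(lo_bound, hi_bound + 1))
    tmpl = _AGE_SINGLE_TEMPLATES[int(rng.integers(len(_AGE_SINGLE_TEMPLATES)))]
    return AgeValue(n, n, unit, qualifier="exact"), tmpl.format(n=n, unit=unit)


def _draw_sex(cfg: SynthConfig, rng: np.random.Generator,
              groups: Tuple[str, ...]) -> Tuple[str, str]:
    mix = cfg.sex_mix
    for g in groups:
        if g in cfg.group_sex_mix:
            mix = cfg.group_sex_mix[g]
            break
    cat = ("female", "male", "both")[int(rng.choice(3, p=list(mix)))]
    templates = _SEX_TEMPLATES[cat]
    return cat, templates[int(rng.integers(len(templates)))]


def generate_document(
    cfg: SynthConfig,
    rng: np.random.Generator,
    doc_id: str = "synth-0",
) -> Tuple[ArticleDoc, GoldAnnotation]:
    """One document plus its gold annotation, consuming the given RNG stream."""
    year = int(rng.integers(cfg.year_range[0], cfg.year_range[1] + 1))
    journal = cfg.journals[int(rng.integers(len(cfg.journals)))]
    group = cfg.disease_groups[int(rng.integers(len(cfg.disease_groups)))]
    subgroup = SUBGROUP_POOL[int(rng.integers(len(SUBGROUP_POOL)))]
    groups = (group,)

    category = CATEGORY_NAMES[int(rng.choice(
        4, p=[cfg.p_both, cfg.p_sex_only, cfg.p_age_only, cfg.p_none]))]

    sentences: List[str] = [_filler(rng, int(rng.integers(20, 40)))]
    sex_status = "none"
    age_status = "none"
    age_value: Optional[AgeValue] = None

    if category in ("both_reported", "sex_only"):
        sex_status, sentence = _draw_sex(cfg, rng, groups)
        sentences.append(sentence)
    if category in ("both_reported", "age_only"):
        age_value, sentence = _draw_age(cfg, rng)
        age_status = "reported"
        sentences.append(sentence)
    if rng.random() < cfg.distractor_rate:
        cls = DISTRACTOR_CLASSES[int(rng.integers(len(DISTRACTOR_CLASSES)))]
        sentences.append(_DISTRACTORS[cls])
    sentences.append(_filler(rng, int(rng.integers(15, 30))))

    doc = ArticleDoc(
        doc_id=doc_id,
        text=" ".join(sentences),
        year=year,
        journal=journal,
        disease_groups=frozenset(groups),
        subgroups=frozenset({subgroup}),
    )
    gold = GoldAnnotation(doc_id=doc_id, sex_status=sex_status,
                          age_status=age_status, age_value=age_value)
    return doc, gold


CATEGORY_NAMES = ("both_reported", "sex_only", "age_only", "none")


def generate_corpus(
    cfg: SynthConfig,
) -> Tuple[List[ArticleDoc], Dict[str, GoldAnnotation], MetadataTable]:
    """n_docs documents with gold annotations and a joined metadata table."""
    rng = np.random.default_rng(cfg.seed)
    docs: List[ArticleDoc] = []
    gold: Dict[str, GoldAnnotation] = {}
    records: Dict[str, MetadataRecord] = {}
    for i in range(cfg.n_docs):
        doc, g = generate_document(cfg, rng, doc_id=f"synth-{i:05d}")
        docs.append(doc)
        gold[doc.doc_id] = g
        records[doc.doc_id] = MetadataRecord(
            year=doc.year, journal=doc.journal,
            disease_groups=doc.disease_groups, subgroups=doc.subgroups,
        )
    return docs, gold, MetadataTable(records)


def write_corpus(
    docs: List[ArticleDoc],
    gold: Dict[str, GoldAnnotation],
    out_dir,
) -> None:
    """Write one .txt per document plus metadata.tsv and gold.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for doc in docs:
        (out / f"{doc.doc_id}.txt").write_text(doc.text, encoding="utf-8")
    with open(out / "metadata.tsv", "w", encoding="utf-8") as fh:
        fh.write("doc_id\tyear\tjournal\tdisease_groups\tsubgroups\n")
        for doc in docs:
            fh.write("\t".join([
                doc.doc_id, str(doc.year), doc.journal or "",
                ";".join(sorted(doc.disease_groups)),
                ";".join(sorted(doc.subgroups)),
            ]) + "\n")
    with open(out / "gold.tsv", "w", encoding="utf-8") as fh:
        fh.write("doc_id\tsex_status\tsex_value\tage_status\tage_value\n")
        for doc in docs:
            g = gold[doc.doc_id]
            sex_status = "reported" if g.sex_status != "none" else "none"
            sex_value = g.sex_status if g.sex_status != "none" else ""
            if g.age_value is not None:
                v = g.age_value
                lo, hi = int(v.min_value), int(v.max_value)
                age_value = f"{lo}-{hi} {v.unit}s" if lo != hi else f"{lo} {v.unit}s"
            else:
                age_value = ""
            fh.write("\t".join([
                doc.doc_id, sex_status, sex_value, g.age_status, age_value,
            ]) + "\n")
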