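"""Reading corpora (plain text, JATS XML) and tabular inputs/outputs.

Text offsets everywhere are 0-based, half-open, over the concatenated
document text. JATS section structure is retained as labeled segments but
extraction operates on the whole text, including tables and captions.
"""

from __future__ import annotations

import csv
import json
import logging
import os
from pathlib import Path
from typing import Dict, List, Optional, Tuple

from lxml import etree

from .extraction import parse_age_phrase
from .models import (
    AgeValue,
    ArticleDoc,
    DocAnnotation,
    GoldAnnotation,
    InputError,
    MetadataRecord,
    MetadataTable,
    Mention,
    SUBGROUPS,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Plain-text corpora

def read_plain_text_corpus(
    directory: os.PathLike,
    manifest: Optional[Dict[str, str]] = None,
) -> Tuple[List[ArticleDoc], List[dict]]:
    """Load every ``*.txt`` file under ``directory`` as one document.

    ``manifest`` optionally maps filename -> doc_id; otherwise the stem is
    the doc_id. Unreadable (non-UTF-8) files are skipped with a warning and
    reported in the returned rejects list, so that
    ``len(docs) + len(rejects)`` equals the number of input files.
    Duplicate doc_ids are a hard error.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise InputError(f"not a directory: {directory}")
    docs: List[ArticleDoc] = []
    rejects: List[dict] = []
    seen = set()
    for path in sorted(directory.glob("*.txt")):
        doc_id = (manifest or {}).get(path.name, path.stem)
        try:
            text = path.read_text(encoding="utf-8")
        except UnicodeDecodeError as exc:
            logger.warning("skipping %s: not valid UTF-8 (%s)", path, exc)
            rejects.append({"file": str(path), "reason": f"not valid UTF-8: {exc}"})
            continue
        if doc_id in seen:
            raise InputError(f"duplicate doc_id {doc_id!r} (file {path})")
        seen.add(doc_id)
        docs.append(ArticleDoc(doc_id=doc_id, text=text))
    return docs, rejects


# ---------------------------------------------------------------------------
# JATS XML

def _text_of(el) -> str:
    return " ".join("".join(el.itertext()).split())


def read_jats_xml(file: os.PathLike) -> ArticleDoc:
    """Parse one JATS article: body paragraphs concatenated in document order.

    Section titles are kept as labeled segments (label, start, end) over the
    concatenated text. Journal and publication year are captured from the
    front matter when present. An article without a <body> yields empty text
    with a warning.
    """
    path = Path(file)
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise InputError(f"cannot parse JATS file {path}: {exc}") from exc
    root = tree.getroot()

    doc_id = None
    for aid in root.findall(".//front//article-id"):
        doc_id = aid.text
        if aid.get("pub-id-type") in ("pmc", "pmcid"):
            break
    if not doc_id:
        doc_id = path.stem

    journal = None
    jt = root.find(".//front//journal-title")
    if jt is not None and jt.text:
        journal = jt.text.strip()
    year = None
    y = root.find(".//front//pub-date/year")
    if y is not None and y.text and y.text.strip().isdigit():
        year = int(y.text.strip())

    body = root.find(".//body")
    if body is None:
        logger.warning("JATS file %s has no <body>; text is empty", path)
        return ArticleDoc(doc_id=doc_id, text="", year=year, journal=journal, segments=[])

    parts: List[str] = []
    segments: List[Tuple[str, int, int]] = []
    pos = 0

    def emit(label: str, paragraphs: List[str]) -> None:
        nonlocal pos
        if not paragraphs:
            return
        seg_start = None
        for p in paragraphs:
            if parts:
                pos += 2  # "\n\n" joiner
            if seg_start is None:
                seg_start = pos
            parts.append(p)
            pos += len(p)
        segments.append((label, seg_start, pos))

    # paragraphs directly under body, then each top-level section in order
    top_paras = [_text_of(p) for p in body.findall("p")]
    if top_paras:
        emit("", top_paras)
    for sec in body.findall("sec"):
        title_el = sec.find("title")
        label = _text_of(title_el) if title_el is not None else ""
        paras = [_text_of(p) for p in sec.iter("p")]
        emit(label, paras)

    text = "\n\n".join(parts)
    return ArticleDoc(doc_id=doc_id, text=text, year=year, journal=journal,
                      segments=segments)


# ---------------------------------------------------------------------------
# Tabular inputs

def _split_multi(cell: str) -> frozenset:
    return frozenset(t.strip() for t in cell.split(";") if t.strip()) if cell else frozenset()


def read_metadata_table(file: os.PathLike) -> MetadataTable:
    """TSV with columns doc_id, year, journal, disease_groups, subgroups.

    Multi-valued cells are semicolon-separated. Subgroup labels are checked
    against the declared vocabulary.
    """
    records: Dict[str, MetadataRecord] = {}
    with open(file, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"doc_id", "year", "journal", "disease_groups", "subgroups"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise InputError(
                f"metadata table {file}: need columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for i, row in enumerate(reader, start=2):
            doc_id = row["doc_id"].strip()
            if not doc_id:
                raise InputError(f"metadata table {file} row {i}: empty doc_id")
            if doc_id in records:
                raise InputError(f"metadata table {file} row {i}: duplicate doc_id {doc_id!r}")
            subgroups = _split_multi(row["subgroups"])
            unknown = subgroups - set(SUBGROUPS)
            if unknown:
                raise InputError(
                    f"metadata table {file} row {i}: unknown subgroup(s) {sorted(unknown)}"
                )
            records[doc_id] = MetadataRecord(
                year=int(row["year"]) if row["year"].strip() else None,
                journal=row["journal"].strip() or None,
                disease_groups=_split_multi(row["disease_groups"]),
                subgroups=subgroups,
            )
    return MetadataTable(records)


_GOLD_SEX_STATUS = {"reported", "none"}
_GOLD_SEX_VALUES = {
    "female": "female", "male": "male", "both": "both",
    "both (mixed)": "both", "both (separated)": "both",
}


def read_gold_annotations(file: os.PathLike) -> Dict[str, GoldAnnotation]:
    """TSV with columns doc_id, sex_status, sex_value, age_status, age_value.

    ``sex_value`` accepts female/male/both plus the qualified forms
    "both (mixed)" and "both (separated)", which collapse to category both.
    ``age_value`` is a free-form age phrase such as "6-8 weeks".
    Unknown status tokens are a hard error naming the row.
    """
    gold: Dict[str, GoldAnnotation] = {}
    with open(file, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"doc_id", "sex_status", "sex_value", "age_status", "age_value"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise InputError(
                f"gold table {file}: need columns {sorted(required)}, got {reader.fieldnames}"
            )
        for i, row in enumerate(reader, start=2):
            doc_id = row["doc_id"].strip()
            sex_status = row["sex_status"].strip().lower()
            if sex_status not in _GOLD_SEX_STATUS:
                raise InputError(
                    f"gold table {file} row {i}: unknown sex_status {row['sex_status']!r}"
                )
            if sex_status == "reported":
                value = row["sex_value"].strip().lower()
                if value not in _GOLD_SEX_VALUES:
                    raise InputError(
                        f"gold table {file} row {i}: unknown sex_value {row['sex_value']!r}"
                    )
                sex = _GOLD_SEX_VALUES[value]
            else:
                sex = "none"
            age_status = row["age_status"].strip().lower()
            if age_status not in ("reported", "none"):
                raise InputError(
                    f"gold table {file} row {i}: unknown age_status {row['age_status']!r}"
                )
            age_value = None
            if age_status == "reported":
                age_value = parse_age_phrase(row["age_value"].strip())
            if doc_id in gold:
                raise InputError(f"gold table {file} row {i}: duplicate doc_id {doc_id!r}")
            gold[doc_id] = GoldAnnotation(
                doc_id=doc_id, sex_status=sex, age_status=age_status, age_value=age_value,
            )
    return gold


# ---------------------------------------------------------------------------
# Annotation output (JSON-lines with full mention provenance, or flat TSV)

_ANN_COLUMNS = [
    "doc_id", "sex_status", "sex_qualifier", "sex_surface", "sex_start", "sex_end",
    "sex_rule", "age_status", "age_min", "age_max", "age_unit", "age_qualifier",
    "age_surface", "age_start", "age_end", "age_rule",
]


def _mention_to_dict(m: Optional[Mention]) -> Optional[dict]:
    if m is None:
        return None
    d = {"doc_id": m.doc_id, "start": m.start, "end": m.end, "surface": m.surface,
         "kind": m.kind, "rule_id": m.rule_id}
    if m.kind == "sex":
        d["sex_category"] = m.sex_category
    else:
        v = m.age_value
        d["age_value"] = {"min": v.min_value, "max": v.max_value,
                          "unit": v.unit, "qualifier": v.qualifier}
    return d


def _mention_from_dict(d: Optional[dict]) -> Optional[Mention]:
    if d is None:
        return None
    age = None
    if d.get("age_value"):
        a = d["age_value"]
        age = AgeValue(a["min"], a["max"], a["unit"], a["qualifier"])
    return Mention(doc_id=d["doc_id"], start=d["start"], end=d["end"],
                   surface=d["surface"], kind=d["kind"], rule_id=d["rule_id"],
                   sex_category=d.get("sex_category"), age_value=age)


def write_annotations(annotations: List[DocAnnotation], file: os.PathLike) -> None:
    """Write one record per document; format chosen by extension.

    ``.jsonl`` keeps full mention provenance and round-trips losslessly
    through :func:`read_annotations`; ``.tsv`` is a flat diff-friendly view.
    Absent characteristics are written as empty fields, never as the string
    "None". An empty list yields a header-only TSV / empty JSONL.
    """
    path = Path(file)
    if path.suffix == ".tsv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(_ANN_COLUMNS)
            for a in annotations:
                sm, am = a.sex_mention, a.age_mention
                v = a.age_value
                w.writerow([
                    a.doc_id, a.sex_status, a.sex_qualifier or "",
                    sm.surface if sm else "", sm.start if sm else "",
                    sm.end if sm else "", sm.rule_id if sm else "",
                    a.age_status,
                    v.min_value if v else "", v.max_value if v else "",
                    v.unit if v else "", v.qualifier if v else "",
                    am.surface if am else "", am.start if am else "",
                    am.end if am else "", am.rule_id if am else "",
                ])
        return
    with open(path, "w", encoding="utf-8") as fh:
        for a in annotations:
            v = a.age_value
            rec = {
                "doc_id": a.doc_id,
                "sex_status": a.sex_status,
                "sex_qualifier": a.sex_qualifier,
                "sex_mention": _mention_to_dict(a.sex_mention),
                "age_status": a.age_status,
                "age_value": ({"min": v.min_value, "max": v.max_value,
                               "unit": v.unit, "qualifier": v.qualifier}
                              if v else None),
                "age_mention": _mention_to_dict(a.age_mention),
            }
            fh.write(json.dumps(rec) + "\n")


def read_annotations(file: os.PathLike) -> List[DocAnnotation]:
    """Read annotations written by :func:`write_annotations` (JSONL only)."""
    out: List[DocAnnotation] = []
    with open(file, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            age = None
            if rec.get("age_value"):
                a = rec["age_value"]
                age = AgeValue(a["min"], a["max"], a["unit"], a["qualifier"])
            out.append(DocAnnotation(
                doc_id=rec["doc_id"],
                sex_status=rec["sex_status"],
                sex_qualifier=rec.get("sex_qualifier"),
                sex_mention=_mention_from_dict(rec.get("sex_mention")),
                age_status=rec["age_status"],
                age_value=age,
                age_mention=_mention_from_dict(rec.get("age_mention")),
            ))
    return out
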